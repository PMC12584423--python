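"""Probability model: Gaussian likelihood with group-indexed SDs, and priors.

The observation model for trial k of individual i in group g is

    y_k = x_k' beta + a_i + e_k,      a_i ~ N(0, sigma_A[g_i]^2),
                                      e_k ~ N(0, sigma_W[g_k]^2),

where sigma_A and sigma_W each hold either one shared value or one value per
population-by-sex group, according to the :class:`~behavar.design.ModelSpec`.
Modelling the residual SD as a saturated function of the group factor is the
group-heteroscedastic ("distributional") part of the model; storing the four
SDs directly is equivalent to a log-link regression of sigma on the group
factor and keeps every SD positive by construction.

Pointwise log-likelihoods are *conditional* on the individual intercepts
(the convention under which WAIC/LOO are computed from MCMC draws); the
marginal likelihood over a_i is available separately for cross-checks.

Priors are weakly informative: Normal(0, beta_scale) on each fixed-effect
coefficient (standardized-trait scale) and half-Student-t(df, scale) on every
SD component.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import DesignMatrices, ModelSpec
from .exceptions import ConfigurationError

__all__ = [
    "Parameters",
    "PriorConfig",
    "log_likelihood_pointwise",
    "log_prior",
    "simulate_responses",
    "marginal_loglik",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class Parameters:
    """One point in parameter space.

    beta : (p,) fixed-effect coefficients.
    a : (m,) individual random intercepts.
    sigma_a : (1,) or (4,) among-individual SD(s).
    sigma_w : (1,) or (4,) within-individual (residual) SD(s).
    """

    beta: np.ndarray
    a: np.ndarray
    sigma_a: np.ndarray
    sigma_w: np.ndarray

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, float))
        self.a = np.atleast_1d(np.asarray(self.a, float)) if np.size(self.a) else np.zeros(0)
        self.sigma_a = np.atleast_1d(np.asarray(self.sigma_a, float))
        self.sigma_w = np.atleast_1d(np.asarray(self.sigma_w, float))

    def validate_for(self, spec: ModelSpec, design: DesignMatrices) -> None:
        if len(self.beta) != design.n_coef:
            raise ConfigurationError(
                f"beta has {len(self.beta)} entries; design has {design.n_coef} columns"
            )
        if len(self.a) != design.n_individuals:
            raise ConfigurationError("random-intercept vector does not match individual count")
        if len(self.sigma_a) != spec.n_sigma_a or len(self.sigma_w) != spec.n_sigma_w:
            raise ConfigurationError(
                f"sigma lengths {(len(self.sigma_a), len(self.sigma_w))} do not match "
                f"{spec.model_id} ({spec.n_sigma_a}, {spec.n_sigma_w})"
            )

    def to_json(self) -> str:
        return json.dumps({k: np.asarray(v).tolist() for k, v in vars(self).items()})

    @classmethod
    def from_json(cls, s: str) -> "Parameters":
        d = json.loads(s)
        return cls(**{k: np.asarray(v, float) for k, v in d.items()})


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative prior settings (defaults mirror common practice
    for standardized responses)."""

    beta_scale: float = 5.0
    sd_df: float = 3.0
    sd_scale: float = 2.5

    def __post_init__(self):
        if not (self.beta_scale > 0 and self.sd_scale > 0):
            raise ConfigurationError("prior scales must be > 0")
        if not self.sd_df >= 1:
            raise ConfigurationError("half-t degrees of freedom must be >= 1")

    def to_json(self) -> str:
        return json.dumps(
            {"beta_scale": self.beta_scale, "sd_df": self.sd_df, "sd_scale": self.sd_scale}
        )

    @classmethod
    def from_json(cls, s: str) -> "PriorConfig":
        return cls(**json.loads(s))


def _sigma_per(values: np.ndarray, group_index: np.ndarray) -> np.ndarray:
    """Expand a (1,) or (4,) sigma vector to one value per element of group_index."""
    values = np.atleast_1d(values)
    if len(values) == 1:
        return np.full(len(group_index), values[0])
    return values[group_index]


def log_likelihood_pointwise(
    params: Parameters, design: DesignMatrices, y: np.ndarray | None = None
) -> np.ndarray:
    """Per-observation Gaussian log-density, conditional on the random intercepts."""
    y = design.y if y is None else np.asarray(y, float)
    if np.any(params.sigma_w <= 0):
        raise ValueError("sigma_w must be strictly positive")
    mu = design.X @ params.beta
    if design.n_individuals:
        mu = mu + params.a[design.individual_index]
    sd = _sigma_per(params.sigma_w, design.group_of_obs)
    r = (y - mu) / sd
    return -0.5 * _LOG_2PI - np.log(sd) - 0.5 * r * r


def _half_t_logpdf(x: np.ndarray, df: float, scale: float) -> np.ndarray:
    return np.log(2.0) + stats.t.logpdf(x / scale, df) - np.log(scale)


def log_prior(params: Parameters, prior: PriorConfig, spec: ModelSpec,
              design: DesignMatrices | None = None) -> float:
    """Joint log prior density.

    Returns ``-inf`` (rather than raising) when any SD is non-positive, so
    samplers may propose invalid states safely. The random intercepts
    contribute Normal(0, sigma_A[g_i]) terms, which requires the design's
    individual-to-group map when the model has group-specific sigma_A.
    """
    if np.any(params.sigma_a <= 0) or np.any(params.sigma_w <= 0):
        return float("-inf")
    lp = float(np.sum(stats.norm.logpdf(params.beta, scale=prior.beta_scale)))
    lp += float(np.sum(_half_t_logpdf(params.sigma_a, prior.sd_df, prior.sd_scale)))
    lp += float(np.sum(_half_t_logpdf(params.sigma_w, prior.sd_df, prior.sd_scale)))
    if len(params.a):
        if len(params.sigma_a) > 1:
            if design is None:
                raise ConfigurationError(
                    "group-specific sigma_a needs design= to map individuals to groups"
                )
            sd_a = params.sigma_a[design.group_of_individual]
        else:
            sd_a = params.sigma_a[0]
        lp += float(np.sum(stats.norm.logpdf(params.a, scale=sd_a)))
    return lp


def simulate_responses(params: Parameters, design: DesignMatrices, seed) -> np.ndarray:
    """Draw a response vector from the conditional model y = X beta + Z a + e."""
    rng = np.random.default_rng(seed)
    mu = design.X @ params.beta
    if design.n_individuals:
        mu = mu + params.a[design.individual_index]
    sd = _sigma_per(params.sigma_w, design.group_of_obs)
    return mu + rng.normal(0.0, 1.0, size=design.n_obs) * sd


def marginal_loglik(params: Parameters, design: DesignMatrices, y: np.ndarray | None = None) -> float:
    """Log-likelihood with the random intercepts integrated out analytically.

    For each individual the observations are jointly Gaussian with covariance
    sigma_W^2 I + sigma_A^2 J; used only as an oracle for cross-checking the
    conditional likelihood via Monte-Carlo marginalization.
    """
    y = design.y if y is None else np.asarray(y, float)
    mu = design.X @ params.beta
    r = y - mu
    sd_w = _sigma_per(params.sigma_w, design.group_of_obs)
    total = 0.0
    for i in range(design.n_individuals):
        idx = np.nonzero(design.individual_index == i)[0]
        g = design.group_of_individual[i]
        s_a = params.sigma_a[0] if len(params.sigma_a) == 1 else params.sigma_a[g]
        cov = np.diag(sd_w[idx] ** 2) + s_a**2
        total += float(stats.multivariate_normal.logpdf(r[idx], mean=np.zeros(len(idx)), cov=cov))
    return total
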