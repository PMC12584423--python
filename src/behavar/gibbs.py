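"""Posterior sampling by conjugate Gibbs, with convergence diagnostics.

The model is fully conjugate once the half-Student-t priors on the SDs are
written as an inverse-gamma scale mixture (sigma^2 | psi ~ InvGamma(nu/2,
nu/psi), psi ~ InvGamma(1/2, 1/scale^2) gives sigma ~ half-t(nu, scale)), so
the sampler alternates exact block updates:

1. (beta, a) jointly from their multivariate-normal full conditional given
   all SDs;
2. each within-individual variance sigma_W[g]^2 from an inverse gamma given
   the residuals of its group, then its mixing scale psi;
3. each among-individual variance sigma_A[g]^2 from an inverse gamma given
   the random intercepts of its group, then its psi.

No Metropolis step, no tuning; chains are valid from the first iteration and
warmup is discarded purely to forget the initial state. Per-chain RNG
streams are spawned deterministically from the master seed, so runs are
bit-reproducible.

With an empty response vector every full conditional reduces to the prior,
so the sampler then draws from the prior — a useful end-to-end check.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from .design import DesignMatrices, ModelSpec
from .exceptions import ConfigurationError, RankDeficiencyError, SamplerError
from .likelihood import PriorConfig, _LOG_2PI

__all__ = ["MCMCConfig", "PosteriorSamples", "fit_mcmc", "check_convergence", "ConvergenceReport"]


@dataclass(frozen=True)
class MCMCConfig:
    """Chain settings. Total retained draws = n_chains * n_samples / thin."""

    n_chains: int = 4
    n_warmup: int = 1000
    n_samples: int = 2000
    seed: int = 0
    thin: int = 1
    compute_diagnostics: bool = True
    #: skip the pointwise log-likelihood matrix (large for long runs); WAIC/LOO
    #: need it, pure parameter inference does not
    store_loglik: bool = True

    def __post_init__(self):
        if min(self.n_chains, self.n_warmup + 1, self.n_samples, self.thin) < 1:
            raise ConfigurationError("chain settings must be positive")
        if self.n_samples % self.thin:
            raise ConfigurationError("n_samples must be divisible by thin")

    @property
    def n_retained(self) -> int:
        return self.n_samples // self.thin

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PosteriorSamples:
    """Retained MCMC draws plus the pointwise conditional log-likelihoods.

    ``draws`` maps parameter name -> array of shape (chain, draw, dim):
    ``beta`` (p), ``a`` (m), ``sigma_a`` (1 or 4), ``sigma_w`` (1 or 4).
    ``loglik_matrix`` has one row per retained draw (chains stacked) and one
    column per observation.
    """

    draws: dict[str, np.ndarray]
    loglik_matrix: np.ndarray
    diagnostics: pd.DataFrame
    spec: ModelSpec
    config: MCMCConfig
    prior: PriorConfig
    coef_names: list[str]
    group_labels: tuple[str, ...]
    individual_ids: list[str]

    @property
    def n_draws(self) -> int:
        return self.loglik_matrix.shape[0]

    @property
    def n_obs(self) -> int:
        return self.loglik_matrix.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one parameter with chains stacked: (n_draws, dim)."""
        d = self.draws[name]
        return d.reshape(-1, d.shape[-1])

    def sigma_for_group(self, which: str, group: int) -> np.ndarray:
        """Stacked draws of sigma_a/sigma_w for one group (shared draws when
        the component does not vary by group)."""
        d = self.stacked(which)
        return d[:, 0] if d.shape[1] == 1 else d[:, group]

    def loglik_chains(self) -> np.ndarray:
        """Log-likelihood reshaped to (chain, draw, obs)."""
        c = self.config.n_chains
        return self.loglik_matrix.reshape(c, -1, self.loglik_matrix.shape[1])

    # -- persistence (plain-text columnar layout + JSON manifest) -------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        frames = {}
        for name, arr in self.draws.items():
            c, s, k = arr.shape
            cols = self._labels(name, k)
            df = pd.DataFrame(arr.reshape(c * s, k), columns=cols)
            df.insert(0, "chain", np.repeat(np.arange(c), s))
            df.insert(1, "draw", np.tile(np.arange(s), c))
            frames[name] = df
        draws = pd.concat(
            [frames[n].drop(columns=["chain", "draw"]) if i else frames[n]
             for i, n in enumerate(frames)],
            axis=1,
        )
        draws.to_csv(directory / "draws.csv", index=False)
        pd.DataFrame(self.loglik_matrix).to_csv(directory / "loglik.csv", index=False)
        manifest = {
            "spec": json.loads(self.spec.to_json()),
            "config": self.config.to_dict(),
            "prior": json.loads(self.prior.to_json()),
            "coef_names": self.coef_names,
            "group_labels": list(self.group_labels),
            "individual_ids": list(self.individual_ids),
            "diagnostics": self.diagnostics.to_dict(orient="list"),
            "shapes": {k: list(v.shape) for k, v in self.draws.items()},
        }
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    def _labels(self, name: str, k: int) -> list[str]:
        if name == "beta":
            return [f"beta[{c}]" for c in self.coef_names]
        if name == "a":
            return [f"a[{i}]" for i in self.individual_ids]
        labels = self.group_labels if k == 4 else ["shared"]
        return [f"{name}[{g}]" for g in labels]

    @classmethod
    def load(cls, directory) -> "PosteriorSamples":
        directory = Path(directory)
        with open(directory / "manifest.json") as fh:
            manifest = json.load(fh)
        spec = ModelSpec.from_json(json.dumps(manifest["spec"]))
        config = MCMCConfig(**manifest["config"])
        prior = PriorConfig(**manifest["prior"])
        table = pd.read_csv(directory / "draws.csv")
        draws = {}
        start = 2  # skip chain, draw columns
        for name, shape in manifest["shapes"].items():
            k = shape[2]
            block = table.iloc[:, start : start + k].to_numpy()
            draws[name] = block.reshape(shape)
            start += k
        loglik = pd.read_csv(directory / "loglik.csv").to_numpy()
        return cls(
            draws=draws,
            loglik_matrix=loglik,
            diagnostics=pd.DataFrame(manifest["diagnostics"]),
            spec=spec,
            config=config,
            prior=prior,
            coef_names=manifest["coef_names"],
            group_labels=tuple(manifest["group_labels"]),
            individual_ids=manifest["individual_ids"],
        )


def _inv_gamma(rng: np.random.Generator, shape: float, scale: float) -> float:
    """One draw from InvGamma(shape, scale) (density ∝ x^-(shape+1) e^(-scale/x))."""
    return scale / rng.gamma(shape)


def _group_slices(group_of: np.ndarray, n_groups: int, varies: bool):
    """Observation/individual index sets per variance group (one pooled set
    when the component is shared)."""
    if not varies:
        return [np.arange(len(group_of))]
    return [np.nonzero(group_of == g)[0] for g in range(n_groups)]


def fit_mcmc(
    y: np.ndarray | None,
    design: DesignMatrices,
    spec: ModelSpec,
    prior: PriorConfig | None = None,
    config: MCMCConfig | None = None,
    fixed: dict[str, np.ndarray] | None = None,
) -> PosteriorSamples:
    """Sample the posterior of one candidate model by conjugate Gibbs.

    Parameters
    ----------
    y
        Response vector; defaults to ``design.y``. May be empty, in which
        case the sampler reproduces the prior.
    fixed
        Optional dict freezing ``"sigma_a"`` and/or ``"sigma_w"`` at given
        values (skips their updates); used for conjugate closed-form checks.

    Returns
    -------
    PosteriorSamples with draws, the pointwise conditional log-likelihood
    matrix, and per-parameter split R-hat / bulk ESS diagnostics. A warning
    is raised when any R-hat exceeds 1.01 or any bulk ESS falls below 400.
    """
    prior = prior or PriorConfig()
    config = config or MCMCConfig()
    fixed = fixed or {}
    y = design.y if y is None else np.asarray(y, float)
    n = len(y)
    p, m = design.n_coef, design.n_individuals
    if n and n != design.n_obs:
        raise ConfigurationError("response length does not match design")
    if n and n < p + 2:
        raise ConfigurationError(f"need at least p+2={p + 2} observations, got {n}")
    if n and np.linalg.matrix_rank(design.X) < p:
        raise RankDeficiencyError("fixed-effect design is rank deficient; cannot sample")

    n_groups = len(design.group_labels)
    kA, kW = spec.n_sigma_a, spec.n_sigma_w
    W = np.hstack([design.X, design.Z]) if n else np.zeros((0, p + m))

    obs_sets = _group_slices(design.group_of_obs[:n], n_groups, spec.vw_by_group)
    ind_sets = _group_slices(design.group_of_individual, n_groups, spec.va_by_group)
    # per sigma_W-group sufficient statistics (constant across iterations)
    WtW = [W[idx].T @ W[idx] for idx in obs_sets]
    Wty = [W[idx].T @ y[idx] for idx in obs_sets]
    n_w = np.array([len(idx) for idx in obs_sets], float)
    m_a = np.array([len(idx) for idx in ind_sets], float)

    nu, A = prior.sd_df, prior.sd_scale
    total_iter = config.n_warmup + config.n_samples
    keep = config.n_retained
    ss = np.random.SeedSequence(config.seed)
    chain_rngs = [np.random.default_rng(s) for s in ss.spawn(config.n_chains)]

    out = {
        "beta": np.empty((config.n_chains, keep, p)),
        "a": np.empty((config.n_chains, keep, m)),
        "sigma_a": np.empty((config.n_chains, keep, kA)),
        "sigma_w": np.empty((config.n_chains, keep, kW)),
    }
    n_ll = n if config.store_loglik else 0
    loglik = np.empty((config.n_chains, keep, n_ll))
    sd_obs_index = design.group_of_obs[:n] if spec.vw_by_group else np.zeros(n, int)

    for c, rng in enumerate(chain_rngs):
        # overdispersed but bounded initial SDs
        sig_w = np.clip(np.abs(rng.standard_t(nu, kW)) * A, 0.1, 10.0)
        sig_a = np.clip(np.abs(rng.standard_t(nu, kA)) * A, 0.1, 10.0)
        if "sigma_w" in fixed:
            sig_w = np.atleast_1d(np.asarray(fixed["sigma_w"], float)).copy()
        if "sigma_a" in fixed:
            sig_a = np.atleast_1d(np.asarray(fixed["sigma_a"], float)).copy()
        psi_w = np.ones(kW)
        psi_a = np.ones(kA)
        theta = np.zeros(p + m)
        kept = 0
        for it in range(total_iter):
            # --- (beta, a) joint Gaussian block ---
            lam = 1.0 / sig_w**2
            Q = sum(lam[g] * WtW[g] for g in range(kW)) if n else np.zeros((p + m, p + m))
            b = sum(lam[g] * Wty[g] for g in range(kW)) if n else np.zeros(p + m)
            prior_prec = np.empty(p + m)
            prior_prec[:p] = 1.0 / prior.beta_scale**2
            if m:
                sd_a_ind = sig_a[design.group_of_individual] if kA == 4 else sig_a[0]
                prior_prec[p:] = 1.0 / np.square(sd_a_ind)
            Q = Q + np.diag(prior_prec) if n else np.diag(prior_prec)
            try:
                L = linalg.cholesky(Q, lower=True)
            except linalg.LinAlgError as err:
                raise SamplerError(
                    "location block precision is not positive definite",
                    state={"chain": c, "iteration": it, "sigma_w": sig_w.tolist(),
                           "sigma_a": sig_a.tolist(), "error": str(err)},
                ) from err
            mean = linalg.cho_solve((L, True), b)
            z = rng.standard_normal(p + m)
            theta = mean + linalg.solve_triangular(L.T, z, lower=False)
            beta, a = theta[:p], theta[p:]

            # --- sigma_W blocks (inverse-gamma given residuals, then psi) ---
            if "sigma_w" not in fixed:
                resid = y - W @ theta if n else np.zeros(0)
                for g in range(kW):
                    rss = float(np.sum(resid[obs_sets[g]] ** 2)) if n else 0.0
                    var = _inv_gamma(rng, (nu + n_w[g] if n else nu) / 2.0,
                                     nu / psi_w[g] + rss / 2.0)
                    sig_w[g] = np.sqrt(var)
                    psi_w[g] = _inv_gamma(rng, (nu + 1) / 2.0, nu / var + 1.0 / A**2)

            # --- sigma_A blocks (given random intercepts) ---
            if "sigma_a" not in fixed:
                for g in range(kA):
                    ssa = float(np.sum(a[ind_sets[g]] ** 2)) if m else 0.0
                    var = _inv_gamma(rng, (nu + m_a[g]) / 2.0, nu / psi_a[g] + ssa / 2.0)
                    sig_a[g] = np.sqrt(var)
                    psi_a[g] = _inv_gamma(rng, (nu + 1) / 2.0, nu / var + 1.0 / A**2)

            if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(sig_w))
                    and np.all(np.isfinite(sig_a))):
                raise SamplerError(
                    "non-finite state encountered",
                    state={"chain": c, "iteration": it, "theta_max": float(np.max(np.abs(theta))),
                           "sigma_w": sig_w.tolist(), "sigma_a": sig_a.tolist()},
                )

            k = it - config.n_warmup
            if k >= 0 and (k + 1) % config.thin == 0:
                out["beta"][c, kept] = beta
                out["a"][c, kept] = a
                out["sigma_a"][c, kept] = sig_a
                out["sigma_w"][c, kept] = sig_w
                kept += 1

        # pointwise conditional log-likelihood for the retained draws
        if n and config.store_loglik:
            mu = out["beta"][c] @ design.X.T
            if m:
                mu = mu + out["a"][c][:, design.individual_index]
            sd = out["sigma_w"][c][:, sd_obs_index]
            r = (y[None, :] - mu) / sd
            loglik[c] = -0.5 * _LOG_2PI - np.log(sd) - 0.5 * r * r

    diag = pd.DataFrame(columns=["parameter", "rhat", "ess_bulk"])
    if config.compute_diagnostics:
        report = _diagnose(out, _param_labels(out, design))
        diag = report
        bad = report[(report["rhat"] > 1.01) | (report["ess_bulk"] < 400)]
        if len(bad) and config.n_chains > 1:
            worst = bad.sort_values("rhat", ascending=False).iloc[0]
            warnings.warn(
                f"{len(bad)} parameter(s) fail diagnostics thresholds "
                f"(worst: {worst['parameter']} rhat={worst['rhat']:.3f} "
                f"ess={worst['ess_bulk']:.0f})",
                RuntimeWarning,
                stacklevel=2,
            )

    return PosteriorSamples(
        draws=out,
        loglik_matrix=loglik.reshape(config.n_chains * keep, n_ll),
        diagnostics=diag,
        spec=spec,
        config=config,
        prior=prior,
        coef_names=design.coef_names,
        group_labels=design.group_labels,
        individual_ids=list(design.individual_ids),
    )


def _param_labels(draws: dict[str, np.ndarray], design: DesignMatrices) -> dict[str, list[str]]:
    labels = {
        "beta": [f"beta[{c}]" for c in design.coef_names],
        "a": [f"a[{i}]" for i in design.individual_ids],
    }
    for name in ("sigma_a", "sigma_w"):
        k = draws[name].shape[-1]
        tags = design.group_labels if k == 4 else ("shared",)
        labels[name] = [f"{name}[{t}]" for t in tags]
    return labels


def _diagnose(draws: dict[str, np.ndarray], labels: dict[str, list[str]]) -> pd.DataFrame:
    import arviz as az

    rows = []
    for name, arr in draws.items():
        for j in range(arr.shape[-1]):
            chains = arr[:, :, j]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rhat = float(az.rhat(chains)) if chains.shape[0] > 1 else float("nan")
                ess = float(az.ess(chains, method="bulk"))
            rows.append({"parameter": labels[name][j], "rhat": rhat, "ess_bulk": ess})
    return pd.DataFrame(rows)


@dataclass
class ConvergenceReport:
    table: pd.DataFrame
    rhat_max: float
    ess_min: float
    passed: bool
    messages: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        return (
            f"convergence {status} (thresholds: rhat <= {self.rhat_max}, "
            f"ess >= {self.ess_min})\n" + self.table.to_string(index=False)
        )


def check_convergence(
    samples: PosteriorSamples, rhat_max: float = 1.01, ess_min: float = 400.0
) -> ConvergenceReport:
    """Split R-hat and bulk ESS for every scalar parameter, with a pass flag.

    R-hat is unavailable for a single chain (a warning is issued and only the
    ESS threshold applies). Constant chains yield undefined R-hat and are
    flagged as failing. Never mutates the draws.
    """
    messages: list[str] = []
    labels = {
        "beta": [f"beta[{c}]" for c in samples.coef_names],
        "a": [f"a[{i}]" for i in samples.individual_ids],
        "sigma_a": [f"sigma_a[{t}]" for t in
                    (samples.group_labels if samples.draws["sigma_a"].shape[-1] == 4 else ("shared",))],
        "sigma_w": [f"sigma_w[{t}]" for t in
                    (samples.group_labels if samples.draws["sigma_w"].shape[-1] == 4 else ("shared",))],
    }
    table = _diagnose(samples.draws, labels)
    single_chain = samples.config.n_chains < 2
    if single_chain:
        messages.append("single chain: split R-hat unavailable; only ESS checked")
        warnings.warn(messages[-1], RuntimeWarning, stacklevel=2)
        rhat_ok = True
    else:
        degenerate = table["rhat"].isna()
        if degenerate.any():
            messages.append(
                f"undefined R-hat (zero-variance chains) for: "
                f"{table.loc[degenerate, 'parameter'].tolist()}"
            )
        rhat_ok = bool((table["rhat"] <= rhat_max).all()) and not degenerate.any()
    ess_ok = bool((table["ess_bulk"] >= ess_min).all())
    return ConvergenceReport(
        table=table, rhat_max=rhat_max, ess_min=ess_min,
        passed=rhat_ok and ess_ok, messages=messages,
    )
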