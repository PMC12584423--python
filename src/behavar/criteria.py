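"""WAIC and PSIS-LOO model comparison from pointwise log-likelihoods.

Both criteria estimate the expected log pointwise predictive density (elpd)
of a fitted model from the (n_draws x n_obs) matrix of conditional
log-likelihoods. WAIC is computed directly from its two pointwise formulas
(log-mean-exp predictive density minus the per-observation variance penalty,
the p_waic2 form). PSIS-LOO smooths the per-observation importance weights
with a generalized-Pareto tail fit (via arviz's reference implementation of
Pareto-smoothed importance sampling) and reports the per-observation shape
diagnostic pareto_k; values above 0.7 make that observation's contribution
unreliable and trigger a warning.

Model selection picks the maximal elpd, breaking near-ties (|diff| below
half its standard error) in favour of the simpler model in the parsimony
order M1 < M2 < M3 < M4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .exceptions import AlignmentError, ConfigurationError
from .gibbs import PosteriorSamples

__all__ = ["InformationCriterion", "ModelRanking", "waic", "psis_loo", "select_model",
           "compare_models", "ComparisonResult"]

#: parsimony order used to break near-ties
PARSIMONY_ORDER = ("M1", "M2", "M3", "M4")


@dataclass
class InformationCriterion:
    """One model's predictive-fit estimate on the elpd and deviance scales."""

    method: str  # "waic" | "loo"
    elpd: float
    penalty: float
    se: float
    pointwise: np.ndarray  # per-observation elpd contributions
    pareto_k: np.ndarray | None = None  # LOO only

    @property
    def ic_value(self) -> float:
        """Deviance-scale value, -2 * elpd."""
        return -2.0 * self.elpd

    @property
    def n_obs(self) -> int:
        return len(self.pointwise)


def _validate_loglik(loglik: np.ndarray, min_draws: int) -> np.ndarray:
    ll = np.asarray(loglik, float)
    if ll.ndim != 2:
        raise ConfigurationError("log-likelihood matrix must be 2-D (draws x observations)")
    if ll.shape[0] < min_draws:
        raise ConfigurationError(f"need at least {min_draws} draws, got {ll.shape[0]}")
    if np.any(np.isnan(ll)) or np.any(ll == np.inf):
        raise ConfigurationError("log-likelihood matrix contains NaN or +inf")
    dead = np.all(np.isneginf(ll), axis=0)
    if dead.any():
        raise ConfigurationError(
            f"observations {np.nonzero(dead)[0].tolist()} have zero likelihood in every draw"
        )
    return ll


def waic(loglik_matrix: np.ndarray) -> InformationCriterion:
    """Widely applicable information criterion from an (S x n) log-likelihood
    matrix.

    Pointwise: lppd_k = log(mean_s exp ll_sk) (stabilized); p_k = var_s(ll_sk)
    with the n-1 convention; elpd_k = lppd_k - p_k. The standard error is
    sqrt(n * var_k(elpd_k)).
    """
    ll = _validate_loglik(loglik_matrix, min_draws=2)
    S, n = ll.shape
    lppd = logsumexp(ll, axis=0) - np.log(S)
    p_waic = np.var(ll, axis=0, ddof=1)
    pointwise = lppd - p_waic
    se = float(np.sqrt(n * np.var(pointwise, ddof=1))) if n > 1 else 0.0
    return InformationCriterion(
        method="waic",
        elpd=float(np.sum(pointwise)),
        penalty=float(np.sum(p_waic)),
        se=se,
        pointwise=pointwise,
    )


def psis_loo(loglik_matrix: np.ndarray, seed: int | None = None,
             n_chains: int = 1) -> InformationCriterion:
    """Pareto-smoothed importance-sampling approximation to exact
    leave-one-out cross-validation.

    ``seed`` is accepted for interface uniformity; the computation is
    deterministic. ``n_chains`` (the matrix rows are chains stacked in order)
    feeds the relative-efficiency correction of the tail fit.
    """
    import arviz as az

    ll = _validate_loglik(loglik_matrix, min_draws=2)
    S, n = ll.shape
    if S < 100:
        warnings.warn(
            f"PSIS-LOO with only {S} draws is unreliable (>=100 recommended)",
            RuntimeWarning,
            stacklevel=2,
        )
    if S % n_chains:
        raise ConfigurationError("draw count not divisible by n_chains")
    chains = ll.reshape(n_chains, S // n_chains, n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if n_chains > 1:
            # relative MCMC efficiency from the log-likelihood draws themselves
            ess = az.ess(az.convert_to_dataset(chains), method="mean")
            reff = float(np.asarray(ess.to_array()).mean()) / S
        else:
            reff = 1.0
        idata = az.from_dict(log_likelihood={"y": chains})
        result = az.loo(idata, pointwise=True, reff=reff)
    pointwise = np.asarray(result.loo_i.values, float)
    pareto_k = np.asarray(result.pareto_k.values, float)
    # a constant log-likelihood column has zero weight variance: its LOO
    # contribution is exact and the tail diagnostic is vacuously benign
    constant = np.var(ll, axis=0, ddof=1) < 1e-12
    pareto_k[constant] = 0.0
    if not np.all(np.isfinite(pointwise)):
        bad = np.nonzero(~np.isfinite(pointwise))[0].tolist()
        raise ConfigurationError(f"non-finite smoothed weights for observations {bad}")
    high = pareto_k > 0.7
    if high.any():
        warnings.warn(
            f"{int(high.sum())} observation(s) with pareto_k > 0.7; "
            "their LOO contributions are unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    return InformationCriterion(
        method="loo",
        elpd=float(result.elpd_loo),
        penalty=float(result.p_loo),
        se=float(result.se),
        pointwise=pointwise,
        pareto_k=pareto_k,
    )


@dataclass
class ModelRanking:
    """Per-model criteria with differences against the best model."""

    criterion: str
    table: pd.DataFrame  # model, elpd, penalty, ic_value, se, elpd_diff, diff_se
    selected_model: str

    def __str__(self) -> str:
        return (
            f"{self.criterion.upper()} ranking (selected: {self.selected_model})\n"
            + self.table.to_string(index=False, float_format=lambda v: f"{v:.2f}")
        )


def _parsimony_rank(model_id: str) -> int:
    try:
        return PARSIMONY_ORDER.index(model_id)
    except ValueError:
        return len(PARSIMONY_ORDER)


def select_model(
    criteria: dict[str, InformationCriterion], rule: str = "elpd"
) -> ModelRanking:
    """Rank models by elpd and pick the winner.

    All criteria must be computed on the same observations. A model whose
    elpd deficit against the best is smaller than half the paired standard
    error of the difference is treated as tied, and ties go to the simplest
    model in the order M1 < M2 < M3 < M4.
    """
    if len(criteria) < 2:
        raise ConfigurationError("need at least two models to compare")
    n_set = {ic.n_obs for ic in criteria.values()}
    if len(n_set) != 1:
        raise AlignmentError(f"models were fitted to different observation sets (n = {sorted(n_set)})")
    n = n_set.pop()
    method = {ic.method for ic in criteria.values()}
    label = method.pop() if len(method) == 1 else rule

    best_id = max(criteria, key=lambda mid: criteria[mid].elpd)
    best = criteria[best_id]
    rows = []
    contenders = []
    for mid, ic in criteria.items():
        diff = best.elpd - ic.elpd
        if mid == best_id:
            diff_se = 0.0
        else:
            d = best.pointwise - ic.pointwise
            diff_se = float(np.sqrt(n * np.var(d, ddof=1))) if n > 1 else 0.0
        rows.append(
            {"model": mid, "elpd": ic.elpd, "penalty": ic.penalty,
             "ic_value": ic.ic_value, "se": ic.se, "elpd_diff": -diff, "diff_se": diff_se}
        )
        if diff <= 0.5 * diff_se or mid == best_id:
            contenders.append(mid)
    selected = min(contenders, key=_parsimony_rank)
    table = pd.DataFrame(rows).sort_values("elpd", ascending=False).reset_index(drop=True)
    return ModelRanking(criterion=label, table=table, selected_model=selected)


@dataclass
class ComparisonResult:
    """WAIC- and LOO-based rankings for one trait, with disagreement flag."""

    waic_ranking: ModelRanking
    loo_ranking: ModelRanking
    agree: bool = field(init=False)

    def __post_init__(self):
        self.agree = self.waic_ranking.selected_model == self.loo_ranking.selected_model

    @property
    def selected_model(self) -> str:
        """The LOO choice when the criteria disagree (LOO is the more robust
        of the two); identical to the WAIC choice otherwise."""
        return self.loo_ranking.selected_model

    def to_frame(self) -> pd.DataFrame:
        w = self.waic_ranking.table.assign(criterion="waic")
        l = self.loo_ranking.table.assign(criterion="loo")
        return pd.concat([w, l], ignore_index=True)

    def __str__(self) -> str:
        note = "" if self.agree else "\nNOTE: WAIC and LOO select different models."
        return f"{self.waic_ranking}\n\n{self.loo_ranking}{note}"


def compare_models(samples_by_model: dict[str, PosteriorSamples]) -> ComparisonResult:
    """Compute both criteria for every fitted model and rank them."""
    waics, loos = {}, {}
    for mid, s in samples_by_model.items():
        waics[mid] = waic(s.loglik_matrix)
        loos[mid] = psis_loo(s.loglik_matrix, n_chains=s.config.n_chains)
    result = ComparisonResult(
        waic_ranking=select_model(waics),
        loo_ranking=select_model(loos),
    )
    if not result.agree:
        warnings.warn(
            f"WAIC selects {result.waic_ranking.selected_model} but LOO selects "
            f"{result.loo_ranking.selected_model}",
            RuntimeWarning,
            stacklevel=2,
        )
    return result
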