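"""Posterior summaries: fixed-effect contrasts, variance components,
repeatability, and pairwise group contrast tables.

Every quantity is computed *draw-wise* — V_A = sigma_A^2, V_W = sigma_W^2 and
R = V_A / (V_A + V_W) are evaluated per retained MCMC draw, and group
contrasts are per-iteration differences of paired draws — then summarized by
the posterior mean and equal-tailed quantile intervals. Summarizing first
and differencing afterwards would give the same means but wrong intervals,
because the group posteriors are correlated through shared parameters.

A contrast is flagged "substantial" when its equal-tailed 95% credible
interval excludes zero. Repeatability contrasts can additionally be marked
NA when a group's among-individual variance is indistinguishable from zero
(R is then not meaningfully defined); the raw value is retained alongside
the flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignMatrices
from .exceptions import AlignmentError, ConfigurationError
from .gibbs import PosteriorSamples

__all__ = [
    "repeatability",
    "VarianceSummary",
    "ContrastTable",
    "fixed_effect_summary",
    "variance_components",
    "contrast_table",
    "group_mean_contrasts",
    "format_contrast_grid",
]

_QUANTILES = (0.025, 0.25, 0.75, 0.975)
_QLABELS = ("q2.5", "q25", "q75", "q97.5")


def repeatability(va, vw):
    """Repeatability R = V_A / (V_A + V_W), the fraction of phenotypic
    variance due to consistent among-individual differences.

    Accepts scalars or draw arrays (element-wise). Both variances must be
    nonnegative and cannot both be zero.
    """
    va = np.asarray(va, float)
    vw = np.asarray(vw, float)
    if np.any(va < 0) or np.any(vw < 0):
        raise ValueError("variance components must be nonnegative")
    total = va + vw
    if np.any(total == 0):
        raise ZeroDivisionError("repeatability undefined when V_A + V_W = 0")
    r = va / total
    return float(r) if r.ndim == 0 else r


def _summary_row(draws: np.ndarray) -> dict:
    qs = np.quantile(draws, _QUANTILES)
    return {"mean": float(np.mean(draws)), **{l: float(q) for l, q in zip(_QLABELS, qs)}}


@dataclass
class VarianceSummary:
    """Posterior of (V_A, V_W, R) for one population-by-sex group."""

    group: str
    va_draws: np.ndarray
    vw_draws: np.ndarray
    r_draws: np.ndarray = field(init=False)
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self):
        if len(self.va_draws) != len(self.vw_draws):
            raise AlignmentError("V_A and V_W draw counts differ")
        self.r_draws = repeatability(self.va_draws, self.vw_draws)
        self.summary = pd.DataFrame(
            [_summary_row(d) for d in (self.va_draws, self.vw_draws, self.r_draws)],
            index=pd.Index(["va", "vw", "r"], name="quantity"),
        )

    def draws(self, quantity: str) -> np.ndarray:
        return {"va": self.va_draws, "vw": self.vw_draws, "r": self.r_draws}[quantity]


def variance_components(samples: PosteriorSamples) -> list[VarianceSummary]:
    """Per-group posterior of V_A, V_W and R from a fitted model.

    For model specs with a shared component, every group receives the
    *same* draws for that component, so all pairwise contrasts of it are
    exactly zero — the structural statement that the groups do not differ.
    """
    out = []
    for g, label in enumerate(samples.group_labels):
        sa = samples.sigma_for_group("sigma_a", g)
        sw = samples.sigma_for_group("sigma_w", g)
        out.append(VarianceSummary(group=label, va_draws=sa**2, vw_draws=sw**2))
    return out


def fixed_effect_summary(
    samples: PosteriorSamples,
    terms: tuple[str, ...] = ("population", "sex", "population:sex"),
) -> pd.DataFrame:
    """Posterior mean and equal-tailed 95% CI of fixed-effect coefficients
    (standardized-trait scale), one row per coefficient of the requested
    terms."""
    beta = samples.stacked("beta")
    rows = []
    for term in terms:
        cols = [
            j
            for j, name in enumerate(samples.coef_names)
            if _coef_term(name) == term
        ]
        if not cols:
            raise ConfigurationError(f"term {term!r} has no coefficient in the fitted model")
        for j in cols:
            d = beta[:, j]
            lo, hi = np.quantile(d, (0.025, 0.975))
            rows.append(
                {"term": term, "coefficient": samples.coef_names[j],
                 "mean": float(np.mean(d)), "lower95": float(lo), "upper95": float(hi)}
            )
    return pd.DataFrame(rows)


def _coef_term(name: str) -> str:
    if ":" in name:
        return ":".join(part.split("[")[0] for part in name.split(":"))
    return name.split("[")[0]


@dataclass
class ContrastTable:
    """Pairwise group differences of one quantity, draw-aligned.

    Matrix entries follow the convention entry(row, col) = value(row group)
    - value(col group); antisymmetry and a zero diagonal hold exactly.
    ``substantial`` is True iff the 95% CI excludes 0. ``na_flag`` marks
    entries whose value is reported but not meaningfully defined (the raw
    numbers stay in ``mean``/``lower``/``upper``).
    """

    quantity: str
    groups: tuple[str, ...]
    mean: pd.DataFrame
    lower: pd.DataFrame
    upper: pd.DataFrame
    substantial: pd.DataFrame
    na_flag: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = []
        for r in self.groups:
            for c in self.groups:
                if r == c:
                    continue
                rows.append(
                    {"quantity": self.quantity, "row": r, "col": c,
                     "mean": self.mean.loc[r, c], "lower95": self.lower.loc[r, c],
                     "upper95": self.upper.loc[r, c],
                     "substantial": bool(self.substantial.loc[r, c]),
                     "na": bool(self.na_flag.loc[r, c])}
                )
        return pd.DataFrame(rows)

    def entry(self, row: str, col: str) -> dict:
        return {
            "mean": float(self.mean.loc[row, col]),
            "lower95": float(self.lower.loc[row, col]),
            "upper95": float(self.upper.loc[row, col]),
            "substantial": bool(self.substantial.loc[row, col]),
            "na": bool(self.na_flag.loc[row, col]),
        }


def _blank_grid(groups, value=0.0, dtype=float) -> pd.DataFrame:
    return pd.DataFrame(
        np.full((len(groups), len(groups)), value, dtype=dtype),
        index=list(groups), columns=list(groups),
    )


def contrast_table(
    summaries: list[VarianceSummary],
    quantity: str = "delta_vw",
    va_zero_tol: float = 0.0,
) -> ContrastTable:
    """Pairwise posterior contrasts of V_A, V_W or R between groups.

    Differences are taken per MCMC iteration (draw-aligned across groups)
    and then summarized by the mean and equal-tailed 95% interval. For
    ``delta_r``, entries involving a group whose V_A lower 2.5% bound is at
    or below ``va_zero_tol`` are NA-flagged: repeatability differences are
    not interpretable when among-individual variance is indistinguishable
    from zero.
    """
    if quantity not in ("delta_va", "delta_vw", "delta_r"):
        raise ConfigurationError(f"unknown contrast quantity {quantity!r}")
    if len(summaries) < 2:
        raise ConfigurationError("need at least two groups to contrast")
    key = quantity.removeprefix("delta_")
    counts = {len(s.draws(key)) for s in summaries}
    if len(counts) != 1:
        raise AlignmentError(f"groups have misaligned draw counts {sorted(counts)}")
    groups = tuple(s.group for s in summaries)
    by_group = {s.group: s for s in summaries}

    mean = _blank_grid(groups)
    lower = _blank_grid(groups)
    upper = _blank_grid(groups)
    substantial = _blank_grid(groups, False, bool)
    na = _blank_grid(groups, False, bool)

    va_undefined = {
        s.group: bool(np.quantile(s.va_draws, 0.025) <= va_zero_tol) for s in summaries
    }
    for i, gi in enumerate(groups):
        for j in range(i + 1, len(groups)):
            gj = groups[j]
            d = by_group[gi].draws(key) - by_group[gj].draws(key)
            mu = float(np.mean(d))
            lo, hi = (float(q) for q in np.quantile(d, (0.025, 0.975)))
            sub = not (lo <= 0.0 <= hi)
            mean.loc[gi, gj], mean.loc[gj, gi] = mu, -mu
            lower.loc[gi, gj], upper.loc[gi, gj] = lo, hi
            lower.loc[gj, gi], upper.loc[gj, gi] = -hi, -lo
            substantial.loc[gi, gj] = substantial.loc[gj, gi] = sub
            if quantity == "delta_r" and (va_undefined[gi] or va_undefined[gj]):
                na.loc[gi, gj] = na.loc[gj, gi] = True
    return ContrastTable(
        quantity=quantity, groups=groups, mean=mean, lower=lower, upper=upper,
        substantial=substantial, na_flag=na,
    )


def group_mean_contrasts(samples: PosteriorSamples, design: DesignMatrices) -> ContrastTable:
    """Pairwise differences in average trait level between groups.

    Each group's mean level is the fitted fixed-effect prediction averaged
    over that group's observed design rows (contexts average out in a
    balanced design); differences are taken per draw.
    """
    beta = samples.stacked("beta")
    groups = samples.group_labels
    level_draws = {}
    for g, label in enumerate(groups):
        rows = design.X[design.group_of_obs == g]
        if not len(rows):
            raise ConfigurationError(f"group {label} has no observations")
        level_draws[label] = beta @ rows.mean(axis=0)

    mean = _blank_grid(groups)
    lower = _blank_grid(groups)
    upper = _blank_grid(groups)
    substantial = _blank_grid(groups, False, bool)
    na = _blank_grid(groups, False, bool)
    for i, gi in enumerate(groups):
        for j in range(i + 1, len(groups)):
            gj = groups[j]
            d = level_draws[gi] - level_draws[gj]
            mu = float(np.mean(d))
            lo, hi = (float(q) for q in np.quantile(d, (0.025, 0.975)))
            mean.loc[gi, gj], mean.loc[gj, gi] = mu, -mu
            lower.loc[gi, gj], upper.loc[gi, gj] = lo, hi
            lower.loc[gj, gi], upper.loc[gj, gi] = -hi, -lo
            substantial.loc[gi, gj] = substantial.loc[gj, gi] = not (lo <= 0.0 <= hi)
    return ContrastTable(
        quantity="delta_fixed", groups=tuple(groups), mean=mean, lower=lower,
        upper=upper, substantial=substantial, na_flag=na,
    )


def format_contrast_grid(vw: ContrastTable, r: ContrastTable) -> pd.DataFrame:
    """Render the two contrast tables as one grid: Delta V_W above the
    diagonal, Delta R below, each cell "mean (lo, hi)" with '*' marking
    substantial entries and 'NA' replacing flagged repeatability cells."""
    if vw.groups != r.groups:
        raise AlignmentError("contrast tables cover different groups")
    groups = vw.groups
    grid = _blank_grid(groups, "", object)
    for i, gi in enumerate(groups):
        for j, gj in enumerate(groups):
            if i == j:
                grid.loc[gi, gj] = "-"
            elif i < j:
                grid.loc[gi, gj] = _cell(vw, gi, gj)
            else:
                grid.loc[gi, gj] = _cell(r, gi, gj)
    return grid


def _cell(table: ContrastTable, row: str, col: str) -> str:
    e = table.entry(row, col)
    if e["na"]:
        return "NA"
    star = "*" if e["substantial"] else ""
    return f"{e['mean']:.2f} ({e['lower95']:.2f}, {e['upper95']:.2f}){star}"
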