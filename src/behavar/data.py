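"""Reading, validation and preprocessing of long-format behavioral trial data.

The analysis operates on *trial tables*: one row per individual x context
trial, with the individual's population and sex attached to every row.
Individuals belong to exactly one population-by-sex group (e.g. ``PKF`` =
population PK, females); the group label is the deterministic concatenation
of the two factor labels and drives all group-specific variance modelling
downstream.

Preprocessing follows common practice for behavioral traits measured on
positive, skewed scales: an optional Yeo-Johnson power transform (parameter
chosen by maximum likelihood, with the option of exempting particular
contexts) followed by standardization of the whole trait column to sample
mean 0 and sample SD 1. Every preprocessing step is captured in a
:class:`PreprocessRecord` that can re-apply or exactly invert it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DegenerateDataError, ValidationError

__all__ = [
    "TrialTable",
    "PreprocessRecord",
    "read_trials",
    "standardize_trait",
    "gaussianize_trait",
    "preprocess_trait",
]

#: canonical column names of a trial table
COLUMNS = ("individual_id", "population", "sex", "context", "trait_name", "value")

#: default context labels, in testing order (first level is the design baseline)
DEFAULT_CONTEXTS = ("novel_env", "familiar_env", "novel_object")


def _ordered_levels(series: pd.Series, preferred: tuple[str, ...] = ()) -> list:
    """Distinct levels of ``series``: preferred order when it covers them, else sorted."""
    levels = set(series.unique())
    if preferred and levels.issubset(set(preferred)):
        return [c for c in preferred if c in levels]
    return sorted(levels)


@dataclass
class TrialTable:
    """Validated long-format table of behavioral trials.

    Parameters
    ----------
    df
        DataFrame with columns ``individual_id, population, sex, context,
        trait_name, value``. A derived ``group`` column (population + sex
        concatenated) is added on construction.
    dropped_missing
        Number of rows removed because the trait value was missing
        (populated by :func:`read_trials`).
    """

    df: pd.DataFrame
    dropped_missing: int = 0

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"trial table is missing columns {missing}")
        df = self.df.copy()
        df["value"] = pd.to_numeric(df["value"])
        for c in ("individual_id", "population", "sex", "context", "trait_name"):
            df[c] = df[c].astype(str)
        df["group"] = df["population"] + df["sex"]
        self.df = df.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.df
        if not np.all(np.isfinite(df["value"].to_numpy(float))):
            raise ValidationError("trial table contains non-finite trait values")
        labels = df.groupby("individual_id")[["population", "sex"]].nunique()
        bad = labels[(labels > 1).any(axis=1)]
        if len(bad):
            raise ValidationError(
                f"individuals with conflicting population/sex labels: {list(bad.index)}"
            )
        dup = df.duplicated(subset=["individual_id", "context", "trait_name"])
        if dup.any():
            rows = df.loc[dup, ["individual_id", "context", "trait_name"]]
            raise ValidationError(
                f"duplicate (individual, context, trait) rows:\n{rows.to_string(index=False)}"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def traits(self) -> list[str]:
        return sorted(self.df["trait_name"].unique())

    @property
    def individuals(self) -> list[str]:
        return sorted(self.df["individual_id"].unique())

    @property
    def groups(self) -> list[str]:
        pops = _ordered_levels(self.df["population"])
        sexes = _ordered_levels(self.df["sex"])
        present = set(self.df["group"])
        return [p + s for p in pops for s in sexes if p + s in present]

    def context_levels(self) -> list[str]:
        return _ordered_levels(self.df["context"], DEFAULT_CONTEXTS)

    def subset_trait(self, trait: str) -> "TrialTable":
        if trait not in set(self.df["trait_name"]):
            raise ConfigurationError(f"trait {trait!r} not present in table")
        return TrialTable(self.df[self.df["trait_name"] == trait].drop(columns="group"))

    def with_values(self, trait: str, values: np.ndarray) -> "TrialTable":
        """Copy of the table with the value column of ``trait`` replaced."""
        df = self.df.drop(columns="group").copy()
        mask = (df["trait_name"] == trait).to_numpy()
        if mask.sum() != len(values):
            raise ValidationError("replacement values do not match trait row count")
        df.loc[mask, "value"] = np.asarray(values, float)
        return TrialTable(df, dropped_missing=self.dropped_missing)

    def values_for(self, trait: str) -> np.ndarray:
        mask = self.df["trait_name"] == trait
        if not mask.any():
            raise ConfigurationError(f"trait {trait!r} not present in table")
        return self.df.loc[mask, "value"].to_numpy(float)

    def to_csv(self, path) -> None:
        self.df.drop(columns="group").to_csv(path, index=False)


def read_trials(path, column_map: dict[str, str] | None = None) -> TrialTable:
    """Read a delimited text file into a validated :class:`TrialTable`.

    Parameters
    ----------
    path
        CSV file with a header row.
    column_map
        Mapping from canonical column names (``individual_id`` ...) to the
        file's column names. Omitted entries default to the canonical name.

    Rows with a missing trait value are dropped; their count is stored on
    the returned table as ``dropped_missing``.
    """
    column_map = dict(column_map or {})
    unknown = set(column_map) - set(COLUMNS)
    if unknown:
        raise ConfigurationError(f"column_map refers to unknown canonical columns {sorted(unknown)}")
    raw = pd.read_csv(path)
    rename = {}
    for canonical in COLUMNS:
        source = column_map.get(canonical, canonical)
        if source not in raw.columns:
            raise ConfigurationError(
                f"column {source!r} (for {canonical!r}) not found in {path}; "
                f"available: {list(raw.columns)}"
            )
        rename[source] = canonical
    df = raw.rename(columns=rename)[list(COLUMNS)]
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    n_missing = int(df["value"].isna().sum())
    df = df.dropna(subset=["value"])
    return TrialTable(df, dropped_missing=n_missing)


# -- preprocessing -------------------------------------------------------------


@dataclass
class PreprocessRecord:
    """Invertible record of the preprocessing applied to one trait column.

    ``transform`` is applied first (to rows whose context is not in
    ``excluded_contexts``), then the whole column is standardized with the
    stored mean/SD. ``apply`` reproduces the analysis column from raw
    values; ``invert`` recovers raw values exactly.
    """

    trait_name: str
    transform: str = "none"  # "none" | "yeo_johnson"
    transform_parameter: float = float("nan")
    standardize_mean: float = 0.0
    standardize_sd: float = 1.0
    excluded_contexts: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.transform not in ("none", "yeo_johnson"):
            raise ConfigurationError(f"unknown transform {self.transform!r}")
        if not self.standardize_sd > 0:
            raise ConfigurationError("standardize_sd must be > 0")
        self.excluded_contexts = tuple(self.excluded_contexts)

    def _transform_mask(self, contexts) -> np.ndarray:
        contexts = np.asarray(contexts, dtype=object)
        return ~np.isin(contexts, list(self.excluded_contexts))

    def apply(self, values: np.ndarray, contexts=None) -> np.ndarray:
        x = np.asarray(values, float).copy()
        if self.transform == "yeo_johnson":
            mask = (
                np.ones(len(x), bool) if contexts is None else self._transform_mask(contexts)
            )
            x[mask] = _yeo_johnson(x[mask], self.transform_parameter)
        return (x - self.standardize_mean) / self.standardize_sd

    def invert(self, values: np.ndarray, contexts=None) -> np.ndarray:
        x = np.asarray(values, float) * self.standardize_sd + self.standardize_mean
        if self.transform == "yeo_johnson":
            mask = (
                np.ones(len(x), bool) if contexts is None else self._transform_mask(contexts)
            )
            x[mask] = _yeo_johnson_inverse(x[mask], self.transform_parameter)
        return x

    def to_dict(self) -> dict:
        d = asdict(self)
        d["excluded_contexts"] = list(self.excluded_contexts)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessRecord":
        d = dict(d)
        d["excluded_contexts"] = tuple(d.get("excluded_contexts", ()))
        return cls(**d)


def _yeo_johnson(x: np.ndarray, lam: float) -> np.ndarray:
    """Yeo-Johnson power transform (monotone for every real lambda).

    Uses expm1/log1p forms, which stay accurate as lambda approaches the
    0 and 2 branch points."""
    out = np.empty_like(x, float)
    pos = x >= 0
    if abs(lam) > 1e-12:
        out[pos] = np.expm1(lam * np.log1p(x[pos])) / lam
    else:
        out[pos] = np.log1p(x[pos])
    if abs(lam - 2.0) > 1e-12:
        out[~pos] = -np.expm1((2.0 - lam) * np.log1p(-x[~pos])) / (2.0 - lam)
    else:
        out[~pos] = -np.log1p(-x[~pos])
    return out


def _yeo_johnson_inverse(y: np.ndarray, lam: float) -> np.ndarray:
    out = np.empty_like(y, float)
    pos = y >= 0  # forward maps x>=0 <-> y>=0
    if abs(lam) > 1e-12:
        out[pos] = np.expm1(np.log1p(lam * y[pos]) / lam)
    else:
        out[pos] = np.expm1(y[pos])
    if abs(lam - 2.0) > 1e-12:
        out[~pos] = -np.expm1(np.log1p(-(2.0 - lam) * y[~pos]) / (2.0 - lam))
    else:
        out[~pos] = -np.expm1(-y[~pos])
    return out


def standardize_trait(table: TrialTable, trait: str) -> tuple[TrialTable, PreprocessRecord]:
    """Standardize one trait column to sample mean 0 and sample SD 1 (ddof=1).

    Raises :class:`DegenerateDataError` for a (near-)constant column.
    """
    x = table.values_for(trait)
    if len(np.unique(x)) < 2:
        raise DegenerateDataError(f"trait {trait!r} is constant; cannot standardize")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if not sd > 0:
        raise DegenerateDataError(f"trait {trait!r} has zero sample SD")
    record = PreprocessRecord(trait_name=trait, standardize_mean=mean, standardize_sd=sd)
    return table.with_values(trait, (x - mean) / sd), record


def gaussianize_trait(
    table: TrialTable,
    trait: str,
    exclude_contexts: tuple[str, ...] = (),
) -> tuple[TrialTable, PreprocessRecord]:
    """Apply a Yeo-Johnson transform to one trait, parameter chosen by MLE.

    ``exclude_contexts`` lists context levels whose rows are left on the raw
    scale (the study design exempts one trait x context combination from
    transformation); the MLE uses only the transformed rows. If the profile
    likelihood optimisation fails, the identity transform is kept and a
    warning is issued.
    """
    sub = table.df["trait_name"] == trait
    if not sub.any():
        raise ConfigurationError(f"trait {trait!r} not present in table")
    contexts = table.df.loc[sub, "context"].to_numpy()
    x = table.df.loc[sub, "value"].to_numpy(float)
    fit_mask = ~np.isin(contexts, list(exclude_contexts))
    try:
        if fit_mask.sum() < 3:
            raise ValueError("too few rows to fit a transform parameter")
        _, lam = stats.yeojohnson(x[fit_mask])
        lam = float(lam)
        if not np.isfinite(lam):
            raise ValueError("non-finite Yeo-Johnson parameter")
    except Exception as err:  # optimizer failure -> identity fallback
        warnings.warn(
            f"Yeo-Johnson fit failed for trait {trait!r} ({err}); keeping transform=none",
            RuntimeWarning,
            stacklevel=2,
        )
        record = PreprocessRecord(trait_name=trait, transform="none")
        return table, record
    record = PreprocessRecord(
        trait_name=trait,
        transform="yeo_johnson",
        transform_parameter=lam,
        excluded_contexts=tuple(exclude_contexts),
    )
    new = x.copy()
    new[fit_mask] = _yeo_johnson(x[fit_mask], lam)
    return table.with_values(trait, new), record


def preprocess_trait(
    table: TrialTable,
    trait: str,
    transform: bool = True,
    exclude_contexts: tuple[str, ...] = (),
) -> tuple[TrialTable, PreprocessRecord]:
    """Full preprocessing for one trait: optional Gaussianization, then
    standardization of the whole column. Returns the processed table and a
    single invertible record combining both steps."""
    if transform:
        table, trec = gaussianize_trait(table, trait, exclude_contexts)
    else:
        trec = PreprocessRecord(trait_name=trait, transform="none")
    table, srec = standardize_trait(table, trait)
    combined = replace(
        trec,
        standardize_mean=srec.standardize_mean,
        standardize_sd=srec.standardize_sd,
    )
    return table, combined
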