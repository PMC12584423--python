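"""The four candidate variance structures and design-matrix assembly.

All four models share the same location structure — fixed effects of
population, sex, their interaction and context, plus a random intercept per
individual — and differ only in whether the among-individual SD (sigma_A)
and/or the within-individual (residual) SD (sigma_W) are shared across the
four population-by-sex groups or take one value per group:

===== ================== ==================
model sigma_A by group?  sigma_W by group?
===== ================== ==================
M1    no                 no
M2    yes                no
M3    no                 yes
M4    yes                yes
===== ================== ==================

The models are nested (M1 in M2/M3 in M4): forcing the group-specific SDs
equal recovers the simpler model's likelihood exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import TrialTable, _ordered_levels
from .exceptions import ConfigurationError, RankDeficiencyError

__all__ = ["ModelSpec", "DesignMatrices", "build_design", "MODEL_IDS"]

MODEL_IDS = ("M1", "M2", "M3", "M4")
_FLAGS = {"M1": (False, False), "M2": (True, False), "M3": (False, True), "M4": (True, True)}

#: group order used everywhere (rows/columns of contrast tables)
DEFAULT_GROUPS = ("PKF", "PKM", "PMF", "PMM")

DEFAULT_FIXED_EFFECTS = ("intercept", "population", "sex", "population:sex", "context")


@dataclass(frozen=True)
class ModelSpec:
    """Which variance components vary by group, and the shared structure."""

    model_id: str
    va_by_group: bool
    vw_by_group: bool
    fixed_effects: tuple[str, ...] = DEFAULT_FIXED_EFFECTS
    groups: tuple[str, ...] = DEFAULT_GROUPS

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ConfigurationError(f"model_id must be one of {MODEL_IDS}")
        if (self.va_by_group, self.vw_by_group) != _FLAGS[self.model_id]:
            raise ConfigurationError(
                f"{self.model_id} requires (va_by_group, vw_by_group) = {_FLAGS[self.model_id]}"
            )
        if len(set(self.groups)) != 4:
            raise ConfigurationError("exactly 4 distinct group labels required")

    @classmethod
    def from_id(cls, model_id: str, groups: tuple[str, ...] = DEFAULT_GROUPS) -> "ModelSpec":
        va, vw = _FLAGS[model_id]
        return cls(model_id, va, vw, groups=tuple(groups))

    @property
    def n_sigma_a(self) -> int:
        return 4 if self.va_by_group else 1

    @property
    def n_sigma_w(self) -> int:
        return 4 if self.vw_by_group else 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_id": self.model_id,
                "va_by_group": self.va_by_group,
                "vw_by_group": self.vw_by_group,
                "fixed_effects": list(self.fixed_effects),
                "groups": list(self.groups),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        d = json.loads(s)
        return cls(
            d["model_id"],
            d["va_by_group"],
            d["vw_by_group"],
            tuple(d["fixed_effects"]),
            tuple(d["groups"]),
        )


def candidate_set(groups: tuple[str, ...] = DEFAULT_GROUPS) -> list[ModelSpec]:
    """The four-model candidate set M1..M4."""
    return [ModelSpec.from_id(m, groups) for m in MODEL_IDS]


@dataclass
class DesignMatrices:
    """Assembled design structures for one trait.

    Attributes
    ----------
    X : (n_obs, p) fixed-effect design, treatment coding.
    coef_names : column labels of X, in order.
    individual_index : (n_obs,) int — observation -> individual (0..m-1).
    individual_ids : (m,) labels in index order.
    group_of_individual : (m,) int — individual -> group (0..3).
    group_of_obs : (n_obs,) int.
    group_labels : the 4 group labels, in fixed order.
    y : (n_obs,) response vector (the preprocessed trait values).
    """

    X: np.ndarray
    coef_names: list[str]
    individual_index: np.ndarray
    individual_ids: list[str]
    group_of_individual: np.ndarray
    group_of_obs: np.ndarray
    group_labels: tuple[str, ...]
    y: np.ndarray

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def Z(self) -> np.ndarray:
        """Dense (n_obs, m) incidence matrix of the individual random effect."""
        Z = np.zeros((self.n_obs, self.n_individuals))
        if self.n_individuals:
            Z[np.arange(self.n_obs), self.individual_index] = 1.0
        return Z


def _treatment_columns(values: pd.Series, levels: list, term: str):
    """Dummy columns for all non-reference levels of a factor."""
    if len(levels) < 2:
        raise RankDeficiencyError(
            f"term {term!r} has a single observed level ({levels}); design would be rank deficient",
            term=term,
        )
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((values == lev).to_numpy(float))
        names.append(f"{term}[{lev}]")
    return cols, names


def build_design(table: TrialTable, spec: ModelSpec, trait: str | None = None) -> DesignMatrices:
    """Assemble fixed-effect design, individual incidence and group indices.

    The table must contain a single trait (or ``trait`` names which one to
    use). Treatment coding with the first level of each factor as the
    reference; the deterministic column order is intercept, population, sex,
    population:sex, then the context dummies.
    """
    if trait is None:
        traits = table.traits
        if len(traits) != 1:
            raise ConfigurationError(
                f"table holds {len(traits)} traits; pass trait= to select one"
            )
        trait = traits[0]
    df = table.df[table.df["trait_name"] == trait].reset_index(drop=True)
    if df.empty:
        raise ConfigurationError(f"trait {trait!r} not present in table")

    pop_levels = _ordered_levels(df["population"])
    sex_levels = _ordered_levels(df["sex"])
    ctx_levels = _ordered_levels(df["context"], tuple(table.context_levels()))

    cols: list[np.ndarray] = []
    names: list[str] = []
    for term in spec.fixed_effects:
        if term == "intercept":
            cols.append(np.ones(len(df)))
            names.append("intercept")
        elif term == "population":
            c, n = _treatment_columns(df["population"], pop_levels, "population")
            cols += c
            names += n
        elif term == "sex":
            c, n = _treatment_columns(df["sex"], sex_levels, "sex")
            cols += c
            names += n
        elif term == "population:sex":
            if len(pop_levels) < 2 or len(sex_levels) < 2:
                raise RankDeficiencyError(
                    "population:sex interaction needs both factors at 2 levels",
                    term="population:sex",
                )
            for p in pop_levels[1:]:
                for s in sex_levels[1:]:
                    cols.append(
                        ((df["population"] == p) & (df["sex"] == s)).to_numpy(float)
                    )
                    names.append(f"population[{p}]:sex[{s}]")
        elif term == "context":
            c, n = _treatment_columns(df["context"], ctx_levels, "context")
            cols += c
            names += n
        else:
            raise ConfigurationError(f"unknown fixed-effect term {term!r}")

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(
            f"fixed-effect design is rank deficient (columns {names})"
        )

    ids = sorted(df["individual_id"].unique())
    id_index = {i: k for k, i in enumerate(ids)}
    individual_index = df["individual_id"].map(id_index).to_numpy(int)

    group_labels = tuple(spec.groups)
    obs_group = (df["population"] + df["sex"]).to_numpy(object)
    unknown = sorted(set(obs_group) - set(group_labels))
    if unknown:
        raise ConfigurationError(
            f"groups {unknown} in data are not in the spec's group list {group_labels}"
        )
    g_index = {g: k for k, g in enumerate(group_labels)}
    group_of_obs = np.array([g_index[g] for g in obs_group], int)
    group_of_individual = np.empty(len(ids), int)
    group_of_individual[individual_index] = group_of_obs  # consistent: 1 group per id

    return DesignMatrices(
        X=X,
        coef_names=names,
        individual_index=individual_index,
        individual_ids=ids,
        group_of_individual=group_of_individual,
        group_of_obs=group_of_obs,
        group_labels=group_labels,
        y=df["value"].to_numpy(float),
    )
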