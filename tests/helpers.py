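"""Shared builders for toy tables, designs and posterior stubs."""

import numpy as np
import pandas as pd

from behavar import MCMCConfig, PosteriorSamples, PriorConfig, TrialTable
from behavar.design import DesignMatrices, ModelSpec


def make_table(group_sizes=(2, 2, 2, 2), contexts=("novel_env", "familiar_env", "novel_object"),
               trait="trait", values=None, seed=0):
    """Small complete trial table; values default to seeded standard normals."""
    groups = ("PKF", "PKM", "PMF", "PMM")
    rows = []
    for g, label in enumerate(groups[: len(group_sizes)]):
        for k in range(group_sizes[g]):
            for ctx in contexts:
                rows.append((f"{label}{k}", label[:-1], label[-1], ctx, trait, 0.0))
    df = pd.DataFrame(rows, columns=["individual_id", "population", "sex",
                                     "context", "trait_name", "value"])
    if values is None:
        values = np.random.default_rng(seed).normal(size=len(df))
    df["value"] = np.asarray(values, float)
    return TrialTable(df)


def make_design(y, X=None, group_of_obs=None, n_individuals=0, individual_index=None):
    """Hand-built DesignMatrices for toy models (default: intercept only,
    one group, no random effects)."""
    y = np.asarray(y, float)
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    group_of_obs = np.zeros(n, int) if group_of_obs is None else np.asarray(group_of_obs, int)
    if n_individuals == 0:
        individual_index = np.zeros(0, int)
        group_of_individual = np.zeros(0, int)
    else:
        if individual_index is None:
            individual_index = np.arange(n) % n_individuals
        individual_index = np.asarray(individual_index, int)
        group_of_individual = np.zeros(n_individuals, int)
        group_of_individual[individual_index] = group_of_obs
    return DesignMatrices(
        X=X,
        coef_names=[f"b{j}" for j in range(X.shape[1])],
        individual_index=individual_index,
        individual_ids=[f"ind{k}" for k in range(n_individuals)],
        group_of_individual=group_of_individual,
        group_of_obs=group_of_obs,
        group_labels=("PKF", "PKM", "PMF", "PMM"),
        y=y,
    )


def fake_samples(beta_chains, sigma_a=None, sigma_w=None, coef_names=None, spec=None):
    """PosteriorSamples stub built from explicit draw arrays.

    beta_chains: (chains, draws, p). sigma arrays default to ones.
    """
    beta_chains = np.asarray(beta_chains, float)
    c, s, p = beta_chains.shape
    sigma_a = np.ones((c, s, 1)) if sigma_a is None else np.asarray(sigma_a, float)
    sigma_w = np.ones((c, s, 1)) if sigma_w is None else np.asarray(sigma_w, float)
    spec = spec or ModelSpec.from_id("M1")
    return PosteriorSamples(
        draws={"beta": beta_chains, "a": np.zeros((c, s, 0)),
               "sigma_a": sigma_a, "sigma_w": sigma_w},
        loglik_matrix=np.zeros((c * s, 1)),
        diagnostics=pd.DataFrame(),
        spec=spec,
        config=MCMCConfig(n_chains=c, n_warmup=1, n_samples=s, seed=0,
                          compute_diagnostics=False),
        prior=PriorConfig(),
        coef_names=coef_names or [f"b{j}" for j in range(p)],
        group_labels=("PKF", "PKM", "PMF", "PMM"),
        individual_ids=[],
    )
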