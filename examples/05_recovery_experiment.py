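"""Replicate parameter-recovery experiment: generate, fit, summarize.

Reports bias and RMSE of the posterior medians, 95%-CI coverage, and how
often each pairwise Delta V_W contrast is flagged substantial — the power
of the contrast when the generating SDs truly differ, or a false-positive
rate when they do not.
"""

from behavar import MCMCConfig, ModelSpec, StudyScenario, recovery_experiment

scenario = StudyScenario(
    group_sizes=(20, 20, 20, 20), sigma_a_true=(0.7,),
    sigma_w_true=(0.5, 1.0, 1.0, 1.0), seed=6,
)
report = recovery_experiment(
    scenario, ModelSpec.from_id("M3"), n_replicates=10,
    mcmc=MCMCConfig(n_chains=1, n_warmup=200, n_samples=400,
                    compute_diagnostics=False),
)

summary = report.summary()
sigma_rows = summary[summary["parameter"].str.startswith("sigma")]
print("recovery of the SD parameters over 10 replicates:")
print(sigma_rows.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nDelta V_W substantial-flag rate per group pair:")
print(report.flag_rates().to_string(index=False))
print("\nPairs involving PKF (true 2:1 SD ratio) should be flagged far more")
print("often than the equal-SD pairs; coverage should sit near 0.95.")
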