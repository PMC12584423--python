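"""Pairwise posterior contrasts of within-individual variance and
repeatability between groups.

Each off-diagonal cell is the posterior mean and equal-tailed 95% CI of
(row group - column group), computed per MCMC iteration. '*' marks cells
whose CI excludes zero ("substantial"); Delta V_W sits above the diagonal,
Delta R below.
"""

from behavar import (
    MCMCConfig, ModelSpec, StudyScenario, build_design, contrast_table,
    fit_mcmc, generate_study, format_contrast_grid, variance_components,
)

table = generate_study(StudyScenario(
    group_sizes=(25, 25, 25, 25), sigma_a_true=(0.7,),
    sigma_w_true=(0.5, 1.0, 1.0, 1.0), seed=4,
))
spec = ModelSpec.from_id("M3")
samples = fit_mcmc(None, build_design(table, spec), spec,
                   config=MCMCConfig(n_chains=2, n_warmup=300, n_samples=600, seed=5,
                                     compute_diagnostics=False))
summaries = variance_components(samples)
vw = contrast_table(summaries, "delta_vw")
r = contrast_table(summaries, "delta_r")

print("Delta V_W above diagonal, Delta R below; '*' = 95% CI excludes 0\n")
print(format_contrast_grid(vw, r).to_string())
print("\nPKF's generating residual variance is a quarter of the others', so")
print("its row/column should be starred: lower V_W and higher R than every")
print("other group, with the antisymmetric entries mirrored exactly.")
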