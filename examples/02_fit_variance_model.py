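"""Fit the heteroscedastic-residual model and read off the variance
partitioning.

Model M3 keeps one among-individual SD for all groups but gives each
population-by-sex group its own residual (within-individual) SD. The
per-group repeatability R = V_A / (V_A + V_W) then differs between groups
only through V_W: the more flexible a group is within individuals, the less
repeatable its behavior.
"""

import numpy as np

from behavar import (
    MCMCConfig, ModelSpec, StudyScenario, build_design, check_convergence,
    fit_mcmc, generate_study, variance_components,
)

table = generate_study(StudyScenario(seed=1))
spec = ModelSpec.from_id("M3")
design = build_design(table, spec)
samples = fit_mcmc(None, design, spec,
                   config=MCMCConfig(n_chains=2, n_warmup=400, n_samples=800, seed=2))

report = check_convergence(samples)
print(f"convergence: {'pass' if report.passed else 'check diagnostics'} "
      f"(max R-hat {report.table['rhat'].max():.3f})\n")

print("posterior mean [95% CI] per group:")
for s in variance_components(samples):
    va, vw, r = (s.summary.loc[q] for q in ("va", "vw", "r"))
    print(f"  {s.group}:  Vw = {vw['mean']:.2f} [{vw['q2.5']:.2f}, {vw['q97.5']:.2f}]"
          f"   R = {r['mean']:.2f} [{r['q2.5']:.2f}, {r['q97.5']:.2f}]")
print("\nV_A is shared, so group differences in R are driven by V_W alone;")
print("generating V_w was (0.42, 0.62, 0.73, 0.61) for (PKF, PKM, PMF, PMM).")
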