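"""Recover known mixed-model structure from a synthetic cohort.

Generates a per-lap dataset in which VTE at the second choice point
depends on VTE at the first (slope 0.0685) with rat and session random
intercepts, then fits the corresponding linear mixed model and compares
estimates with the generating truth.
"""

from twostep.stats import fit_lmm, spec_vte_correlation
from twostep.synth import CohortConfig, gen_lmm_dataset

truth = {"beta": 0.0685, "sigma_r": 0.225, "sigma_s": 0.369, "sigma_eps": 0.904}
cfg = CohortConfig(n_rats=7, sessions_per_rat=20, laps_per_session=74)
spec = spec_vte_correlation()
df, gt = gen_lmm_dataset(
    spec,
    {"zlogidphi1": truth["beta"]},
    {k: truth[k] for k in ("sigma_r", "sigma_s", "sigma_eps")},
    cfg,
    seed=1,
)
fit = fit_lmm(spec, df)

print(f"n = {fit.n_obs} laps, converged = {fit.converged}\n")
print("fixed effects (estimate [95% CI], t, p):")
print(fit.fixed.round(4).to_string())
print("\nrandom-effect SDs (estimate [95% CI]) vs truth:")
for name, key in (("sigma_r", "sigma_r"), ("sigma_s", "sigma_s"), ("sigma_eps", "sigma_eps")):
    row = fit.random.loc[name]
    print(f"  {name}: {row['sd']:.3f} [{row['ci_low']:.3f}, {row['ci_high']:.3f}]"
          f"  (truth {truth[key]})")
print("\nThe slope on zlogidphi1 should bracket 0.0685: within-lap VTE at the\n"
      "two choice points is correlated beyond rat- and session-level shifts.")
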