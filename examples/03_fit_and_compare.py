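"""Fit all three choice algorithms to one dataset and compare by DIC.

Generates a small hybrid-agent cohort (the ground truth), fits the
model-free, model-based and hybrid algorithms by MCMC, and ranks them.
Expect the hybrid to win with a DIC margin far above the support
threshold of 7.
"""

import warnings

import numpy as np

from twostep import TaskConfig, simulate_session
from twostep.fitting import compare_models, fit_algorithm
from twostep.synth import PRESETS

cfg = TaskConfig()
rng = np.random.default_rng(3)
sessions = [simulate_session(PRESETS["hybrid"], "hybrid", cfg, rng) for _ in range(60)]

fits = []
for algo in ("mf", "mb", "hybrid"):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result, _ = fit_algorithm(
            algo, sessions, cfg, n_chains=2, n_iter=800, n_warmup=400, seed=0,
            compute_map=False,
        )
    fits.append(result)
    w = result.mean.get("w")
    extra = f", posterior mean w = {w:.2f}" if w is not None else ""
    print(f"{algo:7s} DIC {result.dic:9.1f}  p_D {result.p_d:5.1f}{extra}")

print()
print(compare_models(fits).to_string(index=False))
print(
    "\nDIC differences > 7 mean the higher-scoring model has considerably\n"
    "less support; the generating hybrid (w = 0.65) should be recovered."
)
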