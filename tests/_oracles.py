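"""Independent oracles used by the tests.

These deliberately re-derive quantities by the most transparent route
available -- a per-trial Python walk for the likelihood, full enumeration
for the exact signed-rank test -- and share no code with the production
paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

_A1 = {"A": 0, "B": 1}
_A2 = {"left": 0, "right": 1}
_CTX = {"C2": 1, "C3": 2}


def naive_loglik(theta, algorithm, sessions, cfg):
    """Trial-by-trial re-implementation of the choice likelihood."""
    from twostep.fitting import PARAM_NAMES

    td = dict(zip(PARAM_NAMES[algorithm], theta))
    alpha1 = td.get("alpha1", 0.0)
    lam = td.get("lam", 0.0)
    w = td.get("w")
    ll = 0.0
    for sess in sessions:
        q = np.full((3, 2), cfg.mean_reward)
        prev1 = prev2 = None
        for lap in sess:
            i1, s2, i2 = _A1[lap.choice1], _CTX[lap.context], _A2[lap.choice2]
            if algorithm == "mf":
                v1 = q[0].copy()
            else:
                pc = cfg.p_common
                vmb = np.array(
                    [
                        pc * q[1].max() + (1 - pc) * q[2].max(),
                        (1 - pc) * q[1].max() + pc * q[2].max(),
                    ]
                )
                v1 = vmb if algorithm == "mb" else w * vmb + (1 - w) * q[0]
            for values, beta, idx, prev in (
                (v1, td["beta1"], i1, prev1),
                (q[s2].copy(), td["beta2"], i2, prev2),
            ):
                bonus = np.zeros(2)
                if prev is not None:
                    bonus[prev] = td["p"]
                logits = beta * (values + bonus)
                logits -= logits.max()
                ll += logits[idx] - math.log(np.exp(logits).sum())
            if algorithm in ("mf", "hybrid"):
                q[0, i1] += alpha1 * (q[s2, i2] - q[0, i1])
            delta2 = lap.reward - q[s2, i2]
            q[s2, i2] += td["alpha2"] * delta2
            if algorithm in ("mf", "hybrid"):
                q[0, i1] += alpha1 * lam * delta2
            prev1, prev2 = i1, i2
    return ll


def brute_force_signed_rank_p(differences) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    from scipy.stats import rankdata

    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    stats = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    stats = np.asarray(stats)
    p_le = np.mean(stats <= w_obs + 1e-9)
    p_ge = np.mean(stats >= w_obs - 1e-9)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def random_theta(algorithm, rng):
    """A parameter vector drawn inside each parameter's support."""
    from twostep.fitting import PARAM_NAMES

    out = []
    for nm in PARAM_NAMES[algorithm]:
        if nm in ("alpha1", "alpha2", "lam", "w"):
            out.append(rng.uniform(0.0, 1.0))
        elif nm in ("beta1", "beta2"):
            out.append(rng.uniform(0.0, 5.0))
        else:
            out.append(rng.normal(0.0, 0.5))
    return np.array(out)
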