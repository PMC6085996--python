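"""Bayesian fitting of the choice algorithms and DIC model comparison.

The likelihood of a dataset is the product over sessions, trials and the
two choice stages of the softmax probability assigned to the action the
subject actually took, with the Q table reset to its mean-reward
initialization at every session start.  Parameters are pooled across
subjects (one theta for the whole dataset).

Priors (vaguely informative): Beta(1.2, 1.2) on the unit-interval
parameters (learning rates, lambda, w), Exponential(rate 0.5) on the
inverse temperatures, Normal(0, 10) on the perseveration weight.

Posterior sampling uses an adaptive random-walk Metropolis on
unconstrained transforms (logit for [0,1] parameters, log for the betas):
per-chain step-size and proposal-covariance adaptation during warm-up,
frozen afterwards.  Convergence is summarized by split-R-hat and bulk ESS.

Model comparison uses the Deviance Information Criterion
DIC = D(theta_bar) + 2 * p_D with p_D = D_bar - D(theta_bar) and
D(theta) = -2 log p(data | theta); DIC differences greater than 7 mark the
higher-scoring model as having considerably less support.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import beta as beta_dist, expon, norm
from scipy.optimize import minimize

from .task import LapRecord, TaskConfig

__all__ = [
    "PARAM_NAMES",
    "FitError",
    "NumericalError",
    "PosteriorSamples",
    "FitResult",
    "encode_sessions",
    "dataset_loglik",
    "log_prior",
    "adaptive_rwm_chain",
    "sample_posterior",
    "map_estimate",
    "dic_score",
    "compare_models",
    "fit_algorithm",
]

#: free parameters of each algorithm, in canonical order
PARAM_NAMES = {
    "mf": ("alpha1", "alpha2", "lam", "beta1", "beta2", "p"),
    "mb": ("alpha2", "beta1", "beta2", "p"),
    "hybrid": ("alpha1", "alpha2", "lam", "beta1", "beta2", "p", "w"),
}

# transform kind per parameter: "unit" -> logit/sigmoid, "pos" -> log/exp
_KIND = {
    "alpha1": "unit",
    "alpha2": "unit",
    "lam": "unit",
    "w": "unit",
    "beta1": "pos",
    "beta2": "pos",
    "p": "real",
}

_PRIOR = {
    "unit": beta_dist(1.2, 1.2),
    "pos": expon(scale=2.0),  # rate 0.5
    "real": norm(0.0, 10.0),
}


class FitError(RuntimeError):
    pass


class NumericalError(FitError):
    pass


# ---------------------------------------------------------------------------
# data encoding


_A1_CODE = {"A": 0, "B": 1}
_CTX_CODE = {"C2": 1, "C3": 2}
_A2_CODE = {"left": 0, "right": 1}


def encode_sessions(sessions: list) -> dict:
    """Pack a list of sessions (each a list of LapRecord) into padded arrays.

    Returns a dict of int/float arrays of shape (n_sessions, max_laps) plus
    a boolean validity mask, suitable for the vectorized likelihood.
    """
    if not sessions:
        raise ValueError("sessions must be nonempty")
    S = len(sessions)
    L = max(len(s) for s in sessions)
    a1 = np.zeros((S, L), dtype=np.intp)
    ctx = np.ones((S, L), dtype=np.intp)
    a2 = np.zeros((S, L), dtype=np.intp)
    rew = np.zeros((S, L), dtype=float)
    mask = np.zeros((S, L), dtype=bool)
    for i, sess in enumerate(sessions):
        for t, lap in enumerate(sess):
            a1[i, t] = _A1_CODE[lap.choice1]
            ctx[i, t] = _CTX_CODE[lap.context]
            a2[i, t] = _A2_CODE[lap.choice2]
            rew[i, t] = lap.reward
            mask[i, t] = True
    return {"a1": a1, "ctx": ctx, "a2": a2, "rew": rew, "mask": mask}


def _dataset_signature(enc: dict) -> str:
    h = hashlib.sha256()
    for key in ("a1", "ctx", "a2", "mask"):
        h.update(np.ascontiguousarray(enc[key]).tobytes())
    h.update(np.ascontiguousarray(np.round(enc["rew"], 9)).tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# likelihood


def _theta_dict(theta, algorithm: str) -> dict:
    names = PARAM_NAMES[algorithm]
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (len(names),):
        raise ValueError(
            f"{algorithm} expects {len(names)} parameters {names}, got shape {theta.shape}"
        )
    return dict(zip(names, theta))


def _loglik_encoded(theta, algorithm: str, enc: dict, cfg: TaskConfig) -> float:
    """Vectorized-over-sessions log likelihood of the observed choices."""
    td = _theta_dict(theta, algorithm)
    alpha1 = td.get("alpha1", 0.0)
    alpha2 = td["alpha2"]
    lam = td.get("lam", 0.0)
    beta1, beta2, pers = td["beta1"], td["beta2"], td["p"]
    w = td.get("w", 1.0 if algorithm == "mb" else 0.0)
    mf_cache = algorithm in ("mf", "hybrid")

    a1, ctx, a2 = enc["a1"], enc["ctx"], enc["a2"]
    rew, mask = enc["rew"], enc["mask"]
    S, L = a1.shape
    rows = np.arange(S)
    pc = cfg.p_common

    q = np.full((S, 3, 2), cfg.mean_reward)
    prev1 = np.full(S, -1, dtype=np.intp)
    prev2 = np.full(S, -1, dtype=np.intp)
    ll = 0.0
    for t in range(L):
        m = mask[:, t]
        a1t, ctxt, a2t, r = a1[:, t], ctx[:, t], a2[:, t], rew[:, t]

        # stage-1 action values under the algorithm (two 1-D columns)
        if algorithm != "mf":
            max_c2 = np.maximum(q[:, 1, 0], q[:, 1, 1])
            max_c3 = np.maximum(q[:, 2, 0], q[:, 2, 1])
            va = pc * max_c2 + (1 - pc) * max_c3
            vb = (1 - pc) * max_c2 + pc * max_c3
            if algorithm == "hybrid":
                va = w * va + (1 - w) * q[:, 0, 0]
                vb = w * vb + (1 - w) * q[:, 0, 1]
        else:
            va, vb = q[:, 0, 0], q[:, 0, 1]

        l0 = beta1 * (va + np.where(prev1 == 0, pers, 0.0))
        l1 = beta1 * (vb + np.where(prev1 == 1, pers, 0.0))
        lse = np.logaddexp(l0, l1)
        ll += float((np.where(a1t == 1, l1, l0)[m] - lse[m]).sum())

        v2 = q[rows, ctxt, :]
        l0 = beta2 * (v2[:, 0] + np.where(prev2 == 0, pers, 0.0))
        l1 = beta2 * (v2[:, 1] + np.where(prev2 == 1, pers, 0.0))
        lse = np.logaddexp(l0, l1)
        ll += float((np.where(a2t == 1, l1, l0)[m] - lse[m]).sum())
        if not np.isfinite(ll):
            raise NumericalError(
                f"non-finite log-likelihood at lap {t} ({algorithm}, theta={theta})"
            )

        # learning updates (masked laps leave the table untouched)
        q2a = q[rows, ctxt, a2t]
        if mf_cache:
            q1a = q[rows, 0, a1t]
            q[rows, 0, a1t] = q1a + alpha1 * (q2a - q1a) * m
        delta2 = r - q2a
        q[rows, ctxt, a2t] = q2a + alpha2 * delta2 * m
        if mf_cache:
            q[rows, 0, a1t] = q[rows, 0, a1t] + alpha1 * lam * delta2 * m
        prev1 = np.where(m, a1t, prev1)
        prev2 = np.where(m, a2t, prev2)
    return ll


def dataset_loglik(theta, algorithm: str, sessions: list, cfg: TaskConfig) -> float:
    """Log probability of all observed choices given theta.

    ``sessions`` is a list of sessions, each a list of LapRecord; the Q
    table is reset at every session start.  The sum runs over sessions,
    trials and both choice stages.
    """
    if algorithm not in PARAM_NAMES:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return _loglik_encoded(theta, algorithm, encode_sessions(sessions), cfg)


# ---------------------------------------------------------------------------
# priors and transforms


def log_prior(theta, algorithm: str) -> float:
    """Sum of per-parameter log prior densities; -inf outside support."""
    names = PARAM_NAMES[algorithm]
    theta = np.asarray(theta, dtype=float)
    total = 0.0
    for name, x in zip(names, theta):
        lp = _PRIOR[_KIND[name]].logpdf(x)
        if not np.isfinite(lp):
            return -np.inf
        total += float(lp)
    return total


def to_unconstrained(theta, algorithm: str) -> np.ndarray:
    z = []
    for name, x in zip(PARAM_NAMES[algorithm], np.asarray(theta, dtype=float)):
        kind = _KIND[name]
        if kind == "unit":
            x = min(max(x, 1e-12), 1 - 1e-12)
            z.append(np.log(x) - np.log1p(-x))
        elif kind == "pos":
            z.append(np.log(max(x, 1e-300)))
        else:
            z.append(x)
    return np.array(z)


def to_constrained(z, algorithm: str) -> np.ndarray:
    x = []
    for name, zi in zip(PARAM_NAMES[algorithm], np.asarray(z, dtype=float)):
        kind = _KIND[name]
        if kind == "unit":
            x.append(expit(zi))
        elif kind == "pos":
            x.append(np.exp(zi))
        else:
            x.append(zi)
    return np.array(x)


def _log_jacobian(z, algorithm: str) -> float:
    total = 0.0
    for name, zi in zip(PARAM_NAMES[algorithm], np.asarray(z, dtype=float)):
        kind = _KIND[name]
        if kind == "unit":
            # log sigma'(z) = log s + log(1 - s)
            s = expit(zi)
            total += np.log(max(s, 1e-300)) + np.log(max(1 - s, 1e-300))
        elif kind == "pos":
            total += zi
    return float(total)


# ---------------------------------------------------------------------------
# posterior sampling


@dataclass
class PosteriorSamples:
    """MCMC draws of theta with per-draw log posterior and deviance."""

    algorithm: str
    param_names: tuple
    draws: np.ndarray  # (n_draws, n_params), constrained scale
    z_draws: np.ndarray  # unconstrained scale
    chain: np.ndarray  # (n_draws,) chain label
    log_posterior: np.ndarray
    log_lik: np.ndarray
    rhat: dict
    ess: dict
    accept_rate: float
    converged: bool
    dataset_signature: str
    _deviance_fn: object = field(repr=False, default=None)

    @property
    def deviance(self) -> np.ndarray:
        return -2.0 * self.log_lik

    def theta_bar(self, scale: str = "unconstrained") -> np.ndarray:
        """Posterior mean of theta, averaged on the requested scale."""
        if scale == "unconstrained":
            return to_constrained(self.z_draws.mean(axis=0), self.algorithm)
        if scale == "constrained":
            return self.draws.mean(axis=0)
        raise ValueError("scale must be 'unconstrained' or 'constrained'")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=list(self.param_names))
        df.insert(0, "chain", self.chain)
        iters = np.concatenate(
            [np.arange(np.sum(self.chain == c)) for c in np.unique(self.chain)]
        )
        df.insert(1, "iter", iters)
        df["log_posterior"] = self.log_posterior
        df["deviance"] = self.deviance
        return df


def _split_rhat(x: np.ndarray) -> float:
    """Split-R-hat of one parameter; x has shape (n_chains, n_iter)."""
    n_chains, n = x.shape
    half = n // 2
    if half < 2:
        return np.nan
    halves = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n = halves.shape
    chain_means = halves.mean(axis=1)
    b = n * chain_means.var(ddof=1)
    w = halves.var(axis=1, ddof=1).mean()
    if w <= 0:
        return np.nan
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _bulk_ess(x: np.ndarray) -> float:
    """Effective sample size from pooled autocorrelations (Geyer pairs)."""
    n_chains, n = x.shape
    if n < 4:
        return np.nan
    acov = []
    for c in range(n_chains):
        xc = x[c] - x[c].mean()
        f = np.fft.rfft(xc, 2 * n)
        a = np.fft.irfft(f * np.conj(f))[:n].real / n
        acov.append(a)
    acov = np.mean(acov, axis=0)
    if acov[0] <= 0:
        return np.nan
    rho = acov / acov[0]
    # initial positive sequence over pairs
    tau = 1.0
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k] if 2 * k < n else 0.0
        if pair < 0:
            break
        tau += 2 * pair
    return float(n_chains * n / max(tau, 1e-12))


def adaptive_rwm_chain(
    logpost,
    z0: np.ndarray,
    n_iter: int,
    n_warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.3,
):
    """One adaptive random-walk Metropolis chain on R^d.

    ``logpost(z)`` must return ``(log_density, aux)`` where ``aux`` is any
    scalar stored alongside the draw (e.g. a log likelihood).  During
    warm-up the scalar step size follows a Robbins-Monro recursion toward
    ``target_accept`` and the proposal covariance is re-estimated from the
    recent history at two checkpoints; both are frozen afterwards.

    Returns (draws, log_densities, aux_values, n_accept) for the
    ``n_iter - n_warmup`` post-warm-up iterations.
    """
    d = len(z0)
    z = np.asarray(z0, dtype=float).copy()
    lp, aux = logpost(z)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")
    keep = n_iter - n_warmup
    out_z = np.empty((keep, d))
    out_lp = np.empty(keep)
    out_aux = np.empty(keep)
    checkpoints = {int(n_warmup * f) for f in (0.4, 0.7)}
    log_step = np.log(1.0 / np.sqrt(d))
    chol = np.eye(d)
    history = np.empty((max(n_warmup, 1), d))
    t_adapt = 0
    n_accept = 0
    for i in range(n_iter):
        prop = z + np.exp(log_step) * (chol @ rng.standard_normal(d))
        lp_prop, aux_prop = logpost(prop)
        accept = np.log(rng.random()) < lp_prop - lp
        if accept:
            z, lp, aux = prop, lp_prop, aux_prop
        if i < n_warmup:
            history[i] = z
            t_adapt += 1
            log_step += (float(accept) - target_accept) / t_adapt**0.6
            if i in checkpoints and i >= max(2 * d, 20):
                cov = np.cov(history[i // 2 : i + 1].T) + 1e-8 * np.eye(d)
                chol = np.linalg.cholesky(np.atleast_2d(cov))
                log_step = np.log(2.38 / np.sqrt(d))
                t_adapt = 10  # damp, but keep adapting
        else:
            j = i - n_warmup
            out_z[j] = z
            out_lp[j] = lp
            out_aux[j] = aux
            n_accept += int(accept)
    return out_z, out_lp, out_aux, n_accept


def sample_posterior(
    algorithm: str,
    sessions: list,
    cfg: TaskConfig,
    n_chains: int = 4,
    n_iter: int = 2000,
    n_warmup: int = 1000,
    seed=0,
    rhat_threshold: float = 1.01,
    ess_threshold: float = 400.0,
    target_accept: float = 0.3,
) -> PosteriorSamples:
    """Adaptive random-walk Metropolis sampling of the pooled posterior.

    ``n_iter`` counts total iterations per chain including the ``n_warmup``
    adaptation phase; the returned draws are the post-warm-up iterations of
    every chain.  Non-convergence (split-R-hat above threshold or ESS below
    threshold) is flagged in the result, not raised.
    """
    if algorithm not in PARAM_NAMES:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if n_iter <= n_warmup:
        raise ValueError("n_iter must exceed n_warmup")
    names = PARAM_NAMES[algorithm]
    d = len(names)
    enc = encode_sessions(sessions)
    signature = _dataset_signature(enc)

    def loglik(theta):
        return _loglik_encoded(theta, algorithm, enc, cfg)

    def logpost_z(z):
        theta = to_constrained(z, algorithm)
        lp = log_prior(theta, algorithm)
        if not np.isfinite(lp):
            return -np.inf, -np.inf
        llk = loglik(theta)
        return llk + lp + _log_jacobian(z, algorithm), llk

    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(n_chains)
    keep = n_iter - n_warmup
    all_z = np.empty((n_chains, keep, d))
    all_lp = np.empty((n_chains, keep))
    all_ll = np.empty((n_chains, keep))
    n_accept = 0

    # moderate overdispersed initialization boxes on the unconstrained
    # scale (wide prior draws of the betas can strand a chain on a
    # likelihood cliff that warm-up cannot climb out of)
    _INIT_BOX = {"unit": (-2.0, 2.0), "pos": (-1.0, 1.5), "real": (-1.0, 1.0)}

    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        for _ in range(100):
            z0 = np.array([rng.uniform(*_INIT_BOX[_KIND[nm]]) for nm in names])
            lp0, _ = logpost_z(z0)
            if np.isfinite(lp0):
                break
        else:  # pragma: no cover
            raise FitError("could not find a finite-posterior initial point")
        zs, lps, auxs, acc = adaptive_rwm_chain(
            logpost_z, z0, n_iter, n_warmup, rng, target_accept
        )
        all_z[c], all_lp[c], all_ll[c] = zs, lps, auxs
        n_accept += acc

    rhat = {nm: _split_rhat(all_z[:, :, k]) for k, nm in enumerate(names)}
    ess = {nm: _bulk_ess(all_z[:, :, k]) for k, nm in enumerate(names)}
    converged = all(
        np.isfinite(r) and r < rhat_threshold for r in rhat.values()
    ) and all(np.isfinite(e) and e > ess_threshold for e in ess.values())
    if not converged:
        warnings.warn(
            f"{algorithm}: MCMC convergence flags tripped "
            f"(max R-hat {max(rhat.values()):.3f}, min ESS {min(ess.values()):.0f})",
            RuntimeWarning,
            stacklevel=2,
        )

    z_flat = all_z.reshape(-1, d)
    draws = np.apply_along_axis(to_constrained, 1, z_flat, algorithm)

    def deviance_fn(theta):
        theta = np.asarray(theta, dtype=float)
        if not np.isfinite(log_prior(theta, algorithm)):
            bad = [
                nm
                for nm, x in zip(names, theta)
                if not np.isfinite(_PRIOR[_KIND[nm]].logpdf(x))
            ]
            raise FitError(f"theta outside prior support for parameter(s) {bad}")
        return -2.0 * loglik(theta)

    return PosteriorSamples(
        algorithm=algorithm,
        param_names=names,
        draws=draws,
        z_draws=z_flat,
        chain=np.repeat(np.arange(n_chains), keep),
        log_posterior=all_lp.reshape(-1),
        log_lik=all_ll.reshape(-1),
        rhat=rhat,
        ess=ess,
        accept_rate=n_accept / (n_chains * keep),
        converged=converged,
        dataset_signature=signature,
        _deviance_fn=deviance_fn,
    )


# ---------------------------------------------------------------------------
# MAP, DIC, model comparison


def map_estimate(
    algorithm: str,
    sessions: list,
    cfg: TaskConfig,
    n_restarts: int = 4,
    seed=0,
) -> np.ndarray:
    """Posterior mode (constrained scale) via L-BFGS in unconstrained
    coordinates with multiple prior-seeded restarts."""
    names = PARAM_NAMES[algorithm]
    enc = encode_sessions(sessions)
    rng = np.random.default_rng(seed)
    box = {"unit": (-2.0, 2.0), "pos": (-1.0, 1.5), "real": (-1.0, 1.0)}

    def neg_logpost(z):
        theta = to_constrained(z, algorithm)
        lp = log_prior(theta, algorithm)
        if not np.isfinite(lp):
            return 1e300
        try:
            return -(_loglik_encoded(theta, algorithm, enc, cfg) + lp)
        except NumericalError:
            return 1e300

    best, best_val, failures = None, np.inf, []
    for _ in range(n_restarts):
        z0 = np.array([rng.uniform(*box[_KIND[nm]]) for nm in names])
        try:
            res = minimize(neg_logpost, z0, method="L-BFGS-B")
        except Exception as exc:  # pragma: no cover
            failures.append(repr(exc))
            continue
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    if best is None:
        raise FitError(f"all MAP restarts failed: {failures}")
    # derivative-free polish: the numeric-gradient path can stall on the
    # stiff likelihood surface near the boundaries
    polish = minimize(
        neg_logpost, best, method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
    )
    if polish.fun < best_val:
        best = polish.x
    return to_constrained(best, algorithm)


def dic_score(samples: PosteriorSamples, scale: str = "unconstrained"):
    """DIC and effective parameter count from posterior draws.

    D_bar is the mean deviance over draws; D(theta_bar) the deviance at the
    draw mean (averaged on ``scale``, then back-transformed when
    unconstrained).  Returns (DIC, p_D).
    """
    if len(samples.log_lik) < 2:
        raise ValueError("need at least 2 draws")
    d_bar = float(samples.deviance.mean())
    d_at_mean = float(samples._deviance_fn(samples.theta_bar(scale)))
    p_d = d_bar - d_at_mean
    return d_at_mean + 2.0 * p_d, p_d


@dataclass
class FitResult:
    """Posterior summary of one algorithm fit (mirrors a per-model table:
    MAP / posterior mean / SD per parameter, plus DIC)."""

    algorithm: str
    param_names: tuple
    map: dict
    mean: dict
    sd: dict
    median: dict
    ci_low: dict
    ci_high: dict
    dic: float
    p_d: float
    log_post_map: float
    rhat: dict
    ess: dict
    converged: bool
    n_draws: int
    dataset_signature: str

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "parameters": {
                nm: {
                    "map": self.map[nm],
                    "mean": self.mean[nm],
                    "sd": self.sd[nm],
                    "median": self.median[nm],
                    "ci2.5": self.ci_low[nm],
                    "ci97.5": self.ci_high[nm],
                }
                for nm in self.param_names
            },
            "dic": self.dic,
            "p_d": self.p_d,
            "log_post_map": self.log_post_map,
            "diagnostics": {"rhat": self.rhat, "ess": self.ess, "converged": self.converged},
            "n_draws": self.n_draws,
            "dataset_signature": self.dataset_signature,
        }


def fit_algorithm(
    algorithm: str,
    sessions: list,
    cfg: TaskConfig,
    n_chains: int = 4,
    n_iter: int = 2000,
    n_warmup: int = 1000,
    seed=0,
    compute_map: bool = True,
) -> tuple[FitResult, PosteriorSamples]:
    """Sample the posterior, optionally locate the MAP, and score DIC."""
    samples = sample_posterior(
        algorithm, sessions, cfg, n_chains=n_chains, n_iter=n_iter,
        n_warmup=n_warmup, seed=seed,
    )
    names = samples.param_names
    if compute_map:
        theta_map = map_estimate(algorithm, sessions, cfg, seed=seed)
    else:
        theta_map = samples.draws[np.argmax(samples.log_posterior)]
    lp_map = dataset_loglik(theta_map, algorithm, sessions, cfg) + log_prior(
        theta_map, algorithm
    )
    dic, p_d = dic_score(samples)
    q = np.percentile(samples.draws, [2.5, 50, 97.5], axis=0)
    result = FitResult(
        algorithm=algorithm,
        param_names=names,
        map=dict(zip(names, theta_map)),
        mean=dict(zip(names, samples.draws.mean(axis=0))),
        sd=dict(zip(names, samples.draws.std(axis=0, ddof=1))),
        median=dict(zip(names, q[1])),
        ci_low=dict(zip(names, q[0])),
        ci_high=dict(zip(names, q[2])),
        dic=dic,
        p_d=p_d,
        log_post_map=lp_map,
        rhat=samples.rhat,
        ess=samples.ess,
        converged=samples.converged,
        n_draws=len(samples.log_lik),
        dataset_signature=samples.dataset_signature,
    )
    return result, samples


def compare_models(fits: list, support_threshold: float = 7.0) -> pd.DataFrame:
    """Rank fits by DIC (ascending) on a shared dataset.

    The returned frame annotates the DIC difference to the best model and
    whether that difference exceeds the "considerably less support"
    threshold (default 7).
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    sigs = {f.dataset_signature for f in fits}
    if len(sigs) != 1:
        raise ValueError(f"fits are not on the same dataset: signatures {sorted(sigs)}")
    rows = sorted(fits, key=lambda f: f.dic)
    best = rows[0].dic
    return pd.DataFrame(
        {
            "algorithm": [f.algorithm for f in rows],
            "dic": [f.dic for f in rows],
            "p_d": [f.p_d for f in rows],
            "delta_dic": [f.dic - best for f in rows],
            "support": [
                "most likely"
                if f.dic == best
                else (
                    "considerably less support"
                    if f.dic - best > support_threshold
                    else "no considerable difference"
                )
                for f in rows
            ],
        }
    )
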