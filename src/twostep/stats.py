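"""Statistical battery for two-step behavior.

Covers the four analysis families used with this task:

* stay-probability tables: probability of repeating the first-stage choice
  as a function of the previous lap's delay (2-s bins) and transition type
  -- the signature that separates model-based from model-free behavior;
* per-session Spearman correlations with a group-level signed-rank test;
* lap-wise rank-sum tests against late-session laps, Bonferroni corrected;
* Gaussian linear mixed models with random intercepts for rat and for
  session nested in rat, fit by maximum likelihood.

The exact small-sample Wilcoxon signed-rank test enumerates the full
sign-assignment null distribution (doubled ranks keep tie-averaged ranks
integral), switching to a continuity-corrected normal approximation for
n > 25.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "stay_probability_table",
    "SpearmanBySession",
    "spearman_by_session",
    "wilcoxon_signed_rank_exact",
    "lapwise_rank_sum",
    "MixedModelSpec",
    "MixedModelFit",
    "fit_lmm",
    "spec_vte_correlation",
    "spec_transition",
    "spec_vte1_full",
]


# ---------------------------------------------------------------------------
# stay probability


def stay_probability_table(
    laps: pd.DataFrame,
    bin_width: float = 2.0,
    delay_range: tuple = (1.0, 30.0),
) -> pd.DataFrame:
    """Stay fraction by (previous-lap delay bin, previous-lap transition).

    ``laps`` is a lap-event table with columns rat_id, session_id, lap,
    choice1, transition, delay_s.  For each within-session lap t > 1,
    stay = 1 iff choice1 repeats the previous lap's choice1; rows are
    aggregated by the *previous* lap's delay bin and transition type.
    Empty cells are reported as NaN, not zero.
    """
    if len(laps) < 2:
        raise ValueError("need at least 2 laps")
    df = laps.sort_values(["rat_id", "session_id", "lap"]).copy()
    grp = df.groupby(["rat_id", "session_id"], sort=False)
    df["stay"] = (df["choice1"] == grp["choice1"].shift()).astype(float)
    df["prev_delay"] = grp["delay_s"].shift()
    df["prev_transition"] = grp["transition"].shift()
    df = df.dropna(subset=["prev_delay", "prev_transition"]).copy()
    lo, hi = delay_range
    edges = np.arange(lo, hi + bin_width, bin_width)
    df["delay_bin"] = pd.cut(df["prev_delay"], edges, include_lowest=True)
    out = (
        df.groupby(["delay_bin", "prev_transition"], observed=False)["stay"]
        .agg(stay_fraction="mean", n="count")
        .reset_index()
    )
    out.loc[out["n"] == 0, "stay_fraction"] = np.nan
    return out


# ---------------------------------------------------------------------------
# Spearman by session + group signed rank


@dataclass
class SpearmanBySession:
    rho: pd.Series  # index (rat_id, session_id)
    median_rho: float
    p_group: float
    n_dropped: int


def spearman_by_session(
    data: pd.DataFrame,
    x: str,
    y: str,
    min_laps: int = 3,
) -> SpearmanBySession:
    """Tie-corrected Spearman rho per session, plus a two-sided signed-rank
    test of the per-session rho's against zero.

    Sessions with fewer than ``min_laps`` complete pairs, or with a
    constant input (undefined rho), are dropped and counted.
    """
    rhos = {}
    n_dropped = 0
    for key, g in data.groupby(["rat_id", "session_id"], sort=False):
        sub = g[[x, y]].dropna()
        if len(sub) < min_laps:
            n_dropped += 1
            continue
        if sub[x].nunique() < 2 or sub[y].nunique() < 2:
            n_dropped += 1
            continue
        rho = sps.spearmanr(sub[x], sub[y]).statistic
        if np.isfinite(rho):
            rhos[key] = rho
        else:  # pragma: no cover
            n_dropped += 1
    if not rhos:
        raise ValueError("no session yielded a defined correlation")
    rho = pd.Series(rhos)
    p = wilcoxon_signed_rank_exact(rho.to_numpy())
    return SpearmanBySession(
        rho=rho, median_rho=float(rho.median()), p_group=p, n_dropped=n_dropped
    )


# ---------------------------------------------------------------------------
# exact Wilcoxon signed rank


def wilcoxon_signed_rank_exact(differences, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p-value.

    For n <= ``exact_max_n`` nonzero differences the p-value is exact,
    computed from the full 2^n sign-assignment null distribution of the
    signed-rank statistic (ranks are doubled so tie-averaged ranks stay
    integral).  Larger samples use a normal approximation with tie and
    continuity corrections.  Zero differences are discarded; an all-zero
    input is an error.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero; the test is undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        r2 = np.round(2 * ranks).astype(int)
        total = int(r2.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: total + 1 - r]
            counts = counts + shifted
        denom = 2.0**n
        w2 = int(round(2 * w_plus))
        p_le = counts[: w2 + 1].sum() / denom
        p_ge = counts[w2:].sum() / denom
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    mean = n * (n + 1) / 4.0
    ties = pd.Series(ranks).value_counts().to_numpy()
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((ties**3 - ties).sum()) / 48.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# lap-wise rank sum


def lapwise_rank_sum(
    data: pd.DataFrame,
    value: str,
    n_early: int = 50,
    reference_min_lap: int = 51,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-lap two-sample rank-sum test against pooled late-session laps.

    For each within-session lap index 1..``n_early``, that lap's values
    across sessions are compared with the pooled values of all laps with
    index >= ``reference_min_lap`` (Wilcoxon rank sum), Bonferroni
    corrected over the number of tests actually performed.
    """
    ref = data.loc[data["lap"] >= reference_min_lap, value].dropna().to_numpy()
    if len(ref) == 0:
        raise ValueError("reference set (late laps) is empty")
    rows = []
    for lap in range(1, n_early + 1):
        vals = data.loc[data["lap"] == lap, value].dropna().to_numpy()
        if len(vals) < 2:
            warnings.warn(f"lap {lap}: fewer than 2 observations, skipped", stacklevel=2)
            continue
        stat, p = sps.ranksums(vals, ref)
        rows.append({"lap": lap, "n": len(vals), "statistic": stat, "p_raw": p})
    out = pd.DataFrame(rows)
    m = len(out)
    out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * m)
    out["significant"] = out["p_raw"] < alpha / m
    return out


# ---------------------------------------------------------------------------
# linear mixed models


@dataclass(frozen=True)
class MixedModelSpec:
    """One Gaussian LMM specification: response, fixed-effect formula RHS,
    and data-preparation rules.  Random intercepts for rat and for session
    nested in rat are always included."""

    name: str
    response: str
    fixed: str
    drop_first_lap: bool = False
    zscore_map: tuple = ()  # pairs (new_column, source_column), pooled z-score

    @property
    def formula(self) -> str:
        return f"{self.response} ~ {self.fixed}"


def spec_vte_correlation() -> MixedModelSpec:
    """Predict (z-scored) VTE at the second choice point from VTE at the
    first choice point on the same lap."""
    return MixedModelSpec(
        name="vte-corr",
        response="zlogidphi2",
        fixed="zlogidphi1",
        zscore_map=(("zlogidphi1", "logidphi_cp1"), ("zlogidphi2", "logidphi_cp2")),
    )


def spec_transition(response: str) -> MixedModelSpec:
    """Response (VTE at either choice point, or path stereotypy) against
    rare-transition indicators for the current and previous lap."""
    return MixedModelSpec(
        name=f"{response}-transition",
        response=response,
        fixed="rare + rare_prev",
        drop_first_lap=True,
    )


def spec_vte1_full() -> MixedModelSpec:
    """VTE at the first choice point against previous-lap transition,
    choice repetition and previous-lap delay, with all interactions."""
    return MixedModelSpec(
        name="vte1-full",
        response="logidphi_cp1",
        fixed="rare_prev * repeat * delay_prev",
        drop_first_lap=True,
    )


@dataclass
class MixedModelFit:
    """Fixed-effect estimates with 95% CIs, t, residual DF and p, plus the
    three standard deviations (rat, session, residual) with CIs."""

    spec_name: str
    fixed: pd.DataFrame  # index term; columns estimate, ci_low, ci_high, tstat, df, p
    random: pd.DataFrame  # index sigma_r/sigma_s/sigma_eps; columns sd, ci_low, ci_high
    n_obs: int
    converged: bool
    boundary: bool

    def to_dict(self) -> dict:
        return {
            "spec": self.spec_name,
            "fixed": self.fixed.reset_index().to_dict(orient="records"),
            "random": self.random.reset_index().to_dict(orient="records"),
            "n_obs": self.n_obs,
            "converged": self.converged,
            "boundary": self.boundary,
        }


def _sd_ci(sd: float, se_var: float, z: float = 1.959963984540054):
    """Lognormal (log-scale Wald) CI for a standard deviation, from the
    standard error of the corresponding variance estimate."""
    if sd <= 0 or not np.isfinite(se_var) or se_var <= 0:
        return np.nan, np.nan
    se_log_sd = se_var / (2.0 * sd * sd)
    return sd * np.exp(-z * se_log_sd), sd * np.exp(z * se_log_sd)


def fit_lmm(spec: MixedModelSpec, data: pd.DataFrame) -> MixedModelFit:
    """Fit one mixed-model specification by maximum likelihood.

    Random structure: intercept per rat, plus a variance component for
    session nested within rat.  Rows missing any variable the spec uses
    are dropped -- in particular, first-of-session laps fall out of the
    previous-lap specs because their lagged covariates are undefined.
    Fixed-effect degrees of freedom use the residual (n - rank)
    convention; variance-component CIs are log-scale Wald intervals.
    """
    df = data.copy()
    for new, src in spec.zscore_map:
        if new not in df.columns:
            col = df[src].astype(float)
            df[new] = (col - col.mean()) / col.std(ddof=0)
    used = [spec.response] + [
        c for c in df.columns if c in spec.fixed or c in ("rat_id", "session_id")
    ]
    df = df.dropna(subset=[c for c in set(used) if c in df.columns])
    df = df.reset_index(drop=True)

    model = smf.mixedlm(
        spec.formula,
        df,
        groups=df["rat_id"],
        re_formula="1",
        vc_formula={"session": "0 + C(session_id)"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=False, method=["lbfgs", "powell"])

    k_fe = model.k_fe
    n = int(result.nobs)
    dof = n - k_fe
    est = result.fe_params
    se = result.bse_fe
    tstat = est / se
    tcrit = sps.t.ppf(0.975, dof)
    pvals = 2.0 * sps.t.sf(np.abs(tstat), dof)
    fixed = pd.DataFrame(
        {
            "estimate": est,
            "ci_low": est - tcrit * se,
            "ci_high": est + tcrit * se,
            "tstat": tstat,
            "df": dof,
            "p": pvals,
        }
    )

    var_r = float(result.cov_re.iloc[0, 0])
    var_s = float(result.vcomp[0]) if len(result.vcomp) else 0.0
    var_e = float(result.scale)
    # standard errors of the variance parameters from the ML information
    # matrix; statsmodels reports them after the fixed-effect block
    bse_all = np.asarray(result.bse)
    se_var_r = bse_all[k_fe] if len(bse_all) > k_fe else np.nan
    se_var_s = bse_all[k_fe + 1] if len(bse_all) > k_fe + 1 else np.nan
    sd_r, sd_s, sd_e = np.sqrt(var_r), np.sqrt(var_s), np.sqrt(var_e)
    # residual variance is profiled out; chi-square approximation for its CI
    se_var_e = var_e * np.sqrt(2.0 / dof)
    random = pd.DataFrame(
        {
            "sd": [sd_r, sd_s, sd_e],
            "ci_low": [
                _sd_ci(sd_r, se_var_r)[0],
                _sd_ci(sd_s, se_var_s)[0],
                _sd_ci(sd_e, se_var_e)[0],
            ],
            "ci_high": [
                _sd_ci(sd_r, se_var_r)[1],
                _sd_ci(sd_s, se_var_s)[1],
                _sd_ci(sd_e, se_var_e)[1],
            ],
        },
        index=["sigma_r", "sigma_s", "sigma_eps"],
    )

    total_var = var_r + var_s + var_e
    boundary = bool(min(var_r, var_s) < 1e-6 * total_var)
    if boundary:
        warnings.warn(
            f"{spec.name}: a random-effect variance is on the boundary (singular fit)",
            RuntimeWarning,
            stacklevel=2,
        )
    return MixedModelFit(
        spec_name=spec.name,
        fixed=fixed,
        random=random,
        n_obs=n,
        converged=bool(result.converged),
        boundary=boundary,
    )
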