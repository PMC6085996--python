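"""Ground-truth generators standing in for the study's rats.

Three families of synthetic data, all deterministic under a fixed seed and
all serialized with a ground-truth record sufficient to score recovery
experiments:

* agent-driven choice cohorts: rats x sessions x laps of two-step task
  behavior generated by the package's own agent models, with per-rat
  parameter jitter for cohort heterogeneity;
* 2-D trajectories through an idealized maze with controllable head-sweep
  (VTE) injection at either choice point and additive path noise;
* per-lap mixed-model datasets with known fixed coefficients and
  rat/session variance components, built on the covariate structure of a
  generated cohort.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .agents import AgentParams, simulate_session
from .metrics import Trajectory, Zone
from .stats import MixedModelSpec
from .task import LapRecord, TaskConfig

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "PRESETS",
    "DEFAULT_ZONES",
    "gen_cohort",
    "gen_random_baseline",
    "gen_trajectory",
    "gen_lmm_dataset",
    "laps_to_frame",
    "frame_to_sessions",
]

#: agent parameter presets: the simulation settings used for the
#: model-free / model-based signature figures, the zero-learning random
#: baseline, and a hybrid with a mid-range model-based weight
PRESETS = {
    "mf": AgentParams(alpha1=0.5, alpha2=0.5, lam=0.0, beta1=3.0, beta2=3.0, p=0.3),
    "mb": AgentParams(alpha2=0.5, beta1=3.0, beta2=3.0, p=0.3),
    "hybrid": AgentParams(
        alpha1=0.5, alpha2=0.5, lam=0.0, beta1=3.0, beta2=3.0, p=0.3, w=0.65
    ),
    "random": AgentParams(alpha1=0.0, alpha2=0.0, lam=0.0, beta1=3.0, beta2=3.0, p=0.0),
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort scale: defaults mirror the study (7 rats, ~51 sessions each,
    ~74 laps per session) with 10% CV per-rat parameter jitter."""

    n_rats: int = 7
    sessions_per_rat: int = 51
    laps_per_session: int = 74
    param_jitter_cv: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if min(self.n_rats, self.sessions_per_rat, self.laps_per_session) < 1:
            raise ValueError("counts must be positive")
        if self.param_jitter_cv < 0:
            raise ValueError("param_jitter_cv must be >= 0")


@dataclass
class GroundTruth:
    """Everything needed to score a recovery experiment on a generated
    dataset."""

    kind: str
    algorithm: str | None = None
    params: dict | None = None
    params_by_rat: dict | None = None
    coefficients: dict | None = None
    variance_components: dict | None = None
    vte_labels: dict | None = None
    cohort: dict | None = None
    task: dict | None = None
    seed: int | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=float)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# lap-event frames


_LAP_COLUMNS = [
    "rat_id",
    "session_id",
    "lap",
    "choice1",
    "context",
    "transition",
    "choice2",
    "end_state",
    "delay_s",
    "reward",
    "p_choice1",
    "p_choice2",
]


def laps_to_frame(records: list, rat_id, session_id) -> pd.DataFrame:
    """One session of LapRecord -> lap-event table rows (laps 1-based)."""
    return pd.DataFrame(
        {
            "rat_id": rat_id,
            "session_id": session_id,
            "lap": [r.lap_index + 1 for r in records],
            "choice1": [r.choice1 for r in records],
            "context": [r.context for r in records],
            "transition": [r.transition for r in records],
            "choice2": [r.choice2 for r in records],
            "end_state": [r.end_state for r in records],
            "delay_s": [r.delay for r in records],
            "reward": [r.reward for r in records],
            "p_choice1": [r.p_choice1 for r in records],
            "p_choice2": [r.p_choice2 for r in records],
        }
    )


def frame_to_sessions(df: pd.DataFrame) -> list:
    """Lap-event table -> list of sessions (lists of LapRecord)."""
    sessions = []
    for _, g in df.sort_values(["rat_id", "session_id", "lap"]).groupby(
        ["rat_id", "session_id"], sort=False
    ):
        sessions.append(
            [
                LapRecord(
                    lap_index=int(row.lap) - 1,
                    choice1=row.choice1,
                    context=row.context,
                    transition=row.transition,
                    choice2=row.choice2,
                    end_state=row.end_state,
                    delay=float(row.delay_s),
                    reward=float(row.reward),
                    p_choice1=None if pd.isna(row.p_choice1) else float(row.p_choice1),
                    p_choice2=None if pd.isna(row.p_choice2) else float(row.p_choice2),
                )
                for row in g.itertuples()
            ]
        )
    return sessions


def _jitter_params(params: AgentParams, cv: float, rng) -> AgentParams:
    """Multiplicative per-rat jitter, clipped to each parameter's bounds;
    exactly-zero parameters stay zero."""
    out = {}
    for name in ("alpha1", "alpha2", "lam", "beta1", "beta2", "p", "w"):
        v = getattr(params, name)
        if cv > 0 and v != 0:
            v = v * (1.0 + cv * rng.standard_normal())
        if name in ("alpha1", "alpha2", "lam", "w"):
            v = float(np.clip(v, 0.0, 1.0))
        elif name in ("beta1", "beta2"):
            v = float(max(v, 0.0))
        out[name] = float(v)
    return AgentParams(**out)


def gen_cohort(
    cfg: CohortConfig,
    algorithm: str,
    params: AgentParams,
    task_cfg: TaskConfig | None = None,
    seed=None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a full cohort; returns the lap-event table and ground truth.

    Session ids are globally unique strings ``r{rat}s{session}`` so session
    random effects are trivially nested within rat.
    """
    if task_cfg is None:
        task_cfg = TaskConfig(n_laps=cfg.laps_per_session)
    seed = cfg.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    rat_seeds = root.spawn(cfg.n_rats)
    frames = []
    params_by_rat = {}
    for r in range(1, cfg.n_rats + 1):
        rng = np.random.default_rng(rat_seeds[r - 1])
        rat_params = _jitter_params(params, cfg.param_jitter_cv, rng)
        params_by_rat[str(r)] = asdict(rat_params)
        for s in range(1, cfg.sessions_per_rat + 1):
            records = simulate_session(rat_params, algorithm, task_cfg, rng)
            frames.append(laps_to_frame(records, r, f"r{r}s{s:03d}"))
    df = pd.concat(frames, ignore_index=True)[_LAP_COLUMNS]
    truth = GroundTruth(
        kind="cohort",
        algorithm=algorithm,
        params=asdict(params),
        params_by_rat=params_by_rat,
        cohort=asdict(cfg),
        task=asdict(task_cfg),
        seed=seed,
    )
    return df, truth


def gen_random_baseline(
    cfg: CohortConfig, task_cfg: TaskConfig | None = None, seed=None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Zero-learning-rate (random choice) cohort: with all Q values equal
    and no learning, every choice probability is exactly 0.5."""
    cfg = CohortConfig(
        n_rats=cfg.n_rats,
        sessions_per_rat=cfg.sessions_per_rat,
        laps_per_session=cfg.laps_per_session,
        param_jitter_cv=0.0,
        seed=cfg.seed,
    )
    return gen_cohort(cfg, "mf", PRESETS["random"], task_cfg=task_cfg, seed=seed)


# ---------------------------------------------------------------------------
# trajectories

#: idealized maze geometry, arbitrary length units: a start corridor, a
#: first T (CP1), converging corridors to a second T (CP2), feeder arms
DEFAULT_ZONES = {
    "choice1": Zone(-8.0, 8.0, 13.0, 27.0, label="choice1"),
    "choice2": Zone(-8.0, 8.0, 53.0, 67.0, label="choice2"),
}

_CP1 = np.array([0.0, 20.0])
_CP2 = np.array([0.0, 60.0])


def _route_waypoints(choice1: str, choice2: str) -> np.ndarray:
    s1 = -1.0 if choice1 == "A" else 1.0
    s2 = -1.0 if choice2 == "left" else 1.0
    return np.array(
        [
            [0.0, -15.0],
            [0.0, 14.0],
            _CP1,
            [s1 * 12.0, 20.0],
            [s1 * 25.0, 20.0],
            [s1 * 25.0, 33.0],
            [s1 * 12.0, 46.0],
            [0.0, 53.0],
            _CP2,
            [s2 * 12.0, 60.0],
            [s2 * 25.0, 60.0],
            [s2 * 25.0, 72.0],
        ]
    )


def _constant_speed_path(waypoints: np.ndarray, speed: float, fs: float) -> np.ndarray:
    seg = np.diff(waypoints, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = s[-1]
    n = max(int(np.floor(total / speed * fs)) + 1, 2)
    si = np.linspace(0.0, total, n)
    x = np.interp(si, s, waypoints[:, 0])
    y = np.interp(si, s, waypoints[:, 1])
    return np.column_stack([x, y])


def _sweep_angles(theta0: float, n_sweeps: int, amplitude_rad: float, n: int) -> np.ndarray:
    """Piecewise-linear head-angle zigzag with ``n_sweeps`` alternating
    sweeps of ``amplitude_rad`` each (total variation n_sweeps*amplitude)."""
    knots = [theta0]
    sign = 1.0
    for _ in range(n_sweeps):
        knots.append(knots[-1] + sign * amplitude_rad)
        sign = -sign
    knots = np.array(knots)
    u = np.linspace(0.0, 1.0, len(knots))
    return np.interp(np.linspace(0.0, 1.0, n), u, knots)


def gen_trajectory(
    lap: LapRecord,
    vte_cp1: bool = False,
    vte_cp2: bool = False,
    noise_sd: float = 0.3,
    seed=0,
    fs: float = 30.0,
    speed: float = 25.0,
    n_sweeps: int = 2,
    sweep_amplitude_deg: float = 150.0,
    dwell_s: float = 1.5,
    head_lead: float = 5.0,
) -> Trajectory:
    """Synthesize one lap's trajectory through the idealized maze.

    The body follows a smooth constant-speed route matching the lap's
    choices; the head leads the body along the heading by ``head_lead``
    units.  Where a VTE flag is set, a ``dwell_s`` pause is inserted at the
    zone center during which the head performs ``n_sweeps`` back-and-forth
    sweeps of ``sweep_amplitude_deg`` each.  Gaussian positional noise of
    SD ``noise_sd`` is added to both traces.
    """
    rng = np.random.default_rng(seed)
    body = _constant_speed_path(_route_waypoints(lap.choice1, lap.choice2), speed, fs)
    body = gaussian_filter1d(body, 2.0, axis=0, mode="nearest")
    grad = np.gradient(body, axis=0)
    norms = np.linalg.norm(grad, axis=1, keepdims=True)
    heading = grad / np.maximum(norms, 1e-12)
    head = body + head_lead * heading
    theta = np.arctan2(heading[:, 1], heading[:, 0])

    n_dwell = int(round(dwell_s * fs))
    amp = np.radians(sweep_amplitude_deg)
    # insert dwells from the later zone backwards so indices stay valid
    inserts = []
    if vte_cp2:
        inserts.append(_CP2)
    if vte_cp1:
        inserts.append(_CP1)
    for center in inserts:
        i = int(np.argmin(np.linalg.norm(body - center, axis=1)))
        sweep = _sweep_angles(theta[i], n_sweeps, amp, n_dwell)
        body_block = np.repeat(body[i : i + 1], n_dwell, axis=0)
        head_block = body_block + head_lead * np.column_stack(
            [np.cos(sweep), np.sin(sweep)]
        )
        body = np.concatenate([body[: i + 1], body_block, body[i + 1 :]])
        head = np.concatenate([head[: i + 1], head_block, head[i + 1 :]])
        theta = np.concatenate([theta[: i + 1], sweep, theta[i + 1 :]])

    n = len(body)
    t = np.arange(n) / fs
    if noise_sd > 0:
        body = body + rng.normal(0.0, noise_sd, size=body.shape)
        head = head + rng.normal(0.0, noise_sd, size=head.shape)
    return Trajectory(t, body, head)


# ---------------------------------------------------------------------------
# mixed-model datasets


def add_derived_covariates(laps: pd.DataFrame) -> pd.DataFrame:
    """Add rare/rare_prev/repeat/delay_prev columns to a lap-event table."""
    df = laps.sort_values(["rat_id", "session_id", "lap"]).copy()
    grp = df.groupby(["rat_id", "session_id"], sort=False)
    df["rare"] = (df["transition"] == "rare").astype(float)
    df["rare_prev"] = grp["rare"].shift()
    df["delay_prev"] = grp["delay_s"].shift()
    same1 = df["choice1"] == grp["choice1"].shift()
    same2 = df["choice2"] == grp["choice2"].shift()
    df["repeat"] = (same1 & same2).astype(float)
    df.loc[grp.cumcount() == 0, "repeat"] = 0.0
    return df


def gen_lmm_dataset(
    spec: MixedModelSpec,
    coefficients: dict,
    variance_components: dict,
    cfg: CohortConfig,
    seed=0,
    base_laps: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-lap table with a response generated from known truth.

    Covariates come from a real cohort simulation (or ``base_laps``), so
    transition/repeat/delay structure matches the task process.  The
    response is built from the design matrix of ``spec.fixed`` with the
    given ``coefficients`` (design-column name -> value; missing -> 0),
    plus rat and session random intercepts drawn with SDs ``sigma_r`` and
    ``sigma_s`` and Gaussian residuals with SD ``sigma_eps``.
    """
    import patsy

    rng = np.random.default_rng(seed)
    if base_laps is None:
        base_laps, _ = gen_cohort(cfg, "mf", PRESETS["mf"], seed=int(rng.integers(2**31)))
    df = add_derived_covariates(base_laps)
    # predictors that are measurements rather than task covariates are
    # synthesized as standard normals (e.g. z-scored VTE at CP1)
    for term in ("zlogidphi1",):
        if term in spec.fixed and term not in df.columns:
            df[term] = rng.standard_normal(len(df))
    if spec.drop_first_lap:
        first = df.groupby(["rat_id", "session_id"], sort=False)["lap"].transform("min")
        df = df[df["lap"] > first].reset_index(drop=True)

    X = patsy.dmatrix(spec.fixed, df, return_type="dataframe")
    beta = np.array([float(coefficients.get(c, 0.0)) for c in X.columns])
    sigma_r = float(variance_components.get("sigma_r", 0.0))
    sigma_s = float(variance_components.get("sigma_s", 0.0))
    sigma_e = float(variance_components.get("sigma_eps", 0.0))
    rat_fx = {r: rng.normal(0.0, sigma_r) for r in df["rat_id"].unique()}
    ses_fx = {s: rng.normal(0.0, sigma_s) for s in df["session_id"].unique()}
    df[spec.response] = (
        X.to_numpy() @ beta
        + df["rat_id"].map(rat_fx).to_numpy()
        + df["session_id"].map(ses_fx).to_numpy()
        + rng.normal(0.0, sigma_e, size=len(df))
    )
    truth = GroundTruth(
        kind="lmm",
        coefficients={c: float(coefficients.get(c, 0.0)) for c in X.columns},
        variance_components={
            "sigma_r": sigma_r,
            "sigma_s": sigma_s,
            "sigma_eps": sigma_e,
        },
        cohort=asdict(cfg),
        seed=seed,
    )
    return df, truth
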