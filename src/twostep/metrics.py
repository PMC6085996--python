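"""Trajectory-derived deliberation measures.

Vicarious trial and error (VTE) is quantified per choice-point pass by
LogIdPhi: the natural log of the integrated absolute angular velocity of
the head while the animal is inside the choice-point zone,

    LogIdPhi = log( integral_{zone entry}^{zone exit} |d/dt atan2(dy/dt, dx/dt)| dt )

Heading is computed from Gaussian-smoothed head positions, and the angle
series is unwrapped so a continuous 180-degree sweep contributes 180
degrees rather than a wrap artifact.  Angles are measured in degrees by
default (a config switch), which puts typical non-VTE passes near
log(40..80).

Path stereotypy is the inverse of the mean time-resampled distance
between a lap's path and all other same-session paths of the same type
(LL/LR/RL/RR); larger values mean more procedural, repeatable running.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from sklearn.mixture import GaussianMixture

from .task import LapRecord

__all__ = [
    "Trajectory",
    "Zone",
    "LapExcluded",
    "logidphi",
    "fit_vte_threshold",
    "classify_vte",
    "path_stereotypy",
    "choice_repeat_counts",
    "resample_path",
]


class LapExcluded(Exception):
    """A lap that cannot be measured; carries the exclusion reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class Trajectory:
    """Timestamped body and head positions for one session or lap.

    ``t`` must be strictly increasing; positions are (n, 2) arrays in maze
    length units.
    """

    t: np.ndarray
    body: np.ndarray
    head: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("t must be a 1-D array with at least 2 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing")
        for name in ("body", "head"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(t), 2):
                raise ValueError(f"{name} must have shape (len(t), 2)")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "body", np.asarray(self.body, dtype=float))
        object.__setattr__(self, "head", np.asarray(self.head, dtype=float))

    def slice(self, i0: int, i1: int) -> "Trajectory":
        return Trajectory(self.t[i0:i1], self.body[i0:i1], self.head[i0:i1])


@dataclass(frozen=True)
class Zone:
    """Axis-aligned rectangular choice-point zone in maze coordinates."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float
    label: str = ""

    def __post_init__(self):
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError("zone must have nonzero area")

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return (
            (xy[:, 0] >= self.xmin)
            & (xy[:, 0] <= self.xmax)
            & (xy[:, 1] >= self.ymin)
            & (xy[:, 1] <= self.ymax)
        )


def _zone_pass(traj: Trajectory, zone: Zone) -> tuple[int, int]:
    """Sample index range [i0, i1) of the pass: first entry to last exit."""
    inside = zone.contains(traj.head)
    idx = np.flatnonzero(inside)
    if len(idx) < 3:
        raise LapExcluded(f"fewer than 3 tracking samples inside zone {zone.label!r}")
    return int(idx[0]), int(idx[-1]) + 1


def logidphi(
    traj: Trajectory,
    zone: Zone,
    smooth_sigma: float = 2.0,
    units: str = "deg",
    eps: float = 1e-3,
    max_gap_factor: float = 5.0,
) -> float:
    """LogIdPhi of one choice-point pass.

    Parameters
    ----------
    traj : Trajectory
        The lap's trajectory (may extend beyond the zone).
    zone : Zone
        Choice-point zone; the pass runs from first entry to last exit of
        the head position.
    smooth_sigma : float
        Gaussian smoothing of the head coordinates, in samples, applied
        before finite differencing (tames tracking jitter).
    units : {"deg", "rad"}
        Angular units of the integrated sweep before the log.
    eps : float
        Floor on the total sweep before the log (avoids log(0) on a
        perfectly straight pass).
    max_gap_factor : float
        A time gap inside the zone larger than this multiple of the median
        sampling interval raises :class:`LapExcluded` (tracking lag).
    """
    if units not in ("deg", "rad"):
        raise ValueError("units must be 'deg' or 'rad'")
    i0, i1 = _zone_pass(traj, zone)
    t = traj.t[i0:i1]
    dt = np.diff(t)
    med = float(np.median(np.diff(traj.t)))
    if np.any(dt > max_gap_factor * med):
        raise LapExcluded(f"tracking gap inside zone {zone.label!r}")
    head = traj.head[i0:i1]
    if smooth_sigma > 0:
        head = gaussian_filter1d(head, smooth_sigma, axis=0, mode="nearest")
    dx = np.gradient(head[:, 0], t)
    dy = np.gradient(head[:, 1], t)
    phi = np.unwrap(np.arctan2(dy, dx))
    sweep = float(np.sum(np.abs(np.diff(phi))))  # radians
    if units == "deg":
        sweep = np.degrees(sweep)
    return float(np.log(max(sweep, eps)))


def fit_vte_threshold(
    values,
    random_state: int = 0,
    min_ashman_d: float = 2.0,
) -> float:
    """VTE/non-VTE threshold from the pooled LogIdPhi distribution.

    Fits a two-component Gaussian mixture and returns the point of equal
    posterior responsibility between the two components, searched between
    the component means.  If the fitted components are not genuinely
    bimodal (Ashman's D = |m1 - m2| / sqrt((s1^2 + s2^2) / 2) below
    ``min_ashman_d``), a warning is issued and the midpoint of the
    distribution's range is returned.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 100:
        raise ValueError("need at least 100 values to fit a threshold")
    gm = GaussianMixture(n_components=2, random_state=random_state, n_init=3)
    gm.fit(values.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    order = np.argsort(means)
    m_lo, m_hi = means[order]
    ashman_d = (m_hi - m_lo) / np.sqrt(0.5 * float(np.sum(sds**2)))
    if ashman_d < min_ashman_d:
        warnings.warn(
            "degenerate mixture fit (component means nearly coincide); "
            "falling back to the distribution midpoint",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(0.5 * (values.min() + values.max()))
    # equal-responsibility point: grid + bisection on the responsibility gap
    grid = np.linspace(m_lo, m_hi, 1001)
    resp = gm.predict_proba(grid.reshape(-1, 1))
    diff = resp[:, order[1]] - resp[:, order[0]]
    sign_change = np.flatnonzero(np.diff(np.sign(diff)) != 0)
    if len(sign_change) == 0:  # pragma: no cover - extreme weight imbalance
        return float(0.5 * (m_lo + m_hi))
    k = sign_change[0]
    # linear interpolation of the crossing
    x0, x1, d0, d1 = grid[k], grid[k + 1], diff[k], diff[k + 1]
    return float(x0 - d0 * (x1 - x0) / (d1 - d0)) if d1 != d0 else float(x0)


def classify_vte(value: float, threshold: float) -> bool:
    """True iff the LogIdPhi value strictly exceeds the threshold."""
    return bool(value > threshold)


def resample_path(path: np.ndarray, n_resample: int) -> np.ndarray:
    """Resample an (n, 2) path to ``n_resample`` points uniform in
    normalized lap time (samples assumed uniformly spaced in time)."""
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[1] != 2 or len(path) < 2:
        raise ValueError("path must be an (n>=2, 2) array")
    u = np.linspace(0.0, 1.0, len(path))
    uu = np.linspace(0.0, 1.0, n_resample)
    return np.column_stack([np.interp(uu, u, path[:, 0]), np.interp(uu, u, path[:, 1])])


def path_stereotypy(
    lap_path: np.ndarray,
    same_type_paths: list,
    n_resample: int = 100,
    eps: float = 1e-6,
) -> float:
    """Inverse of the mean time-resampled distance to same-type paths.

    Each path is resampled to ``n_resample`` points uniform in normalized
    lap time; the distance to one comparison path is the mean pointwise
    Euclidean distance, and the stereotypy value is the inverse of the mean
    of those distances over all comparison paths (floored at ``eps`` before
    inversion).  A lap with no same-session, same-type comparison path is
    excluded.
    """
    if not same_type_paths:
        raise LapExcluded("only lap of its path type in the session")
    ref = resample_path(lap_path, n_resample)
    dists = []
    for other in same_type_paths:
        o = resample_path(other, n_resample)
        dists.append(float(np.mean(np.linalg.norm(ref - o, axis=1))))
    return 1.0 / max(float(np.mean(dists)), eps)


def choice_repeat_counts(session_laps: list) -> list:
    """Running count of consecutive repeated (choice1, choice2) pairs.

    The counter is 0 on the first lap and on any lap whose choice pair
    differs from the previous lap's, and otherwise increments.
    """
    counts = []
    prev = None
    run = 0
    for lap in session_laps:
        pair = (lap.choice1, lap.choice2)
        run = run + 1 if pair == prev else 0
        counts.append(run)
        prev = pair
    return counts
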