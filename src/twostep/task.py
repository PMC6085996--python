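"""Executable model of the spatial two-step task.

The task has a first-stage choice (state C1, options A/B) that leads
probabilistically to one of two second-stage choice contexts (C2 or C3,
options left/right).  Choosing A commonly (probability ``p_common``) leads
to C2 and rarely to C3; the mapping is reversed for B.  Each of the four
end states (C, D, E, F) carries a delay-to-food cost that drifts across
laps as a bounded Gaussian random walk.  Reward is modelled as
``max_delay - delay``: low-delay feeders are high-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "TaskConfig",
    "DelayState",
    "LapRecord",
    "END_STATES",
    "COMMON_CONTEXT",
    "end_state_for",
    "init_delays",
    "step_delays",
    "sample_transition",
    "compute_reward",
    "run_lap",
]

#: end state reached by each (second-stage context, second-stage action)
END_STATES: Mapping[tuple, str] = {
    ("C2", "left"): "C",
    ("C2", "right"): "D",
    ("C3", "left"): "E",
    ("C3", "right"): "F",
}

#: the second-stage context commonly produced by each first-stage choice
COMMON_CONTEXT: Mapping[str, str] = {"A": "C2", "B": "C3"}

STAGE1_ACTIONS = ("A", "B")
STAGE2_ACTIONS = ("left", "right")


def _as_rng(seed) -> np.random.Generator:
    """Accept an integer seed or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class TaskConfig:
    """Task structure parameters.

    Parameters
    ----------
    p_common : float
        Probability that the first-stage choice leads to its commonly
        associated second-stage context.  Must satisfy ``0.5 < p_common <= 1``.
    min_delay, max_delay : float
        Bounds on the delay-to-food cost, in seconds.
    walk_sd : float
        Standard deviation (s/lap) of the Gaussian random walk applied to
        each end state's delay once per lap.
    n_laps : int
        Laps per simulated session.
    boundary : {"clip", "reflect"}
        How the delay walk is kept inside ``[min_delay, max_delay]``.
    """

    p_common: float = 0.8
    min_delay: float = 1.0
    max_delay: float = 30.0
    walk_sd: float = 1.0
    n_laps: int = 74
    boundary: str = "clip"

    def __post_init__(self):
        if not (0.5 < self.p_common <= 1.0):
            raise ValueError(f"p_common must be in (0.5, 1], got {self.p_common}")
        if not (0 < self.min_delay < self.max_delay):
            raise ValueError("require 0 < min_delay < max_delay")
        if self.walk_sd < 0:
            raise ValueError("walk_sd must be >= 0")
        if self.n_laps < 1:
            raise ValueError("n_laps must be >= 1")
        if self.boundary not in ("clip", "reflect"):
            raise ValueError("boundary must be 'clip' or 'reflect'")

    @property
    def mean_initial_delay(self) -> float:
        return 0.5 * (self.min_delay + self.max_delay)

    @property
    def mean_reward(self) -> float:
        """Expected reward under the uniform initial delay distribution."""
        return self.max_delay - self.mean_initial_delay


@dataclass(frozen=True)
class DelayState:
    """Current delay (s) at each of the four end states C, D, E, F."""

    delays: Mapping[str, float]

    def __post_init__(self):
        if set(self.delays) != {"C", "D", "E", "F"}:
            raise ValueError("delays must have exactly the keys C, D, E, F")

    def as_array(self) -> np.ndarray:
        return np.array([self.delays[s] for s in "CDEF"], dtype=float)


@dataclass(frozen=True)
class LapRecord:
    """One trial of the two-step task.

    ``transition`` is "common" iff the second-stage context is the one
    usually produced by the first-stage choice.  ``reward`` always equals
    ``max_delay - delay``.  ``p_choice1``/``p_choice2`` are optional audit
    fields holding the probability the generating agent assigned to the
    action it actually took.
    """

    lap_index: int
    choice1: str
    context: str
    transition: str
    choice2: str
    end_state: str
    delay: float
    reward: float
    p_choice1: float | None = None
    p_choice2: float | None = None

    def __post_init__(self):
        if self.choice1 not in STAGE1_ACTIONS:
            raise ValueError(f"invalid choice1 {self.choice1!r}")
        if self.choice2 not in STAGE2_ACTIONS:
            raise ValueError(f"invalid choice2 {self.choice2!r}")
        if self.context not in ("C2", "C3"):
            raise ValueError(f"invalid context {self.context!r}")
        expected = "common" if COMMON_CONTEXT[self.choice1] == self.context else "rare"
        if self.transition != expected:
            raise ValueError(
                f"transition {self.transition!r} inconsistent with "
                f"choice1={self.choice1}, context={self.context}"
            )
        if self.end_state != END_STATES[(self.context, self.choice2)]:
            raise ValueError("end_state inconsistent with (context, choice2)")


def end_state_for(context: str, choice2: str) -> str:
    return END_STATES[(context, choice2)]


def init_delays(cfg: TaskConfig, seed) -> DelayState:
    """Draw the four starting delays independently, uniform on the bounds."""
    rng = _as_rng(seed)
    draws = rng.uniform(cfg.min_delay, cfg.max_delay, size=4)
    return DelayState(dict(zip("CDEF", draws)))


def _bound(x: np.ndarray, lo: float, hi: float, how: str) -> np.ndarray:
    if how == "clip":
        return np.clip(x, lo, hi)
    # reflect off both walls; a single fold per wall suffices for small steps,
    # iterate for robustness under large walk_sd
    span = hi - lo
    y = np.asarray(x, dtype=float).copy()
    for _ in range(64):
        below = y < lo
        above = y > hi
        if not (below.any() or above.any()):
            break
        y[below] = 2 * lo - y[below]
        y[above] = 2 * hi - y[above]
        if span <= 0:
            break
    return np.clip(y, lo, hi)


def step_delays(state: DelayState, cfg: TaskConfig, seed) -> DelayState:
    """Advance every end state's delay one lap of the bounded random walk."""
    rng = _as_rng(seed)
    arr = state.as_array()
    arr = arr + rng.normal(0.0, cfg.walk_sd, size=4) if cfg.walk_sd > 0 else arr
    arr = _bound(arr, cfg.min_delay, cfg.max_delay, cfg.boundary)
    return DelayState(dict(zip("CDEF", arr)))


def sample_transition(choice1: str, cfg: TaskConfig, seed) -> tuple[str, str]:
    """Sample the second-stage context produced by a first-stage choice."""
    if choice1 not in STAGE1_ACTIONS:
        raise ValueError(f"invalid choice1 {choice1!r}")
    rng = _as_rng(seed)
    common = rng.random() < cfg.p_common
    if common:
        context = COMMON_CONTEXT[choice1]
    else:
        context = "C3" if COMMON_CONTEXT[choice1] == "C2" else "C2"
    return context, ("common" if common else "rare")


def compute_reward(delay: float, cfg: TaskConfig) -> float:
    """Reward is the distance of the experienced delay from the maximum."""
    if not (cfg.min_delay <= delay <= cfg.max_delay):
        raise ValueError(f"delay {delay} outside [{cfg.min_delay}, {cfg.max_delay}]")
    return cfg.max_delay - delay


def run_lap(
    state: DelayState,
    choice_fn: Callable[[str], str],
    cfg: TaskConfig,
    seed,
    lap_index: int = 0,
) -> tuple[LapRecord, DelayState]:
    """Execute one full lap.

    ``choice_fn(state_label)`` is called with "C1" for the first-stage choice
    (must return "A" or "B") and with the realized context ("C2"/"C3") for the
    second-stage choice (must return "left" or "right").  Delays are stepped
    once, after the lap's outcome is realized.
    """
    rng = _as_rng(seed)
    choice1 = choice_fn("C1")
    if choice1 not in STAGE1_ACTIONS:
        raise ValueError(f"choice_fn returned invalid first-stage action {choice1!r}")
    context, transition = sample_transition(choice1, cfg, rng)
    choice2 = choice_fn(context)
    if choice2 not in STAGE2_ACTIONS:
        raise ValueError(f"choice_fn returned invalid second-stage action {choice2!r}")
    end_state = END_STATES[(context, choice2)]
    delay = float(state.delays[end_state])
    reward = compute_reward(delay, cfg)
    record = LapRecord(
        lap_index=lap_index,
        choice1=choice1,
        context=context,
        transition=transition,
        choice2=choice2,
        end_state=end_state,
        delay=delay,
        reward=reward,
    )
    return record, step_delays(state, cfg, rng)
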