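"""Reinforcement-learning agents for the two-step task.

Three valuation algorithms share one state-action value table:

* model-free ("mf"): SARSA(lambda).  Stage-1 values are cached and updated
  twice per trial -- once by the delta rule after the transition (learning
  rate alpha1, with zero intermediate reward), and once at trial end by the
  eligibility trace (effective rate alpha1*lambda applied to the stage-2
  prediction error).
* model-based ("mb"): stage-2 values learned by the same delta rule
  (alpha2); stage-1 values computed at decision time from the known
  transition probabilities and the best stage-2 option.
* constant-weight hybrid ("hybrid"): stage-1 action values are
  w*Q_MB + (1-w)*Q_MF with both components running simultaneously and
  sharing parameters; w=1 reduces exactly to model-based, w=0 to
  model-free.

Choices follow a softmax over ``beta * (Q + p * rep)``, where ``rep`` marks
the action taken at the same stage on the previous lap (perseveration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_softmax

from .task import (
    STAGE1_ACTIONS,
    STAGE2_ACTIONS,
    DelayState,
    LapRecord,
    TaskConfig,
    compute_reward,
    end_state_for,
    init_delays,
    sample_transition,
    step_delays,
    _as_rng,
)

__all__ = [
    "AgentParams",
    "QState",
    "ALGORITHMS",
    "init_q",
    "mf_stage_update",
    "mf_end_of_trial_update",
    "mb_first_stage_values",
    "hybrid_values",
    "choice_probabilities",
    "simulate_session",
]

ALGORITHMS = ("mf", "mb", "hybrid")

_STATE_INDEX = {"C1": 0, "C2": 1, "C3": 2}
# at C1 the physical actions are left/right; A is the left option
_ACTION_INDEX = {"A": 0, "B": 1, "left": 0, "right": 1}


@dataclass(frozen=True)
class AgentParams:
    """Free parameters theta of the agents.

    alpha1, alpha2 : stage-1 / stage-2 learning rates in [0, 1]
    lam            : eligibility-trace parameter lambda in [0, 1]
    beta1, beta2   : stage-1 / stage-2 softmax inverse temperatures (>= 0)
    p              : perseveration weight (any real; >0 repeats, <0 switches)
    w              : model-based weight in [0, 1]; used only by the hybrid

    The pure model-based agent ignores alpha1, lam and w; the pure
    model-free agent ignores w.
    """

    alpha1: float = 0.0
    alpha2: float = 0.0
    lam: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    p: float = 0.0
    w: float = 0.0

    def __post_init__(self):
        for name in ("alpha1", "alpha2", "lam", "w"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("beta1", "beta2"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


class QState:
    """State-action value table for states C1/C2/C3 x actions left/right.

    A terminal ("virtual") post-reward state has value identically 0 and is
    never stored or updated.
    """

    __slots__ = ("q",)

    def __init__(self, q: np.ndarray):
        q = np.asarray(q, dtype=float)
        if q.shape != (3, 2):
            raise ValueError("q must have shape (3, 2)")
        self.q = q

    def copy(self) -> "QState":
        return QState(self.q.copy())

    def value(self, state: str, action: str) -> float:
        return float(self.q[_STATE_INDEX[state], _ACTION_INDEX[action]])

    def set_value(self, state: str, action: str, v: float) -> None:
        self.q[_STATE_INDEX[state], _ACTION_INDEX[action]] = v

    def __repr__(self):  # pragma: no cover
        return f"QState({self.q!r})"


def init_q(cfg: TaskConfig) -> QState:
    """All six values start at the mean reward (max_delay minus the mean
    initial delay; 14.5 s with defaults)."""
    return QState(np.full((3, 2), cfg.mean_reward))


def mf_stage_update(
    q: QState,
    s: str,
    a: str,
    r: float,
    s_next: str | None,
    a_next: str | None,
    alpha: float,
) -> QState:
    """Delta-rule update of Q(s, a) toward r + Q(s_next, a_next).

    ``s_next=None`` denotes the terminal state (value 0).  Returns a new
    QState; the input is not mutated.
    """
    out = q.copy()
    v_next = 0.0 if s_next is None else q.value(s_next, a_next)
    delta = r + v_next - q.value(s, a)
    out.set_value(s, a, q.value(s, a) + alpha * delta)
    return out


def mf_end_of_trial_update(
    q: QState, s1: str, a1: str, delta2: float, alpha1: float, lam: float
) -> QState:
    """Eligibility-trace update: Q(s1, a1) += alpha1 * lam * delta2."""
    out = q.copy()
    out.set_value(s1, a1, q.value(s1, a1) + alpha1 * lam * delta2)
    return out


def mb_first_stage_values(q: QState, cfg: TaskConfig) -> tuple[float, float]:
    """Model-based values of A and B at decision time.

    Q_MB(C1, a) = p(C2|a) * max Q(C2, .) + p(C3|a) * max Q(C3, .) with the
    transition probabilities fixed at (p_common, 1 - p_common).
    """
    max_c2 = float(q.q[1].max())
    max_c3 = float(q.q[2].max())
    pc = cfg.p_common
    value_a = pc * max_c2 + (1.0 - pc) * max_c3
    value_b = (1.0 - pc) * max_c2 + pc * max_c3
    return value_a, value_b


def hybrid_values(q_mb, q_mf, w: float):
    """Elementwise weighted average w*Q_MB + (1-w)*Q_MF."""
    if not (0.0 <= w <= 1.0):
        raise ValueError("w must be in [0, 1]")
    return tuple(w * mb + (1.0 - w) * mf for mb, mf in zip(q_mb, q_mf))


def choice_probabilities(values, beta: float, p: float, prev_action: int | None):
    """Softmax choice probabilities with perseveration.

    P(a) is proportional to exp(beta * (Q(a) + p * rep(a))) where rep(a)=1
    iff ``a`` equals the same-stage action index on the previous trial.  On
    the first trial of a session pass ``prev_action=None`` (rep is 0 for
    both actions).  Computed via a log-sum-exp so probabilities stay finite
    for any parameter values.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    logits = beta * np.asarray(values, dtype=float)
    if prev_action is not None:
        rep = np.zeros(len(logits))
        rep[prev_action] = 1.0
        logits = logits + beta * p * rep
    return np.exp(log_softmax(logits))


def _stage1_values(q: QState, algorithm: str, params: AgentParams, cfg: TaskConfig):
    if algorithm == "mf":
        return q.q[0, 0], q.q[0, 1]
    if algorithm == "mb":
        return mb_first_stage_values(q, cfg)
    if algorithm == "hybrid":
        return hybrid_values(mb_first_stage_values(q, cfg), (q.q[0, 0], q.q[0, 1]), params.w)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def simulate_session(
    params: AgentParams,
    algorithm: str,
    cfg: TaskConfig,
    seed,
    stage2_rep_context_specific: bool = False,
) -> list[LapRecord]:
    """Simulate one session of ``cfg.n_laps`` laps.

    The Q table is (re)initialized via :func:`init_q` at session start.
    Records carry the agent's probability of its own chosen action at each
    stage in ``p_choice1`` / ``p_choice2``.

    By default rep(a) at the second stage compares the left/right action of
    the previous lap's second stage regardless of which context was visited;
    set ``stage2_rep_context_specific=True`` to require the same context.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    rng = _as_rng(seed)
    q = init_q(cfg)
    delays = init_delays(cfg, rng)
    prev_a1: int | None = None
    prev_a2: int | None = None
    prev_ctx: str | None = None
    records: list[LapRecord] = []
    for lap in range(cfg.n_laps):
        v1 = _stage1_values(q, algorithm, params, cfg)
        p1 = choice_probabilities(v1, params.beta1, params.p, prev_a1)
        a1 = int(rng.random() < p1[1])  # 0 -> A, 1 -> B
        choice1 = STAGE1_ACTIONS[a1]

        context, transition = sample_transition(choice1, cfg, rng)
        rep2_prev = prev_a2
        if stage2_rep_context_specific and prev_ctx is not None and prev_ctx != context:
            rep2_prev = None
        v2 = (q.value(context, "left"), q.value(context, "right"))
        p2 = choice_probabilities(v2, params.beta2, params.p, rep2_prev)
        a2 = int(rng.random() < p2[1])
        choice2 = STAGE2_ACTIONS[a2]

        end_state = end_state_for(context, choice2)
        delay = float(delays.delays[end_state])
        reward = compute_reward(delay, cfg)

        # learning: stage-1 SARSA step (mf/hybrid), stage-2 delta rule,
        # then the end-of-trial eligibility-trace update
        if algorithm in ("mf", "hybrid"):
            q = mf_stage_update(q, "C1", choice1, 0.0, context, choice2, params.alpha1)
        delta2 = reward - q.value(context, choice2)
        q = mf_stage_update(q, context, choice2, reward, None, None, params.alpha2)
        if algorithm in ("mf", "hybrid"):
            q = mf_end_of_trial_update(q, "C1", choice1, delta2, params.alpha1, params.lam)

        records.append(
            LapRecord(
                lap_index=lap,
                choice1=choice1,
                context=context,
                transition=transition,
                choice2=choice2,
                end_state=end_state,
                delay=delay,
                reward=reward,
                p_choice1=float(p1[a1]),
                p_choice2=float(p2[a2]),
            )
        )
        delays = step_delays(delays, cfg, rng)
        prev_a1, prev_a2, prev_ctx = a1, a2, context
    return records
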