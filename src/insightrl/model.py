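"""Prospect-utility Q-learning of two-armed-bandit choice.

The agent keeps one action value per box, Q_right and Q_left, both starting
at zero. On each trial it chooses a box by softmax with inverse temperature
beta, receives ±10 points, passes the reward through a prospect utility
(curvature mu on gains, curvature nu and loss-aversion multiplier lam on
losses), and updates the chosen box's value by

    Q ← Q + alpha_pos · delta + phi   if delta ≥ 0
    Q ← Q + alpha_neg · delta + phi   if delta < 0

where delta = U(R) − Q is the reward prediction error. The unchosen box's
value is untouched. ``phi`` is an additive choice-autocorrelation control
applied to the chosen option on every trial; note that a non-zero phi makes
the chosen value drift without bound over long sessions (see the package
methods note).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from . import _core
from .bandit import BOXES, BehavioralRecord, RewardSchedule, box_index

#: Canonical parameter order used by arrays, tables and the optimizer.
PARAM_NAMES = ("beta", "mu", "nu", "alpha_pos", "alpha_neg", "lam", "phi")


@dataclass(frozen=True)
class ModelParameters:
    """The seven latent learning traits of one agent.

    beta      : softmax inverse temperature (≥ 0); exploitation/exploration.
    mu        : utility curvature on gains (≥ 0); lower = more risk-taking.
    nu        : utility curvature on losses (≥ 0).
    alpha_pos : learning rate for non-negative prediction errors, in [0, 1].
    alpha_neg : learning rate for negative prediction errors, in [0, 1].
    lam       : loss-aversion multiplier on losses (≥ 0).
    phi       : additive autocorrelation-control increment (any real).
    """

    beta: float
    mu: float
    nu: float
    alpha_pos: float
    alpha_neg: float
    lam: float
    phi: float = 0.0

    def __post_init__(self) -> None:
        for name in ("beta", "mu", "nu", "lam"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("alpha_pos", "alpha_neg"):
            a = getattr(self, name)
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_array(cls, arr) -> "ModelParameters":
        return cls(**dict(zip(PARAM_NAMES, map(float, arr))))


@dataclass
class AgentState:
    """Current action values, one per box."""

    q_values: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.q_values) != set(BOXES):
            raise ValueError(f"q_values must have exactly the keys {BOXES}")

    @classmethod
    def initial(cls) -> "AgentState":
        return cls({b: 0.0 for b in BOXES})


@dataclass(frozen=True)
class TrialTrace:
    """Diagnostics for one trial of the value recursion."""

    trial: int
    utility: float
    delta: float
    choice_prob_right: float
    q_before: tuple[float, float]  # (right, left)
    q_after: tuple[float, float]


def prospect_utility(reward: float, params: ModelParameters) -> float:
    """Prospect utility U(R): R^mu on gains, −lam·(−R)^nu on losses, 0 at 0."""
    if reward > 0:
        return float(reward ** params.mu)
    if reward < 0:
        return float(-params.lam * (-reward) ** params.nu)
    return 0.0


def choice_probabilities(state: AgentState, beta: float) -> dict[str, float]:
    """Softmax choice probabilities over the two boxes at temperature 1/beta."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    q = np.array([state.q_values[b] for b in BOXES])
    if not np.all(np.isfinite(q)):
        raise FloatingPointError("non-finite action values")
    z = beta * q
    z -= z.max()  # overflow-safe
    e = np.exp(z)
    p = e / e.sum()
    return dict(zip(BOXES, p.tolist()))


def update_q(
    state: AgentState,
    chosen: str,
    utility: float,
    params: ModelParameters,
    trial: int = 1,
) -> tuple[AgentState, TrialTrace]:
    """One step of the asymmetric value update for the chosen box.

    delta ≥ 0 takes the alpha_pos branch; phi is added on every update.
    The unchosen box's value is carried over unchanged.
    """
    if chosen not in state.q_values:
        raise KeyError(f"unknown box {chosen!r}")
    q_before = (state.q_values["right"], state.q_values["left"])
    p_right = choice_probabilities(state, params.beta)["right"]
    delta = utility - state.q_values[chosen]
    alpha = params.alpha_pos if delta >= 0 else params.alpha_neg
    new_q = dict(state.q_values)
    new_q[chosen] = state.q_values[chosen] + alpha * delta + params.phi
    new_state = AgentState(new_q)
    trace = TrialTrace(
        trial=trial,
        utility=utility,
        delta=delta,
        choice_prob_right=p_right,
        q_before=q_before,
        q_after=(new_q["right"], new_q["left"]),
    )
    return new_state, trace


def _traces_from_arrays(arrays) -> list[TrialTrace]:
    util, delta, p_right, qr_b, ql_b, qr_a, ql_a = arrays
    return [
        TrialTrace(
            trial=t + 1,
            utility=float(util[t]),
            delta=float(delta[t]),
            choice_prob_right=float(p_right[t]),
            q_before=(float(qr_b[t]), float(ql_b[t])),
            q_after=(float(qr_a[t]), float(ql_a[t])),
        )
        for t in range(util.shape[0])
    ]


def replay(record: BehavioralRecord, params: ModelParameters) -> list[TrialTrace]:
    """Run the value recursion over an observed record, returning traces."""
    arrays = _core.replay(record.choices, record.rewards, *params.to_array())
    return _traces_from_arrays(arrays)


def simulate_agent(
    params: ModelParameters,
    schedule: RewardSchedule,
    seed: int | np.random.SeedSequence,
    subject_id: str = "sim",
    collect_traces: bool = True,
) -> tuple[BehavioralRecord, list[TrialTrace] | None]:
    """Forward-simulate one full session.

    The session seed is split into two named substreams (choice sampling,
    reward draws) whose per-trial uniforms are generated up front, so probing
    either stream never perturbs later trials. Choices are drawn by inverse
    CDF on the softmax probability of the right box.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    choice_ss, reward_ss = ss.spawn(2)
    n = schedule.n_trials
    u_choice = np.random.default_rng(choice_ss).random(n)
    u_reward = np.random.default_rng(reward_ss).random(n)
    pr, pl = schedule.p_win_arrays()
    choices, rewards = _core.simulate(
        u_choice, u_reward, pr, pl, schedule.reward_win, schedule.reward_loss,
        *params.to_array(),
    )
    record = BehavioralRecord(subject_id, choices, rewards, schedule)
    if not collect_traces:
        return record, None
    arrays = _core.replay(choices, rewards, *params.to_array())
    return record, _traces_from_arrays(arrays)


def tab_performance(record: BehavioralRecord) -> float:
    """Total points earned over the session (the task's success measure)."""
    if len(record) == 0:
        raise ValueError("empty record")
    return float(record.rewards.sum())


def traces_to_frame(traces: Iterable[TrialTrace]) -> pd.DataFrame:
    """Diagnostics table: trial, delta, utility, q_right, q_left, p_right."""
    rows = [
        {
            "trial": tr.trial,
            "delta": tr.delta,
            "utility": tr.utility,
            "q_right": tr.q_after[0],
            "q_left": tr.q_after[1],
            "p_right": tr.choice_prob_right,
        }
        for tr in traces
    ]
    return pd.DataFrame(rows)


def advantageous_accuracy(record: BehavioralRecord, schedule: RewardSchedule) -> float:
    """Fraction of trials on which the currently richer box was chosen."""
    pr, pl = schedule.p_win_arrays()
    best = np.where(pr >= pl, 0, 1)
    return float((record.choices == best).mean())
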