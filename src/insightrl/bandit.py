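"""Two-armed bandit (TAB) task: reward schedules, reward draws, session data.

The task is a 100-trial two-armed bandit with ±10-point outcomes. One box wins
with probability 0.7 and the other with 0.3; the assignment reverses after
trial 30 and again after trial 70, so an agent that has locked onto the rich
box must keep re-learning. Only the chosen box's outcome is drawn and shown;
no counterfactual feedback exists.

Trial indices are 1-based inclusive throughout the public interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical box labels, index 0 = right, 1 = left.
BOXES = ("right", "left")


def box_index(box: str) -> int:
    """Map a box label to its internal index (0 = right, 1 = left)."""
    try:
        return BOXES.index(box)
    except ValueError:
        raise KeyError(f"unknown box {box!r}; expected one of {BOXES}") from None


@dataclass(frozen=True)
class Block:
    """A contiguous run of trials with fixed win probabilities per box."""

    first: int
    last: int
    p_win_right: float
    p_win_left: float

    def __post_init__(self) -> None:
        if self.first < 1 or self.last < self.first:
            raise ValueError(f"invalid block range [{self.first}, {self.last}]")
        for p in (self.p_win_right, self.p_win_left):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"win probability {p} outside [0, 1]")

    def p_win(self, box: str) -> float:
        return (self.p_win_right, self.p_win_left)[box_index(box)]


@dataclass(frozen=True)
class RewardSchedule:
    """Block structure of win probabilities and reward magnitudes for a session.

    ``blocks`` must tile ``[1, n_trials]`` exactly — no gaps, no overlaps.
    ``reward_win`` is the points paid on a win, ``reward_loss`` on a loss;
    a win must pay strictly more than a loss.
    """

    n_trials: int
    blocks: tuple[Block, ...]
    reward_win: float = 10.0
    reward_loss: float = -10.0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not self.blocks:
            raise ValueError("schedule needs at least one block")
        if self.reward_win <= self.reward_loss:
            raise ValueError("reward_win must exceed reward_loss")
        expect = 1
        for b in self.blocks:
            if b.first != expect:
                raise ValueError(
                    f"blocks do not tile trials: expected start {expect}, got {b.first}"
                )
            expect = b.last + 1
        if expect != self.n_trials + 1:
            raise ValueError(
                f"blocks end at {expect - 1}, schedule has {self.n_trials} trials"
            )

    def block_at(self, trial: int) -> Block:
        if not 1 <= trial <= self.n_trials:
            raise IndexError(f"trial {trial} outside [1, {self.n_trials}]")
        for b in self.blocks:
            if b.first <= trial <= b.last:
                return b
        raise AssertionError("unreachable: blocks tile the session")

    def p_win_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-trial win probabilities, returned as (right, left) arrays."""
        pr = np.empty(self.n_trials)
        pl = np.empty(self.n_trials)
        for b in self.blocks:
            pr[b.first - 1 : b.last] = b.p_win_right
            pl[b.first - 1 : b.last] = b.p_win_left
        return pr, pl

    # -- plain-text serialization ------------------------------------------

    def to_text(self) -> str:
        lines = [
            f"n_trials = {self.n_trials}",
            f"reward_win = {self.reward_win!r}",
            f"reward_loss = {self.reward_loss!r}",
        ]
        for b in self.blocks:
            lines.append(f"block = {b.first} {b.last} {b.p_win_right!r} {b.p_win_left!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RewardSchedule":
        n_trials = None
        reward_win = reward_loss = None
        blocks: list[Block] = []
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "n_trials":
                n_trials = int(value)
            elif key == "reward_win":
                reward_win = float(value)
            elif key == "reward_loss":
                reward_loss = float(value)
            elif key == "block":
                f, l, pr, pl = value.split()
                blocks.append(Block(int(f), int(l), float(pr), float(pl)))
            else:
                raise ValueError(f"unknown schedule field {key!r}")
        if n_trials is None or reward_win is None or reward_loss is None:
            raise ValueError("schedule text missing n_trials/reward_win/reward_loss")
        return cls(n_trials, tuple(blocks), reward_win, reward_loss)


def make_standard_schedule() -> RewardSchedule:
    """The study's 100-trial schedule: 70/30, reversed over trials 31–70."""
    return RewardSchedule(
        n_trials=100,
        blocks=(
            Block(1, 30, 0.7, 0.3),
            Block(31, 70, 0.3, 0.7),
            Block(71, 100, 0.7, 0.3),
        ),
    )


def make_reversal_schedule(
    n_trials: int,
    reversal_every: int = 40,
    p_high: float = 0.7,
    reward_win: float = 10.0,
    reward_loss: float = -10.0,
) -> RewardSchedule:
    """A longer session with the same reversal logic, for recovery studies.

    Blocks of ``reversal_every`` trials alternate which box is advantageous,
    starting with the right box at probability ``p_high``; the final block is
    truncated to fit ``n_trials``.
    """
    blocks = []
    first, right_rich = 1, True
    while first <= n_trials:
        last = min(first + reversal_every - 1, n_trials)
        pr = p_high if right_rich else 1.0 - p_high
        blocks.append(Block(first, last, pr, 1.0 - pr))
        first, right_rich = last + 1, not right_rich
    return RewardSchedule(n_trials, tuple(blocks), reward_win, reward_loss)


def win_probability(schedule: RewardSchedule, trial: int, box: str) -> float:
    """Win probability of ``box`` on 1-based ``trial`` under ``schedule``."""
    return schedule.block_at(trial).p_win(box)


def draw_reward(
    schedule: RewardSchedule,
    trial: int,
    box: str,
    rng: np.random.Generator | int,
) -> float:
    """Draw one outcome: ``reward_win`` w.p. ``win_probability``, else loss.

    ``rng`` may be a Generator (state advances by one uniform) or an integer
    seed for a one-shot reproducible draw.
    """
    p = win_probability(schedule, trial, box)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return schedule.reward_win if rng.random() < p else schedule.reward_loss


def estimate_win_rate(
    schedule: RewardSchedule,
    trials: Sequence[int],
    box: str,
    n_sessions: int,
    seed: int,
) -> tuple[float, int]:
    """Monte-Carlo win frequency of ``box`` over ``trials``, many sessions.

    Each session gets its own substream spawned from ``seed``. Returns the
    empirical win fraction and the total number of draws.
    """
    children = np.random.SeedSequence(seed).spawn(n_sessions)
    wins = 0
    total = 0
    win = schedule.reward_win
    for child in children:
        rng = np.random.default_rng(child)
        for t in trials:
            if draw_reward(schedule, t, box, rng) == win:
                wins += 1
            total += 1
    return wins / total, total


# -- session containers and trial-table I/O --------------------------------


@dataclass(frozen=True)
class TrialOutcome:
    """One completed trial: 1-based index, chosen box, points obtained."""

    trial: int
    choice: str
    reward: float


@dataclass
class BehavioralRecord:
    """One subject's full choice/reward sequence from a bandit session.

    ``choices`` holds internal box indices (0 = right, 1 = left) and
    ``rewards`` the points obtained, both aligned by trial (element t is
    trial t+1). This is the data object the model likelihood consumes.
    """

    subject_id: str
    choices: np.ndarray
    rewards: np.ndarray
    schedule: RewardSchedule | None = None

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=np.int64)
        self.rewards = np.asarray(self.rewards, dtype=np.float64)
        if self.choices.shape != self.rewards.shape or self.choices.ndim != 1:
            raise ValueError("choices and rewards must be equal-length 1-D arrays")
        if self.choices.size and not np.isin(self.choices, (0, 1)).all():
            raise ValueError("choices must be 0 (right) or 1 (left)")

    def __len__(self) -> int:
        return int(self.choices.size)

    @property
    def trials(self) -> list[TrialOutcome]:
        return [
            TrialOutcome(t + 1, BOXES[c], r)
            for t, (c, r) in enumerate(zip(self.choices, self.rewards))
        ]

    def relabeled(self) -> "BehavioralRecord":
        """Swap the right/left labels (choices and, if present, schedule)."""
        sched = self.schedule
        if sched is not None:
            sched = RewardSchedule(
                sched.n_trials,
                tuple(
                    Block(b.first, b.last, b.p_win_left, b.p_win_right)
                    for b in sched.blocks
                ),
                sched.reward_win,
                sched.reward_loss,
            )
        return BehavioralRecord(self.subject_id, 1 - self.choices, self.rewards.copy(), sched)


def records_to_frame(records: Iterable[BehavioralRecord]) -> pd.DataFrame:
    """Long trial-level table: subject_id, trial, choice, reward."""
    parts = []
    for rec in records:
        parts.append(
            pd.DataFrame(
                {
                    "subject_id": rec.subject_id,
                    "trial": np.arange(1, len(rec) + 1),
                    "choice": np.asarray(BOXES)[rec.choices],
                    "reward": rec.rewards,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=["subject_id", "trial", "choice", "reward"])
    return pd.concat(parts, ignore_index=True)


def frame_to_records(frame: pd.DataFrame) -> list[BehavioralRecord]:
    missing = {"subject_id", "trial", "choice", "reward"} - set(frame.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    records = []
    for sid, grp in frame.groupby("subject_id", sort=False):
        grp = grp.sort_values("trial")
        if not (grp["trial"].to_numpy() == np.arange(1, len(grp) + 1)).all():
            raise ValueError(f"subject {sid}: trials must run 1..T without gaps")
        choices = np.array([box_index(c) for c in grp["choice"]])
        records.append(BehavioralRecord(str(sid), choices, grp["reward"].to_numpy()))
    return records


def write_trials(records: Iterable[BehavioralRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_trials(path) -> list[BehavioralRecord]:
    return frame_to_records(pd.read_csv(path, dtype={"subject_id": str}))
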