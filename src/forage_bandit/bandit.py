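"""k-armed bandit environment and the ε-greedy agent.

The model of foraging used throughout the package: a fish choosing among the
four arms of a cross-maze is treated as an ε-greedy learner on a 4-armed
bandit in which exactly one arm pays a binary reward.  The agent keeps a
per-arm action value Q(A) — the running mean of rewards obtained on that arm,
maintained incrementally as Q(A) <- Q(A) + (R - Q(A)) / N(A) — and on each
trial either exploits the best arm so far (probability 1 - ε) or explores a
uniformly random arm (probability ε).

Arms are labeled 1..k in every public interface; internal arrays are
0-indexed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError

TIE_BREAKS = ("first_index", "uniform_random")


@dataclass(frozen=True)
class BanditTask:
    """A k-armed bandit with a single rewarding arm and binary payoff.

    Parameters
    ----------
    n_arms
        Number of arms k (>= 2).
    reward_arm
        Label in 1..k of the unique arm that pays ``reward_value``.
    reward_value
        Payoff on the rewarding arm.  Only the binary case (1.0) is
        supported by the exact oracle; the simulator enforces it too so the
        two routes always model the same process.
    """

    n_arms: int = 4
    reward_arm: int = 1
    reward_value: float = 1.0

    def __post_init__(self) -> None:
        if self.n_arms < 2:
            raise ConfigurationError(f"n_arms must be >= 2, got {self.n_arms}")
        if not 1 <= self.reward_arm <= self.n_arms:
            raise ConfigurationError(
                f"reward_arm must be in 1..{self.n_arms}, got {self.reward_arm}"
            )
        if self.reward_value != 1.0:
            raise ConfigurationError("only binary payoff (reward_value=1.0) is supported")

    def payoff(self, arm: int) -> int:
        """Reward for choosing ``arm`` (1-based label): 1 iff it is the reward arm."""
        return 1 if arm == self.reward_arm else 0


def draw_task(n_arms: int, rng: np.random.Generator) -> BanditTask:
    """Draw a task whose rewarding arm is uniform over 1..k.

    The rewarding arm is drawn once per episode and held fixed for all its
    trials, mirroring a forager that must discover which patch is baited.
    """
    return BanditTask(n_arms=n_arms, reward_arm=int(rng.integers(1, n_arms + 1)))


@dataclass
class AgentState:
    """Mutable state of an ε-greedy learner.

    ``q_values[a]`` is the sample-average action value of arm a+1 and
    ``visit_counts[a]`` the number of times it has been chosen.  With binary
    rewards every Q stays in [0, 1], and the sum of visit counts equals the
    number of completed trials.
    """

    epsilon: float
    q_values: list[float] = field(default_factory=list)
    visit_counts: list[int] = field(default_factory=list)

    @classmethod
    def fresh(cls, epsilon: float, n_arms: int) -> "AgentState":
        """Zero-initialized state: Q = 0 and N = 0 on every arm."""
        if not 0.0 <= epsilon <= 1.0:
            raise ConfigurationError(f"epsilon must be in [0, 1], got {epsilon}")
        return cls(epsilon=epsilon, q_values=[0.0] * n_arms, visit_counts=[0] * n_arms)

    @property
    def n_arms(self) -> int:
        return len(self.q_values)


@dataclass(frozen=True)
class TrialOutcome:
    """One trial of one episode: arm chosen, reward received, and whether the
    choice came from the exploration branch."""

    trial_index: int  # 1-based
    chosen_arm: int  # 1-based label
    reward: int
    explored: bool


def update_action_value(q: float, n: int, r: float) -> float:
    """Incremental sample-average update Q <- Q + (R - Q)/N.

    ``n`` is the visit count *including* the current visit, so the first
    visit (n = 1) sets Q = R exactly.

    Raises
    ------
    ConfigurationError
        If ``n`` is not a positive integer (the visit-count increment must
        precede the value update).
    """
    if n < 1:
        raise ConfigurationError(f"visit count must be >= 1 before the update, got {n}")
    return q + (r - q) / n


def select_arm(
    state: AgentState,
    rng: np.random.Generator,
    tie_break: str = "first_index",
) -> tuple[int, bool]:
    """Choose an arm by the ε-greedy rule.

    With probability ε a uniformly random arm over all k arms (the greedy arm
    is not excluded) is returned with ``explored=True``; otherwise an arm
    maximizing Q is returned with ``explored=False``.  When several arms tie
    for the maximal Q, ``tie_break`` decides:

    - ``first_index``: the lowest-index maximal arm (the convention required
      to reproduce the published group-level simulation means);
    - ``uniform_random``: a uniform draw among the maximal arms.

    Returns the 1-based arm label and the explored flag.
    """
    if tie_break not in TIE_BREAKS:
        raise ConfigurationError(
            f"unknown tie_break {tie_break!r}; expected one of {TIE_BREAKS}"
        )
    k = state.n_arms
    if rng.random() < state.epsilon:
        return int(rng.integers(k)) + 1, True
    q = state.q_values
    best = max(q)
    if tie_break == "first_index":
        return q.index(best) + 1, False
    ties = [a for a, v in enumerate(q) if v == best]
    return ties[int(rng.integers(len(ties)))] + 1, False


def run_episode(
    epsilon: float,
    n_trials: int,
    task: BanditTask,
    rng: np.random.Generator,
    tie_break: str = "first_index",
) -> list[TrialOutcome]:
    """Run one ε-greedy episode of ``n_trials`` trials on ``task``.

    Per trial: select an arm, collect the binary payoff, increment the visit
    count, then apply the sample-average update.  Returns one
    :class:`TrialOutcome` per trial, in order.
    """
    if n_trials < 1:
        raise ConfigurationError(f"n_trials must be >= 1, got {n_trials}")
    state = AgentState.fresh(epsilon, task.n_arms)
    q, n = state.q_values, state.visit_counts
    outcomes: list[TrialOutcome] = []
    for t in range(1, n_trials + 1):
        arm, explored = select_arm(state, rng, tie_break)
        r = task.payoff(arm)
        i = arm - 1
        n[i] += 1
        q[i] = update_action_value(q[i], n[i], r)
        outcomes.append(TrialOutcome(trial_index=t, chosen_arm=arm, reward=r, explored=explored))
    return outcomes


def episode_rewards(outcomes: Sequence[TrialOutcome]) -> np.ndarray:
    """Binary reward sequence of an episode as an int array."""
    return np.array([o.reward for o in outcomes], dtype=np.int8)


def outcomes_to_rows(outcomes: Sequence[TrialOutcome]) -> list[dict]:
    """Episode trace as CSV-ready dict rows."""
    return [
        {
            "trial_index": o.trial_index,
            "chosen_arm": o.chosen_arm,
            "reward": o.reward,
            "explored": int(o.explored),
        }
        for o in outcomes
    ]


def validate_binary_outcomes(outcomes: Sequence[int | float]) -> np.ndarray:
    """Check a reward sequence is non-empty and strictly binary."""
    arr = np.asarray(outcomes)
    if arr.size == 0:
        raise ValidationError("outcome sequence is empty")
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError("outcomes must be binary (0 or 1)")
    return arr.astype(np.int8)
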