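"""Exact expected-reward computation for the ε-greedy single-reward-arm bandit.

With zero-initialized action values and a binary payoff concentrated on one
arm, the agent's belief state collapses: every non-rewarding arm keeps Q = 0
forever, and the rewarding arm jumps to Q = 1 on its first visit and stays
there.  An episode therefore moves through exactly two regimes,

* **undiscovered** — all Q equal zero; the greedy branch falls back to the
  tie-break rule, and the rewarding arm is found (which also scores) with a
  per-trial probability ``p_u`` that depends on the tie-break and on whether
  the rewarding arm happens to be the tie-break's default choice;
* **discovered** — the rewarding arm is the unique Q-maximizer, so every
  trial succeeds with probability ``p_d = (1 - ε) + ε/k``.

Forward dynamic programming over this two-state chain gives the exact
per-trial success probabilities, hence the exact expected average reward,
without Monte Carlo error.  This module is the deterministic oracle against
which the stochastic simulator is verified.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError
from .bandit import TIE_BREAKS


def _undiscovered_success_prob(
    epsilon: float, k: int, tie_break: str, arm_is_default: bool
) -> float:
    """Per-trial probability of choosing the rewarding arm while all Q = 0.

    ``arm_is_default`` only matters for first_index tie-breaking: it says
    whether the rewarding arm is arm 1, the arm the greedy branch defaults to
    before anything has been learned.
    """
    if tie_break == "uniform_random":
        # Greedy breaks the all-zero tie uniformly, so both branches are
        # uniform over k arms.
        return 1.0 / k
    if arm_is_default:
        return (1.0 - epsilon) + epsilon / k
    return epsilon / k


def _per_trial_case(epsilon: float, k: int, n_trials: int, p_u: float) -> np.ndarray:
    """Exact success probability at each trial for a fixed undiscovered rate.

    Forward recursion on P(still undiscovered); discovery coincides with the
    first success, after which every trial succeeds with probability p_d.
    """
    p_d = (1.0 - epsilon) + epsilon / k
    probs = np.empty(n_trials)
    undiscovered = 1.0
    for t in range(n_trials):
        probs[t] = undiscovered * p_u + (1.0 - undiscovered) * p_d
        undiscovered *= 1.0 - p_u
    return probs


def per_trial_success_probabilities(
    epsilon: float,
    k: int = 4,
    n_trials: int = 21,
    tie_break: str = "first_index",
    reward_arm_dist: str | int = "uniform",
    reward_value: float = 1.0,
) -> np.ndarray:
    """Exact probability of earning the reward at each trial 1..n_trials.

    Parameters
    ----------
    epsilon
        Exploration probability in [0, 1].
    k
        Number of arms.
    n_trials
        Episode length.
    tie_break
        Greedy tie-break convention, ``first_index`` or ``uniform_random``.
    reward_arm_dist
        ``"uniform"`` for a rewarding arm drawn uniformly over 1..k once per
        episode, or a fixed 1-based arm label.
    reward_value
        Must be 1.0; any other payoff breaks the two-regime collapse and is
        rejected.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ConfigurationError(f"epsilon must be in [0, 1], got {epsilon}")
    if k < 2:
        raise ConfigurationError(f"k must be >= 2, got {k}")
    if n_trials < 1:
        raise ConfigurationError(f"n_trials must be >= 1, got {n_trials}")
    if tie_break not in TIE_BREAKS:
        raise ConfigurationError(
            f"unknown tie_break {tie_break!r}; expected one of {TIE_BREAKS}"
        )
    if reward_value != 1.0:
        raise ConfigurationError(
            "exact oracle supports only the binary reward_value=1.0 configuration"
        )

    if reward_arm_dist == "uniform":
        # Mixture over the uniformly drawn rewarding arm.  Under
        # uniform_random tie-breaking all arms are exchangeable, so the two
        # cases coincide.
        p_match = _undiscovered_success_prob(epsilon, k, tie_break, True)
        p_other = _undiscovered_success_prob(epsilon, k, tie_break, False)
        return (
            _per_trial_case(epsilon, k, n_trials, p_match)
            + (k - 1) * _per_trial_case(epsilon, k, n_trials, p_other)
        ) / k
    if isinstance(reward_arm_dist, int) and not isinstance(reward_arm_dist, bool):
        if not 1 <= reward_arm_dist <= k:
            raise ConfigurationError(
                f"fixed reward arm must be in 1..{k}, got {reward_arm_dist}"
            )
        p_u = _undiscovered_success_prob(epsilon, k, tie_break, reward_arm_dist == 1)
        return _per_trial_case(epsilon, k, n_trials, p_u)
    raise ConfigurationError(
        f"reward_arm_dist must be 'uniform' or an arm label, got {reward_arm_dist!r}"
    )


def exact_expected_average_reward(
    epsilon: float,
    k: int = 4,
    n_trials: int = 21,
    tie_break: str = "first_index",
    reward_arm_dist: str | int = "uniform",
    reward_value: float = 1.0,
) -> float:
    """Exact expectation of (sum of rewards)/n_trials for one episode."""
    probs = per_trial_success_probabilities(
        epsilon, k, n_trials, tie_break, reward_arm_dist, reward_value
    )
    return float(probs.mean())


def exact_expected_cumulative_rewards(
    epsilon: float,
    k: int = 4,
    n_trials: int = 21,
    tie_break: str = "first_index",
    reward_arm_dist: str | int = "uniform",
) -> np.ndarray:
    """Exact expected cumulative reward after each trial 1..n_trials."""
    return np.cumsum(
        per_trial_success_probabilities(epsilon, k, n_trials, tie_break, reward_arm_dist)
    )
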