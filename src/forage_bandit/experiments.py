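"""Cohort-scale simulation and summary surfaces.

Runs the "digital twin" of each fish — one ε-greedy episode per (agent,
replicate) with the rewarding arm redrawn uniformly per episode — and
condenses the results into the two surfaces used for fish-versus-model
comparison: per-group mean ± SE average reward after T trials, and per-group
mean ± SE cumulative-reward trajectories.

Reproducibility: all randomness flows from a single integer seed through
``numpy.random.SeedSequence``; each agent owns a spawned child stream used
sequentially across its replicates, so results are bit-identical for a given
(seed, parameters) regardless of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bandit import TIE_BREAKS, draw_task, run_episode
from .cohort import standard_error
from .errors import ConfigurationError, ValidationError


@dataclass
class SimulationRun:
    """Raw outcome tensor of a cohort simulation.

    ``rewards`` has shape (n_agents, replicates, n_trials) with binary
    entries; ``epsilons`` aligns with the first axis.
    """

    epsilons: np.ndarray
    n_trials: int
    replicates: int
    tie_break: str
    seed: int
    rewards: np.ndarray

    @property
    def n_agents(self) -> int:
        return len(self.epsilons)

    def average_rewards(self) -> np.ndarray:
        """Per-agent average reward, pooled over replicates and trials."""
        return self.rewards.mean(axis=(1, 2))

    def episode_average_rewards(self) -> np.ndarray:
        """Average reward of every (agent, replicate) episode, flattened."""
        return self.rewards.mean(axis=2).reshape(-1)


def simulate_cohort(
    epsilons: Sequence[float],
    n_trials: int = 21,
    replicates: int = 1,
    tie_break: str = "first_index",
    seed: int = 0,
    n_arms: int = 4,
) -> SimulationRun:
    """Simulate one independent bandit episode per (agent, replicate).

    Each entry of ``epsilons`` is one agent's exploration rate (a fish's
    normalized basal cortisol in the cohort pipeline).  The rewarding arm is
    redrawn uniformly for every episode.
    """
    eps = np.asarray(list(epsilons), dtype=float)
    if eps.size == 0:
        raise ValidationError("epsilon list is empty")
    if np.any((eps < 0) | (eps > 1)) or not np.all(np.isfinite(eps)):
        raise ValidationError("every epsilon must be a finite value in [0, 1]")
    if replicates < 1:
        raise ConfigurationError(f"replicates must be >= 1, got {replicates}")
    if tie_break not in TIE_BREAKS:
        raise ConfigurationError(f"unknown tie_break {tie_break!r}")

    rewards = np.empty((eps.size, replicates, n_trials), dtype=np.int8)
    streams = np.random.SeedSequence(seed).spawn(eps.size)
    for a, (epsilon, stream) in enumerate(zip(eps, streams)):
        rng = np.random.default_rng(stream)
        for rep in range(replicates):
            task = draw_task(n_arms, rng)
            episode = run_episode(epsilon, n_trials, task, rng, tie_break)
            rewards[a, rep, :] = [o.reward for o in episode]
    return SimulationRun(
        epsilons=eps,
        n_trials=n_trials,
        replicates=replicates,
        tie_break=tie_break,
        seed=seed,
        rewards=rewards,
    )


def group_summary(
    per_agent_values: Sequence[float],
    group_labels: Sequence[int],
    epsilons: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Per-group mean ± SE table (the GroupTable surface).

    Columns: ``group, n, mean_epsilon, mean_avg_reward, se``.  SE is the
    sample standard deviation (n-1 denominator) over sqrt(n); a singleton
    group gets SE = NaN.  ``epsilons`` (normalized cortisol) is optional and
    summarized per group when given.
    """
    values = np.asarray(list(per_agent_values), dtype=float)
    labels = np.asarray(list(group_labels), dtype=int)
    if values.size != labels.size:
        raise ValidationError("one value and one group label per agent required")
    eps = None if epsilons is None else np.asarray(list(epsilons), dtype=float)
    rows = []
    for g in np.unique(labels):
        mask = labels == g
        vals = values[mask]
        rows.append(
            {
                "group": int(g),
                "n": int(mask.sum()),
                "mean_epsilon": float(eps[mask].mean()) if eps is not None else np.nan,
                "mean_avg_reward": float(vals.mean()),
                "se": standard_error(vals),
            }
        )
    return pd.DataFrame(rows)


def cumulative_trajectories(
    run: SimulationRun, group_labels: Sequence[int]
) -> pd.DataFrame:
    """Per-group mean ± SE cumulative-reward curves.

    For each group and trial t, the mean and SE over its (agent, replicate)
    episodes of the running reward sum through trial t.  Columns:
    ``group, trial, mean_cum_reward, se``.
    """
    labels = np.asarray(list(group_labels), dtype=int)
    if labels.size != run.n_agents:
        raise ValidationError("one group label per agent required")
    cum = np.cumsum(run.rewards, axis=2)  # (agents, replicates, trials)
    rows = []
    for g in np.unique(labels):
        block = cum[labels == g].reshape(-1, run.n_trials)  # episodes x trials
        means = block.mean(axis=0)
        ses = [standard_error(block[:, t]) for t in range(run.n_trials)]
        for t in range(run.n_trials):
            rows.append(
                {
                    "group": int(g),
                    "trial": t + 1,
                    "mean_cum_reward": float(means[t]),
                    "se": ses[t],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Optional figures (group-mean bars and trajectory curves)


def plot_group_means(table: pd.DataFrame, path, title: str = "Average reward by group"):
    """Errorbar plot of a GroupTable; writes a PNG and returns the path."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(
        table["mean_epsilon"], table["mean_avg_reward"], yerr=table["se"],
        fmt="o-", capsize=3,
    )
    ax.set_xlabel("mean epsilon (normalized cortisol)")
    ax.set_ylabel("average reward")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_trajectories(traj: pd.DataFrame, path, title: str = "Cumulative reward"):
    """Mean ± SE cumulative-reward curves per group; writes a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    for g, block in traj.groupby("group"):
        ax.plot(block["trial"], block["mean_cum_reward"], label=f"group {g}")
        ax.fill_between(
            block["trial"],
            block["mean_cum_reward"] - block["se"].fillna(0),
            block["mean_cum_reward"] + block["se"].fillna(0),
            alpha=0.2,
        )
    ax.set_xlabel("trial")
    ax.set_ylabel("cumulative reward")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
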