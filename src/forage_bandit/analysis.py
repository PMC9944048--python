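"""Fish-versus-simulation comparison statistics.

The biological and computational group tables are compared by the Pearson
product-moment correlation over their per-group mean average rewards — over
all groups, and in leave-one-group-out scenarios (the published headline
numbers drop the group whose live fish underperformed their digital twins
because a quarter of them never scored).  A zero-reward census counts, per
group, the individuals that never accumulated any reward.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedCorrelationError, ValidationError


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Requires at least 3 points and nonzero variance on both sides.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise UndefinedCorrelationError(f"need >= 3 points, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    return float(stats.pearsonr(x, y).statistic)


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Display rounding with ties away from zero (0.625 -> 0.63)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ComparisonReport:
    """Joined fish/simulation tables plus the correlation scenarios.

    ``r_excl[g]`` is the Pearson r over the group-mean pairs with group g
    left out; ``zero_reward_counts`` (optional) maps group -> number of
    individuals with average reward exactly zero.
    """

    fish_table: pd.DataFrame
    sim_table: pd.DataFrame
    r_all: float
    r_excl: dict[int, float]
    zero_reward_counts: dict[int, int] | None = None

    def to_comparison_frame(self) -> pd.DataFrame:
        """Wide per-group table: group, fish_mean, fish_se, sim_mean, sim_se."""
        return pd.DataFrame(
            {
                "group": self.fish_table["group"].to_numpy(),
                "fish_mean": self.fish_table["mean_avg_reward"].to_numpy(),
                "fish_se": self.fish_table["se"].to_numpy(),
                "sim_mean": self.sim_table["mean_avg_reward"].to_numpy(),
                "sim_se": self.sim_table["se"].to_numpy(),
            }
        )

    def to_correlation_frame(self) -> pd.DataFrame:
        rows = [{"scenario": "all_groups", "r": self.r_all}]
        rows += [
            {"scenario": f"excl_group_{g}", "r": r} for g, r in sorted(self.r_excl.items())
        ]
        return pd.DataFrame(rows)

    def render_text(self) -> str:
        lines = ["Fish vs simulation comparison", "=" * 31, ""]
        lines.append(self.to_comparison_frame().to_string(index=False, float_format="%.4f"))
        lines.append("")
        lines.append(f"Pearson r, all groups: {round_half_up(self.r_all):.2f}")
        for g, r in sorted(self.r_excl.items()):
            lines.append(f"Pearson r, excluding group {g}: {round_half_up(r):.2f}")
        if self.zero_reward_counts is not None:
            lines.append("")
            lines.append("Individuals with zero total reward, per group:")
            for g, c in sorted(self.zero_reward_counts.items()):
                lines.append(f"  group {g}: {c}")
        return "\n".join(lines) + "\n"


def compare_groups(
    fish_table: pd.DataFrame, sim_table: pd.DataFrame
) -> ComparisonReport:
    """Correlate two GroupTable frames over their group means.

    Computes r over all G group-mean pairs and, for every group, the r with
    that group excluded (undefined when fewer than 3 pairs would remain).
    """
    fish = fish_table.sort_values("group").reset_index(drop=True)
    sim = sim_table.sort_values("group").reset_index(drop=True)
    if not np.array_equal(fish["group"].to_numpy(), sim["group"].to_numpy()):
        raise ValidationError("fish and simulation tables have different group labels")
    groups = fish["group"].to_numpy()
    x = sim["mean_avg_reward"].to_numpy()
    y = fish["mean_avg_reward"].to_numpy()
    r_all = pearson_r(x, y)
    r_excl: dict[int, float] = {}
    for g in groups:
        mask = groups != g
        if mask.sum() < 3:
            raise UndefinedCorrelationError(
                f"fewer than 3 groups remain after excluding group {g}"
            )
        r_excl[int(g)] = pearson_r(x[mask], y[mask])
    return ComparisonReport(fish_table=fish, sim_table=sim, r_all=r_all, r_excl=r_excl)


def zero_reward_census(
    average_rewards: Sequence[float], group_labels: Sequence[int]
) -> dict[int, int]:
    """Count individuals per group whose average reward is exactly zero."""
    values = np.asarray(list(average_rewards), dtype=float)
    labels = np.asarray(list(group_labels), dtype=int)
    if values.size != labels.size:
        raise ValidationError("one average reward and one label per individual required")
    return {int(g): int((values[labels == g] == 0).sum()) for g in np.unique(labels)}
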