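"""Synthetic cohort generation.

Builds cohorts with the statistical structure the analysis assumes, so every
downstream stage is testable without the original spreadsheet: cortisol
values drawn per group from the measured per-group ranges, a configurable
number of invalid assay records, and trial outcomes produced either by the
ε-greedy bandit model itself (each fish's ε = its normalized cortisol) or by
independent Bernoulli draws at stated per-group rates.

Cortisol within a group is sampled uniformly over the group's range — the
least-informative choice consistent with knowing only each group's range and
mean.  Group mean normalized cortisol therefore approximates, rather than
equals, the published group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import study_data
from .bandit import draw_task, episode_rewards, run_episode
from .cohort import FishRecord, assign_groups, minmax_normalize
from .errors import ConfigurationError

BEHAVIOR_MODELS = ("epsilon_greedy", "bernoulli")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the reference study design: 82 valid fish in five
    ascending-cortisol groups of sizes 16/17/16/16/17 spanning the measured
    per-group cortisol ranges, plus 3 failed-assay and 1 outlier record, and
    21 trials per fish.
    """

    group_ranges: tuple[tuple[float, float], ...] = study_data.CORTISOL_RANGES_NG_ML
    group_sizes: tuple[int, ...] = study_data.GROUP_SIZES
    n_assay_failed: int = study_data.N_ASSAY_FAILED
    n_outlier: int = study_data.N_OUTLIER
    n_trials: int = study_data.N_TRIALS
    n_arms: int = study_data.N_ARMS
    behavior_model: str = "epsilon_greedy"
    #: Per-group success rates, used only by the bernoulli model.
    bernoulli_rates: tuple[float, ...] | None = None
    tie_break: str = "first_index"

    def __post_init__(self) -> None:
        if len(self.group_ranges) != len(self.group_sizes):
            raise ConfigurationError("group_ranges and group_sizes length mismatch")
        if any(s <= 0 for s in self.group_sizes):
            raise ConfigurationError("group sizes must be positive")
        for lo, hi in self.group_ranges:
            if not (0 <= lo < hi):
                raise ConfigurationError(f"empty or invalid cortisol range ({lo}, {hi})")
        for (lo, hi), (lo2, _) in zip(self.group_ranges, self.group_ranges[1:]):
            if lo2 < hi:
                raise ConfigurationError("group cortisol ranges must be ordered and disjoint")
        if self.behavior_model not in BEHAVIOR_MODELS:
            raise ConfigurationError(
                f"behavior_model must be one of {BEHAVIOR_MODELS}, got {self.behavior_model!r}"
            )
        if self.behavior_model == "bernoulli":
            if self.bernoulli_rates is None or len(self.bernoulli_rates) != len(
                self.group_sizes
            ):
                raise ConfigurationError(
                    "bernoulli model needs one success rate per group"
                )
        if self.n_trials < 1 or self.n_assay_failed < 0 or self.n_outlier < 0:
            raise ConfigurationError("invalid counts in cohort spec")

    @property
    def n_valid(self) -> int:
        return int(sum(self.group_sizes))

    @property
    def n_records(self) -> int:
        return self.n_valid + self.n_assay_failed + self.n_outlier


def _as_rng(rng_or_seed: np.random.Generator | int) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def sample_cortisol(
    spec: SyntheticCohortSpec, rng: np.random.Generator | int
) -> list[tuple[float | None, str]]:
    """Draw cortisol values with validity flags for one cohort.

    Valid values are uniform within each group's range, in ascending group
    order; invalid records follow: failed assays carry a missing value,
    outliers an implausibly high one (their values never enter normalization,
    so only the flag matters downstream).
    """
    rng = _as_rng(rng)
    out: list[tuple[float | None, str]] = []
    for (lo, hi), size in zip(spec.group_ranges, spec.group_sizes):
        for v in rng.uniform(lo, hi, size=size):
            out.append((float(v), "valid"))
    for _ in range(spec.n_assay_failed):
        out.append((None, "assay_failed"))
    top = max(hi for _, hi in spec.group_ranges)
    for _ in range(spec.n_outlier):
        out.append((float(rng.uniform(5 * top, 10 * top)), "outlier"))
    return out


def generate_cohort(
    spec: SyntheticCohortSpec, rng: np.random.Generator | int
) -> list[FishRecord]:
    """Generate a full synthetic cohort of :class:`FishRecord` objects.

    Under ``behavior_model="epsilon_greedy"`` each valid fish plays one
    bandit episode with ε equal to its cortisol min-max-normalized within
    the valid subset; the rewarding arm is redrawn uniformly per fish.
    Flagged fish still complete their trials (as in the real experiment) —
    they play with an ε drawn uniformly on [0, 1], and their outcomes are
    inert because the pipeline filters them out before any analysis.

    Under ``behavior_model="bernoulli"`` outcomes are i.i.d. Bernoulli at the
    fish's group rate, a structureless control lacking any learning dynamics.

    Record order is shuffled so that group membership is not encoded in row
    position.  Fully deterministic given the rng state / seed.
    """
    rng = _as_rng(rng)
    sampled = sample_cortisol(spec, rng)
    order = rng.permutation(len(sampled))
    sampled = [sampled[i] for i in order]

    # ε for valid fish = cortisol normalized over the valid subset, exactly
    # what the pipeline will recompute on read-back.
    valid_idx = [i for i, (_, flag) in enumerate(sampled) if flag == "valid"]
    normalized = minmax_normalize([sampled[i][0] for i in valid_idx])
    epsilons: dict[int, float] = dict(zip(valid_idx, normalized))

    if spec.behavior_model == "bernoulli":
        labels = assign_groups([sampled[i][0] for i in valid_idx], spec.group_sizes)
        group_of = dict(zip(valid_idx, labels))

    records: list[FishRecord] = []
    width = len(str(len(sampled)))
    for i, (cort, flag) in enumerate(sampled):
        if spec.behavior_model == "bernoulli" and i in epsilons:
            p = spec.bernoulli_rates[group_of[i] - 1]
            outcomes = tuple(int(x) for x in rng.random(spec.n_trials) < p)
        else:
            eps = epsilons.get(i, float(rng.uniform()))
            task = draw_task(spec.n_arms, rng)
            episode = run_episode(eps, spec.n_trials, task, rng, spec.tie_break)
            outcomes = tuple(int(x) for x in episode_rewards(episode))
        records.append(
            FishRecord(
                fish_id=f"fish_{i + 1:0{width}d}",
                cortisol_ng_ml=cort,
                cortisol_flag=flag,
                outcomes=outcomes,
            )
        )
    return records
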