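"""Cohort ingestion, validity filtering, normalization, and grouping.

A cohort is one row per fish: an identifier, a whole-body basal cortisol
measurement in ng/mL (possibly missing or flagged), and the binary outcomes
of its foraging trials (1 = entered the baited arm first).  The pipeline
keeps only fish whose cortisol assay is valid, rescales their cortisol to
[0, 1] by min-max normalization, and splits them into contiguous
ascending-cortisol groups of configured sizes.

CSV schema (UTF-8, header required)::

    fish_id,cortisol_ng_ml,cortisol_flag,trial_01,...,trial_NN

with optional trailing columns ``normalized_cortisol`` and ``group`` on
output.  Missing cortisol is an empty field; ``cortisol_flag`` is one of
``valid``, ``assay_failed``, ``outlier``.  Outliers are never auto-detected:
the flag column is the single source of truth for validity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bandit import validate_binary_outcomes
from .errors import (
    ConfigurationError,
    DegenerateRangeError,
    InsufficientDataError,
    MissingInputError,
    ValidationError,
)

logger = logging.getLogger(__name__)

CORTISOL_FLAGS = ("valid", "assay_failed", "outlier")

#: Group sizes of the reference study design: five ascending-cortisol groups.
DEFAULT_GROUP_SIZES = (16, 17, 16, 16, 17)
DEFAULT_N_TRIALS = 21


@dataclass(frozen=True)
class FishRecord:
    """One fish: identifier, basal cortisol (ng/mL or None), assay flag, and
    its complete binary trial outcomes."""

    fish_id: str
    cortisol_ng_ml: float | None
    cortisol_flag: str
    outcomes: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.cortisol_flag not in CORTISOL_FLAGS:
            raise ValidationError(
                f"fish {self.fish_id}: unknown cortisol_flag {self.cortisol_flag!r}"
            )
        if self.cortisol_flag == "valid":
            if self.cortisol_ng_ml is None or not np.isfinite(self.cortisol_ng_ml):
                raise ValidationError(
                    f"fish {self.fish_id}: flag is 'valid' but cortisol is missing"
                )
            if self.cortisol_ng_ml < 0:
                raise ValidationError(
                    f"fish {self.fish_id}: negative cortisol {self.cortisol_ng_ml}"
                )
        object.__setattr__(
            self, "outcomes", tuple(int(x) for x in validate_binary_outcomes(self.outcomes))
        )

    @property
    def average_reward(self) -> float:
        return average_reward(self.outcomes)


@dataclass
class Cohort:
    """A filtered, normalized, grouped cohort.

    ``records`` holds only the valid fish, in input order; ``normalized_cortisol``
    and ``group_labels`` align with it.  ``n_excluded`` counts the records
    dropped per flag.
    """

    records: list[FishRecord]
    normalized_cortisol: np.ndarray
    group_labels: np.ndarray
    group_sizes: tuple[int, ...]
    n_excluded: dict[str, int] = field(default_factory=dict)

    @property
    def n_valid(self) -> int:
        return len(self.records)

    @property
    def average_rewards(self) -> np.ndarray:
        return np.array([r.average_reward for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        """Valid fish as a DataFrame with normalized cortisol and group."""
        df = records_to_frame(self.records)
        df["normalized_cortisol"] = self.normalized_cortisol
        df["group"] = self.group_labels
        return df


def average_reward(outcomes: Sequence[int]) -> float:
    """Fraction of rewarded trials: sum of payoffs over the number of trials."""
    arr = validate_binary_outcomes(outcomes)
    return float(arr.sum() / arr.size)


def standard_error(values: Sequence[float]) -> float:
    """Sample SE: sd with the n-1 denominator divided by sqrt(n).

    Returns NaN for a single observation (an SE of a singleton is
    undefined, not zero).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        return float("nan")
    return float(arr.std(ddof=1) / np.sqrt(arr.size))


def filter_valid(records: Iterable[FishRecord]) -> list[FishRecord]:
    """Keep records whose cortisol assay succeeded, preserving order.

    Raises :class:`InsufficientDataError` when fewer than two valid records
    remain, since min-max normalization needs a nondegenerate range.
    """
    records = list(records)
    kept = [r for r in records if r.cortisol_flag == "valid"]
    removed: dict[str, int] = {}
    for r in records:
        if r.cortisol_flag != "valid":
            removed[r.cortisol_flag] = removed.get(r.cortisol_flag, 0) + 1
    for flag, count in sorted(removed.items()):
        logger.info("filter_valid: removed %d record(s) flagged %s", count, flag)
    logger.info("filter_valid: %d of %d records valid", len(kept), len(records))
    if len(kept) < 2:
        raise InsufficientDataError(
            f"need >= 2 valid cortisol records, got {len(kept)}"
        )
    return kept


def minmax_normalize(values: Sequence[float]) -> np.ndarray:
    """Rescale to [0, 1]: v -> (v - min) / (max - min)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("min-max normalization needs >= 2 values")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        raise DegenerateRangeError(f"all values equal ({lo}); range is degenerate")
    return (arr - lo) / (hi - lo)


def assign_groups(
    normalized: Sequence[float], sizes: Sequence[int] = DEFAULT_GROUP_SIZES
) -> np.ndarray:
    """Label fish 1..G by ascending normalized cortisol in blocks of ``sizes``.

    The sort is stable, so fish tied at a block boundary are split by input
    order: the earlier row goes to the lower group.  Returns labels aligned
    with the input order.
    """
    arr = np.asarray(normalized, dtype=float)
    sizes = tuple(int(s) for s in sizes)
    if any(s <= 0 for s in sizes):
        raise ConfigurationError(f"group sizes must be positive, got {sizes}")
    if sum(sizes) != arr.size:
        raise ConfigurationError(
            f"group sizes sum to {sum(sizes)} but there are {arr.size} fish"
        )
    order = np.argsort(arr, kind="stable")
    labels = np.empty(arr.size, dtype=int)
    start = 0
    for g, size in enumerate(sizes, start=1):
        labels[order[start : start + size]] = g
        start += size
    return labels


def build_cohort(
    records: Iterable[FishRecord], group_sizes: Sequence[int] = DEFAULT_GROUP_SIZES
) -> Cohort:
    """Filter, normalize, and group a raw record list into a :class:`Cohort`."""
    records = list(records)
    valid = filter_valid(records)
    removed: dict[str, int] = {}
    for r in records:
        if r.cortisol_flag != "valid":
            removed[r.cortisol_flag] = removed.get(r.cortisol_flag, 0) + 1
    normalized = minmax_normalize([r.cortisol_ng_ml for r in valid])
    labels = assign_groups(normalized, group_sizes)
    return Cohort(
        records=valid,
        normalized_cortisol=normalized,
        group_labels=labels,
        group_sizes=tuple(int(s) for s in group_sizes),
        n_excluded=removed,
    )


# ---------------------------------------------------------------------------
# CSV I/O


def _trial_columns(n_trials: int) -> list[str]:
    return [f"trial_{t:02d}" for t in range(1, n_trials + 1)]


def records_to_frame(records: Sequence[FishRecord]) -> pd.DataFrame:
    if not records:
        raise ValidationError("no records to write")
    n_trials = len(records[0].outcomes)
    rows = []
    for r in records:
        if len(r.outcomes) != n_trials:
            raise ValidationError(
                f"fish {r.fish_id}: expected {n_trials} outcomes, got {len(r.outcomes)}"
            )
        row: dict = {
            "fish_id": r.fish_id,
            "cortisol_ng_ml": r.cortisol_ng_ml,
            "cortisol_flag": r.cortisol_flag,
        }
        row.update(dict(zip(_trial_columns(n_trials), r.outcomes)))
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(
    records: Sequence[FishRecord],
    path: str | Path,
    normalized: Sequence[float] | None = None,
    group_labels: Sequence[int] | None = None,
) -> Path:
    """Write records to the cohort CSV schema.

    ``normalized`` / ``group_labels``, when given, must align with ``records``
    and are appended as the optional output columns.
    """
    df = records_to_frame(records)
    if normalized is not None:
        df["normalized_cortisol"] = np.asarray(normalized, dtype=float)
    if group_labels is not None:
        df["group"] = np.asarray(group_labels, dtype=int)
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def read_cohort(path: str | Path, n_trials: int | None = None) -> list[FishRecord]:
    """Read and validate a cohort CSV into :class:`FishRecord` objects.

    ``n_trials`` pins the expected trial count; by default it is inferred
    from the ``trial_NN`` columns present.  Trial outcomes must be complete
    and binary for every fish, including flagged ones.
    """
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"cohort file not found: {path}")
    df = pd.read_csv(path, dtype={"fish_id": str})
    required = {"fish_id", "cortisol_ng_ml", "cortisol_flag"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: missing required columns {sorted(required - set(df.columns))}"
        )
    trial_cols = sorted(c for c in df.columns if c.startswith("trial_"))
    if n_trials is not None:
        expected = _trial_columns(n_trials)
        if trial_cols != expected:
            raise ValidationError(
                f"{path}: expected trial columns trial_01..trial_{n_trials:02d}"
            )
    elif not trial_cols:
        raise ValidationError(f"{path}: no trial_NN outcome columns found")
    if df[trial_cols].isna().any().any():
        raise ValidationError(f"{path}: trial outcomes must be complete")
    records = []
    for _, row in df.iterrows():
        cort = row["cortisol_ng_ml"]
        records.append(
            FishRecord(
                fish_id=str(row["fish_id"]),
                cortisol_ng_ml=None if pd.isna(cort) else float(cort),
                cortisol_flag=str(row["cortisol_flag"]),
                outcomes=tuple(int(row[c]) for c in trial_cols),
            )
        )
    logger.info("read_cohort: %d records from %s", len(records), path)
    return records
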