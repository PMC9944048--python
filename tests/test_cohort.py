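"""Tests for cohort ingestion, filtering, normalization, and grouping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from forage_bandit.cohort import (
    FishRecord,
    assign_groups,
    average_reward,
    build_cohort,
    filter_valid,
    minmax_normalize,
    read_cohort,
    standard_error,
    write_cohort,
)
from forage_bandit.errors import (
    ConfigurationError,
    DegenerateRangeError,
    InsufficientDataError,
    MissingInputError,
    ValidationError,
)
from conftest import make_record


class TestFishRecord:
    def test_valid_flag_requires_cortisol(self):
        with pytest.raises(ValidationError):
            make_record(cortisol=None, flag="valid")

    def test_nonbinary_outcomes_rejected(self):
        with pytest.raises(ValidationError):
            make_record(outcomes=(0, 2) + (0,) * 19)

    def test_unknown_flag_rejected(self):
        with pytest.raises(ValidationError):
            make_record(flag="suspicious")

    def test_negative_cortisol_rejected(self):
        with pytest.raises(ValidationError):
            make_record(cortisol=-1.0)


class TestFilterValid:
    def test_study_counts(self):
        """86 records with 3 failed assays and 1 outlier leave 82 valid."""
        records = [make_record(f"f{i}", float(i + 1)) for i in range(82)]
        records += [make_record(f"x{i}", None, "assay_failed") for i in range(3)]
        records += [make_record("y0", 999.0, "outlier")]
        assert len(filter_valid(records)) == 82

    def test_all_valid_is_identity(self):
        records = [make_record(f"f{i}", float(i + 1)) for i in range(5)]
        assert filter_valid(records) == records

    def test_order_preserved(self, small_records):
        kept = filter_valid(small_records)
        assert [r.fish_id for r in kept] == ["f1", "f2", "f4", "f6"]

    def test_too_few_valid_records(self):
        records = [make_record("f1", 5.0)] + [
            make_record(f"x{i}", None, "assay_failed") for i in range(4)
        ]
        with pytest.raises(InsufficientDataError):
            filter_valid(records)


class TestMinmaxNormalize:
    def test_arithmetic(self):
        np.testing.assert_allclose(minmax_normalize([2, 5, 8]), [0, 0.5, 1])

    def test_study_extremes(self):
        np.testing.assert_allclose(minmax_normalize([1.68, 135.40]), [0, 1])

    def test_degenerate_range(self):
        with pytest.raises(DegenerateRangeError):
            minmax_normalize([3, 3, 3])

    def test_single_value(self):
        with pytest.raises(InsufficientDataError):
            minmax_normalize([3])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(0, 1e6, allow_nan=False, allow_infinity=False), min_size=2, max_size=40
        ).filter(lambda v: max(v) > min(v))
    )
    def test_idempotence_and_range(self, values):
        once = minmax_normalize(values)
        assert once.min() == 0.0 and once.max() == 1.0
        np.testing.assert_allclose(minmax_normalize(once), once, atol=1e-12)


class TestAssignGroups:
    def test_study_block_sizes_in_cortisol_order(self, rng):
        values = rng.permutation(np.linspace(0, 1, 82))
        labels = assign_groups(values, (16, 17, 16, 16, 17))
        sizes = np.bincount(labels, minlength=6)[1:]
        assert tuple(sizes) == (16, 17, 16, 16, 17)
        # within-group ranges ordered and disjoint
        maxima = [values[labels == g].max() for g in range(1, 6)]
        minima = [values[labels == g].min() for g in range(1, 6)]
        for g in range(4):
            assert maxima[g] < minima[g + 1]

    def test_singleton_groups_ascending(self):
        labels = assign_groups([0.9, 0.1, 0.5, 0.3, 0.7], (1, 1, 1, 1, 1))
        assert list(labels) == [5, 1, 3, 2, 4]

    def test_boundary_tie_is_stable_by_input_order(self):
        # both 0.5s straddle the block boundary: earlier row -> lower group
        labels = assign_groups([0.5, 0.5, 0.1, 0.9], (2, 2))
        assert list(labels) == [1, 2, 1, 2]

    def test_size_sum_mismatch(self):
        with pytest.raises(ConfigurationError):
            assign_groups([0.1, 0.2, 0.3], (2, 2))


class TestAverageReward:
    @pytest.mark.parametrize(
        "outcomes, expected",
        [((1,) * 7 + (0,) * 14, 1 / 3), ((0,) * 21, 0.0), ((1,) * 21, 1.0)],
    )
    def test_fraction_of_rewarded_trials(self, outcomes, expected):
        assert average_reward(outcomes) == pytest.approx(expected)

    def test_nonbinary_rejected(self):
        with pytest.raises(ValidationError):
            average_reward((0, 1, 2))

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            average_reward(())


class TestStandardError:
    def test_two_point_case(self):
        # sd of (0,1) is sqrt(1/2); /sqrt(2) gives exactly 0.5
        assert standard_error([0, 1]) == pytest.approx(0.5)

    def test_constant_values(self):
        assert standard_error([0.3, 0.3, 0.3]) == 0.0

    def test_singleton_is_nan(self):
        assert np.isnan(standard_error([0.5]))


class TestBuildCohort:
    def test_partition_and_normalization(self, small_records):
        cohort = build_cohort(small_records, (2, 2))
        assert cohort.n_valid == 4
        assert cohort.n_excluded == {"assay_failed": 1, "outlier": 1}
        assert cohort.normalized_cortisol.min() == 0.0
        assert cohort.normalized_cortisol.max() == 1.0
        assert sorted(np.bincount(cohort.group_labels, minlength=3)[1:]) == [2, 2]
        frame = cohort.to_frame()
        assert {"normalized_cortisol", "group"} <= set(frame.columns)


class TestCsvRoundTrip:
    def test_records_survive_write_read(self, small_records, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort(small_records, path)
        back = read_cohort(path)
        assert back == small_records

    def test_missing_file(self, tmp_path):
        with pytest.raises(MissingInputError):
            read_cohort(tmp_path / "nope.csv")

    def test_malformed_header(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,value\n1,2\n")
        with pytest.raises(ValidationError):
            read_cohort(path)

    def test_incomplete_outcomes_rejected(self, tmp_path):
        path = tmp_path / "gap.csv"
        path.write_text(
            "fish_id,cortisol_ng_ml,cortisol_flag,trial_01,trial_02\nf1,3.0,valid,1,\n"
        )
        with pytest.raises(ValidationError):
            read_cohort(path)

    def test_trial_count_pinning(self, small_records, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort(small_records, path)
        with pytest.raises(ValidationError):
            read_cohort(path, n_trials=10)
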