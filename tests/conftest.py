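import numpy as np
import pytest

from forage_bandit.cohort import FishRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(fish_id="f1", cortisol=10.0, flag="valid", outcomes=None, n_trials=21):
    if outcomes is None:
        outcomes = (0,) * n_trials
    return FishRecord(
        fish_id=fish_id, cortisol_ng_ml=cortisol, cortisol_flag=flag, outcomes=tuple(outcomes)
    )


@pytest.fixture
def small_records():
    """Six fish, four valid, with distinct cortisol values and mixed outcomes."""
    return [
        make_record("f1", 2.0, "valid", (1,) * 21),
        make_record("f2", 5.0, "valid", (0,) * 21),
        make_record("f3", None, "assay_failed", (0, 1) * 10 + (0,)),
        make_record("f4", 8.0, "valid", (1, 0) * 10 + (1,)),
        make_record("f5", 900.0, "outlier", (1,) * 21),
        make_record("f6", 11.0, "valid", (0,) * 20 + (1,)),
    ]
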