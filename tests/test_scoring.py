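"""The 4-item scoring rule, reference labels, and cohort classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrascore import (
    HIGH,
    LOW,
    ItemCutoffs,
    classify_cohort,
    reference_label,
    score_items,
)
from hydrascore.scoring import MissingDataError, ScoringError

# marker values sitting exactly on each cut-off (item = 0) or just missing
# it (item = 1), for a male respondent
BOUNDARY = {
    "reported_intake_24h": (3697, 3696),
    "reported_void_count_24h": (7, 6),
    "spot_volume": (250, 249),
    "color_score": (2, 3),
}


def male_record(**kw):
    rec = {
        "sex": "male",
        "reported_intake_24h": 4000,
        "reported_void_count_24h": 8,
        "spot_volume": 400,
        "color_score": 1,
    }
    rec.update(kw)
    return rec


@pytest.mark.parametrize("bits", list(itertools.product((0, 1), repeat=4)))
def test_boundary_matrix_forces_item_pattern(bits):
    """All 2^4 boundary combinations force the item pattern, total and class."""
    markers = dict(zip(BOUNDARY, (BOUNDARY[k][b] for k, b in zip(BOUNDARY, bits))))
    scores = score_items(male_record(**markers))
    assert (
        scores.intake_item,
        scores.frequency_item,
        scores.volume_item,
        scores.color_item,
    ) == bits
    assert scores.total == sum(bits)
    assert scores.predicted_class == (HIGH if sum(bits) >= 2 else LOW)


def test_female_intake_threshold_and_mixed_pattern():
    scores = score_items(
        {
            "sex": "female",
            "reported_intake_24h": 2697,
            "reported_void_count_24h": 8,
            "spot_volume": 100,
            "color_score": 3,
        }
    )
    assert (scores.intake_item, scores.frequency_item,
            scores.volume_item, scores.color_item) == (0, 0, 1, 1)
    assert scores.total == 2 and scores.predicted_class == HIGH


def test_missing_marker_aborts_scoring():
    with pytest.raises(MissingDataError, match="spot_volume"):
        score_items(male_record(spot_volume=None))
    with pytest.raises(MissingDataError):
        score_items(male_record(reported_intake_24h=float("nan")))


def test_unknown_sex_is_an_error():
    with pytest.raises(ScoringError, match="sex"):
        score_items(male_record(sex="unknown"))


@settings(deadline=None, max_examples=200)
@given(
    intake=st.floats(0, 8000),
    freq=st.integers(0, 15),
    vol=st.floats(1, 1500),
    color=st.integers(1, 7),
    sex=st.sampled_from(["female", "male"]),
    bump=st.sampled_from(["intake", "freq", "vol", "color"]),
)
def test_improving_any_marker_never_raises_score(intake, freq, vol, color, sex, bump):
    base = {
        "sex": sex,
        "reported_intake_24h": intake,
        "reported_void_count_24h": freq,
        "spot_volume": vol,
        "color_score": color,
    }
    better = dict(base)
    if bump == "intake":
        better["reported_intake_24h"] = intake + 500
    elif bump == "freq":
        better["reported_void_count_24h"] = freq + 1
    elif bump == "vol":
        better["spot_volume"] = vol + 100
    else:
        better["color_score"] = max(1, color - 1)
    assert score_items(better).total <= score_items(base).total


class TestReferenceLabel:
    @pytest.mark.parametrize(
        "usg,cutoff,label",
        [
            (1.012, "low", LOW),
            (1.013, "low", HIGH),
            (1.0124, "low", LOW),
            (1.0125, "low", HIGH),  # rounds half-up to 1.013
            (1.019, "high", LOW),
            (1.020, "high", HIGH),
            (1.0195, "high", HIGH),  # rounds half-up to 1.020
        ],
    )
    def test_cutoff_boundaries_at_recording_precision(self, usg, cutoff, label):
        assert reference_label(usg, cutoff) == label

    def test_out_of_range_usg_is_an_error(self):
        with pytest.raises(ScoringError):
            reference_label(1.05, "low")

    def test_unknown_cutoff_is_an_error(self):
        with pytest.raises(ScoringError):
            reference_label(1.010, "mid")


class TestClassifyCohort:
    def test_zero_noise_cohort_classifies_perfectly(self, zero_noise_classified):
        cl = zero_noise_classified
        assert (cl["predicted_class"] == cl["reference_label"]).all()

    def test_single_record_cohort(self):
        df = pd.DataFrame([{**male_record(), "participant_id": "P1",
                            "session": "morning", "usg_24h": 1.010}])
        classified, incomplete = classify_cohort(df)
        assert len(classified) == 1 and len(incomplete) == 0

    def test_incomplete_records_are_excluded_not_imputed(self, default_features):
        df = default_features.copy()
        df.loc[df.index[:3], "color_score"] = np.nan
        classified, incomplete = classify_cohort(df)
        assert len(incomplete) == 3
        assert len(classified) == len(df) - 3

    def test_duplicate_keys_are_an_error(self):
        row = {**male_record(), "participant_id": "P1", "session": "morning",
               "usg_24h": 1.010}
        with pytest.raises(ScoringError, match="duplicate"):
            classify_cohort(pd.DataFrame([row, row]))

    def test_roundtrip_through_csv_is_lossless(self, default_classified, tmp_path):
        path = tmp_path / "classified.csv"
        default_classified.to_csv(path, index=False)
        back = pd.read_csv(path)
        for col in ("intake_item", "frequency_item", "volume_item", "color_item",
                    "total_score"):
            assert (back[col].to_numpy() == default_classified[col].to_numpy()).all()
        assert (back["predicted_class"] == default_classified["predicted_class"]).all()
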