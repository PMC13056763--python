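"""The 4-item hydration self-assessment model and USG reference labels.

The instrument scores four self-observable markers against fixed cut-offs.
Each item contributes 0 when the marker suggests a LOW urine concentration
(fluid intake at or above the sex-specific reference, spot-void volume
>= 250 mL, 24-h void frequency >= 7, urine colour <= 2) and 1 otherwise.
A total of 0-1 predicts a low 24-h urine concentration (optimal fluid
intake); 2-4 predicts a high concentration (suboptimal intake).

The reference standard is the volume-weighted 24-h USG, dichotomised at
either the low cut-off (low iff USG <= 1.012, i.e. high iff >= 1.013) or
the high cut-off (high iff USG >= 1.020).  USG values are compared after
rounding to 3 decimals, the instrument's recording precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .constants import (
    INTAKE_NEED_FEMALE_ML,
    INTAKE_NEED_MALE_ML,
    USG_CUTOFF_HIGH,
    USG_CUTOFF_LOW,
    USG_MAX,
    USG_MIN,
)

LOW = "low_concentration"
HIGH = "high_concentration"

FEMALE = "female"
MALE = "male"

ITEM_NAMES = ("intake_item", "frequency_item", "volume_item", "color_item")


class ScoringError(ValueError):
    """Raised for invalid scoring inputs."""


class MissingDataError(ScoringError):
    """Raised when a record lacks a marker the model requires."""


@dataclass(frozen=True)
class ItemCutoffs:
    """Cut-offs of the four model items, inclusive on the low-concentration side."""

    intake_female_ml: float = INTAKE_NEED_FEMALE_ML
    intake_male_ml: float = INTAKE_NEED_MALE_ML
    spot_volume_ml: float = 250.0
    void_frequency: int = 7
    color_max_low: int = 2

    def __post_init__(self) -> None:
        for name in ("intake_female_ml", "intake_male_ml", "spot_volume_ml", "void_frequency"):
            if not getattr(self, name) > 0:
                raise ScoringError(f"cutoff {name} must be positive")
        if not 1 <= self.color_max_low <= 6:
            raise ScoringError("color_max_low must lie in 1..6")

    def intake_need(self, sex: str) -> float:
        if sex == FEMALE:
            return self.intake_female_ml
        if sex == MALE:
            return self.intake_male_ml
        raise ScoringError(f"unknown sex {sex!r}; expected 'female' or 'male'")


@dataclass(frozen=True)
class ItemScores:
    """The four 0/1 item flags, their sum, and the predicted class."""

    intake_item: int
    frequency_item: int
    volume_item: int
    color_item: int

    @property
    def total(self) -> int:
        return self.intake_item + self.frequency_item + self.volume_item + self.color_item

    @property
    def predicted_class(self) -> str:
        return HIGH if self.total >= 2 else LOW


def _require(record, name: str):
    try:
        value = record[name]
    except (KeyError, IndexError, TypeError):
        raise MissingDataError(f"record is missing marker {name!r}") from None
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise MissingDataError(f"marker {name!r} is missing (None/NaN)")
    return value


def score_items(record, cutoffs: ItemCutoffs = ItemCutoffs()) -> ItemScores:
    """Score one complete assessment record against the four cut-offs.

    ``record`` is any mapping with keys sex, reported_intake_24h,
    reported_void_count_24h, spot_volume and color_score.  Missing markers
    raise :class:`MissingDataError`; the model is defined only on complete
    4-item records and never imputes.
    """
    sex = _require(record, "sex")
    intake = float(_require(record, "reported_intake_24h"))
    frequency = float(_require(record, "reported_void_count_24h"))
    volume = float(_require(record, "spot_volume"))
    color = int(_require(record, "color_score"))
    if not 1 <= color <= 7:
        raise ScoringError(f"color score must lie in 1..7, got {color}")
    return ItemScores(
        intake_item=0 if intake >= cutoffs.intake_need(sex) else 1,
        frequency_item=0 if frequency >= cutoffs.void_frequency else 1,
        volume_item=0 if volume >= cutoffs.spot_volume_ml else 1,
        color_item=0 if color <= cutoffs.color_max_low else 1,
    )


def _round3(usg: float) -> float:
    return float(Decimal(repr(float(usg))).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def reference_label(usg_24h: float, cutoff: str = "low") -> str:
    """Dichotomise a 24-h USG at the chosen reference cut-off.

    ``cutoff="low"``: low iff USG <= 1.012 (optimal fluid intake), high iff
    >= 1.013.  ``cutoff="high"``: high iff USG >= 1.020.  Comparison uses
    the value rounded to 3 decimals.
    """
    if not (USG_MIN <= usg_24h <= USG_MAX):
        raise ScoringError(
            f"USG {usg_24h} outside physiologic range [{USG_MIN}, {USG_MAX}]"
        )
    u = _round3(usg_24h)
    if cutoff == "low":
        return LOW if u <= USG_CUTOFF_LOW else HIGH
    if cutoff == "high":
        return HIGH if u >= USG_CUTOFF_HIGH else LOW
    raise ScoringError(f"unknown cutoff {cutoff!r}; expected 'low' or 'high'")


def classify_cohort(
    records: pd.DataFrame,
    cutoffs: ItemCutoffs = ItemCutoffs(),
    usg_cutoff: str = "low",
    usg_col: str = "usg_24h",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score and reference-label every complete participant-session record.

    Returns ``(classified, incomplete)``: the main table holds one row per
    complete record with the four items, total, predicted class and
    reference label; records with any missing marker are returned
    separately with the reason, never silently imputed.  Duplicate
    (participant, session) keys are an error.
    """
    keys = records[["participant_id", "session"]].astype(str)
    dupes = keys[keys.duplicated()]
    if len(dupes):
        raise ScoringError(
            f"duplicate (participant, session) keys: {dupes.values.tolist()[:5]}"
        )
    rows, skipped = [], []
    for rec in records.to_dict("records"):
        try:
            usg = _require(rec, usg_col)
            scores = score_items(rec, cutoffs)
            label = reference_label(float(usg), usg_cutoff)
        except MissingDataError as err:
            skipped.append({**rec, "reason": str(err)})
            continue
        rows.append(
            {
                "participant_id": rec["participant_id"],
                "session": rec["session"],
                "intake_item": scores.intake_item,
                "frequency_item": scores.frequency_item,
                "volume_item": scores.volume_item,
                "color_item": scores.color_item,
                "total_score": scores.total,
                "predicted_class": scores.predicted_class,
                usg_col: float(usg),
                "reference_label": label,
            }
        )
    classified = pd.DataFrame(rows)
    incomplete = pd.DataFrame(skipped)
    return classified, incomplete
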