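"""Derived hydration features from raw void streams and self-assessments.

A participant collects every urine void over 32 hours; two intentionally
overlapping 24-h collection windows are anchored at the morning and
afternoon self-assessment times.  This module turns the raw records into
the quantities the downstream scoring and diagnostics stages consume:
the volume-weighted 24-h USG, window volume and void frequency, the thirst
VAS percentage, the body-mass change from a two-day baseline, and the
long-void flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import (
    BODY_MASS_DROP_PCT,
    LONG_VOID_MIN_S,
    THIRST_NOT_THIRSTY_MAX_PCT,
    THIRST_VAS_FULL_MM,
    USG_MAX,
    USG_MIN,
)

WINDOW_HOURS = 24.0
DEFAULT_SESSION_OFFSET_HOURS = 8.0

MORNING = "morning"
AFTERNOON = "afternoon"


class FeatureError(ValueError):
    """Raised for invalid inputs to feature computations."""


@dataclass(frozen=True)
class Void:
    """One timestamped urine sample with its volume (mL) and USG."""

    participant_id: str
    time: pd.Timestamp
    volume: float
    usg: float

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise FeatureError(f"void volume must be > 0, got {self.volume}")
        if not (USG_MIN <= self.usg <= USG_MAX):
            raise FeatureError(
                f"void USG {self.usg} outside physiologic range "
                f"[{USG_MIN}, {USG_MAX}]"
            )


@dataclass
class CollectionWindow:
    """A half-open 24-h interval (start, end] and the voids inside it.

    ``partial`` flags windows anchored earlier than 24 h after the first
    recorded void, i.e. windows that cannot have full coverage.
    """

    participant_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    voids: list[Void] = field(default_factory=list)
    label: str = MORNING
    partial: bool = False

    def __post_init__(self) -> None:
        span = (self.end - self.start) / pd.Timedelta(hours=1)
        if not math.isclose(span, WINDOW_HOURS):
            raise FeatureError(f"window must span 24 h, got {span:.3f} h")
        for v in self.voids:
            if not (self.start < v.time <= self.end):
                raise FeatureError(
                    f"void at {v.time} outside half-open window "
                    f"({self.start}, {self.end}]"
                )


def _as_voids(voids: Iterable[Void] | pd.DataFrame) -> list[Void]:
    if isinstance(voids, pd.DataFrame):
        return [
            Void(str(r.participant_id), pd.Timestamp(r.time), float(r.volume), float(r.usg))
            for r in voids.itertuples()
        ]
    return list(voids)


def extract_windows(
    voids: Iterable[Void] | pd.DataFrame,
    assessment_times: Sequence[pd.Timestamp],
) -> tuple[CollectionWindow, CollectionWindow]:
    """Anchor one 24-h window at each assessment time.

    Each window is the half-open interval (t - 24 h, t]: a void produced at
    the assessment moment belongs to the period it concludes, and a void at
    exactly t - 24 h is excluded.  With the default 8-h offset between the
    morning and afternoon assessments the two windows share 16 h of the
    32-h stream, so a void may belong to both windows.
    """
    vlist = sorted(_as_voids(voids), key=lambda v: v.time)
    if not vlist:
        raise FeatureError("cannot extract windows from an empty void list")
    if len(assessment_times) != 2:
        raise FeatureError("assessment_times must be a pair (morning, afternoon)")
    t_morning, t_afternoon = (pd.Timestamp(t) for t in assessment_times)
    if t_afternoon <= t_morning:
        raise FeatureError("afternoon assessment must follow the morning one")

    pid = vlist[0].participant_id
    first_time = vlist[0].time
    out = []
    for t, label in ((t_morning, MORNING), (t_afternoon, AFTERNOON)):
        start = t - pd.Timedelta(hours=WINDOW_HOURS)
        members = [v for v in vlist if start < v.time <= t]
        out.append(
            CollectionWindow(
                participant_id=pid,
                start=start,
                end=t,
                voids=members,
                label=label,
                partial=bool(t < first_time + pd.Timedelta(hours=WINDOW_HOURS)),
            )
        )
    return out[0], out[1]


def weighted_usg(window: CollectionWindow | Sequence[Void]) -> float:
    """Volume-weighted mean USG of a collection window.

    Computed as sum(USG_i * Volume_i) / sum(Volume_i) over all member
    voids; the result always lies within [min USG_i, max USG_i].
    """
    voids = window.voids if isinstance(window, CollectionWindow) else list(window)
    if not voids:
        raise FeatureError("weighted USG of an empty window is undefined")
    volumes = np.array([v.volume for v in voids], dtype=float)
    usgs = np.array([v.usg for v in voids], dtype=float)
    total = volumes.sum()
    if total <= 0:
        raise FeatureError("total window volume must be > 0")
    value = float(np.dot(usgs, volumes) / total)
    # float round-off must not escape the member range (boundedness invariant)
    return float(min(max(value, usgs.min()), usgs.max()))


def window_metrics(window: CollectionWindow) -> dict:
    """24-h urine volume (mL), void count, and volume-weighted USG."""
    if not window.voids:
        raise FeatureError("window metrics of an empty window are undefined")
    return {
        "volume_24h": float(sum(v.volume for v in window.voids)),
        "void_count_24h": len(window.voids),
        "weighted_usg": weighted_usg(window),
    }


def thirst_percent(vas_mm: float) -> dict:
    """Thirst VAS response as a percentage of the full 175-mm line.

    Returns the percentage plus the companion ``not_thirsty`` predicate,
    true when the percentage is at most 40 (boundary inclusive).
    """
    if vas_mm < 0:
        raise FeatureError(f"VAS length must be >= 0 mm, got {vas_mm}")
    pct = 100.0 * float(vas_mm) / THIRST_VAS_FULL_MM
    return {"percent": pct, "not_thirsty": pct <= THIRST_NOT_THIRSTY_MAX_PCT}


@dataclass(frozen=True)
class BodyMassSeries:
    """Fasted morning body mass (kg) on three consecutive days."""

    participant_id: str
    day1_kg: float
    day2_kg: float
    day3_kg: float

    def __post_init__(self) -> None:
        for name in ("day1_kg", "day2_kg", "day3_kg"):
            if not getattr(self, name) > 0:
                raise FeatureError(f"{name} must be > 0")


def body_mass_change(series: BodyMassSeries) -> dict:
    """Day-2 body-mass change from the day-1/day-3 average baseline.

    A decrease of at least 1% (boundary inclusive) flags possible
    underhydration; gains never flag.
    """
    baseline = (series.day1_kg + series.day3_kg) / 2.0
    pct = 100.0 * (series.day2_kg - baseline) / baseline
    # tolerance keeps the inclusive boundary robust to float round-off
    return {"percent_change": pct, "flag_ge_1pct": pct <= -BODY_MASS_DROP_PCT + 1e-9}


def long_void_flag(duration_s: float) -> bool:
    """True when a void lasted at least 16 s, indicating a larger volume."""
    if duration_s < 0:
        raise FeatureError(f"void duration must be >= 0 s, got {duration_s}")
    return duration_s >= LONG_VOID_MIN_S


def build_features(
    voids: pd.DataFrame,
    assessments: pd.DataFrame,
    bodymass: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One feature row per participant-session.

    ``voids`` needs columns participant_id/time/volume/usg; ``assessments``
    needs participant_id/session/assessment_time plus the self-reported
    markers; ``bodymass`` (optional) needs participant_id/day1_kg/day2_kg/
    day3_kg.  Window anchors are taken from each participant's recorded
    assessment times.
    """
    voids = voids.copy()
    voids["time"] = pd.to_datetime(voids["time"])
    assessments = assessments.copy()
    assessments["assessment_time"] = pd.to_datetime(assessments["assessment_time"])

    bm_map: dict[str, dict] = {}
    if bodymass is not None:
        for r in bodymass.itertuples():
            bm_map[str(r.participant_id)] = body_mass_change(
                BodyMassSeries(str(r.participant_id), r.day1_kg, r.day2_kg, r.day3_kg)
            )

    rows = []
    for pid, grp in assessments.groupby("participant_id", sort=True):
        pid = str(pid)
        pvoids = voids[voids["participant_id"].astype(str) == pid]
        times = grp.set_index("session")["assessment_time"]
        if MORNING not in times.index or AFTERNOON not in times.index:
            raise FeatureError(f"participant {pid} lacks a morning/afternoon pair")
        w_m, w_a = extract_windows(pvoids, (times[MORNING], times[AFTERNOON]))
        windows = {MORNING: w_m, AFTERNOON: w_a}
        for rec in grp.itertuples():
            w = windows[rec.session]
            met = window_metrics(w)
            thirst = thirst_percent(float(rec.thirst_vas_mm))
            row = {
                "participant_id": pid,
                "session": rec.session,
                "sex": rec.sex,
                "usg_24h": met["weighted_usg"],
                "volume_24h": met["volume_24h"],
                "void_count_24h": met["void_count_24h"],
                "window_partial": w.partial,
                "reported_intake_24h": float(rec.reported_intake_24h),
                "reported_void_count_24h": int(rec.reported_void_count_24h),
                "spot_volume": float(rec.spot_volume),
                "color_score": int(rec.color_score),
                "thirst_vas_mm": float(rec.thirst_vas_mm),
                "thirst_percent": thirst["percent"],
                "not_thirsty": thirst["not_thirsty"],
                "void_duration_s": float(rec.void_duration_s),
                "long_void": long_void_flag(float(rec.void_duration_s)),
            }
            bm = bm_map.get(pid)
            row["bm_percent_change"] = bm["percent_change"] if bm else np.nan
            row["bm_flag_ge_1pct"] = bm["flag_ge_1pct"] if bm else False
            rows.append(row)
    return pd.DataFrame(rows).sort_values(["participant_id", "session"], ascending=[True, False]).reset_index(drop=True)
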