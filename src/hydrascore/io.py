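"""Delimited-text schemas and validated readers/writers.

All tables are plain RFC-4180 CSV with documented headers and ISO-8601,
timezone-naive timestamps (the study design works in local clock time).
Readers validate the schema: a missing required column is fatal, while a
malformed row is collected into an error report (with its line number)
and the run continues.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .constants import USG_MAX, USG_MIN

VOID_COLUMNS = ("participant_id", "time", "volume", "usg")
ASSESSMENT_COLUMNS = (
    "participant_id", "session", "assessment_time", "sex",
    "reported_intake_24h", "reported_void_count_24h", "spot_volume",
    "color_score", "thirst_vas_mm", "void_duration_s",
)
BODYMASS_COLUMNS = ("participant_id", "day1_kg", "day2_kg", "day3_kg")


class SchemaError(ValueError):
    """Raised when a file cannot satisfy its table schema."""


@dataclass(frozen=True)
class RowError:
    line: int  # 1-based line number in the file (header is line 1)
    message: str


def _read(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def _validate_rows(df: pd.DataFrame, checks) -> tuple[pd.DataFrame, list[RowError]]:
    errors: list[RowError] = []
    keep = []
    for idx, row in df.iterrows():
        problem = None
        for check, message in checks:
            try:
                if not check(row):
                    problem = message
                    break
            except Exception as exc:  # unparsable value
                problem = f"{message} ({exc})"
                break
        if problem is None:
            keep.append(idx)
        else:
            errors.append(RowError(line=int(idx) + 2, message=problem))
    return df.loc[keep].reset_index(drop=True), errors


def read_voids(path: str | Path) -> tuple[pd.DataFrame, list[RowError]]:
    """Read and validate a voids table (one row per urine void)."""
    df = _read(path, VOID_COLUMNS)
    checks = [
        (lambda r: pd.notna(pd.Timestamp(r["time"])), "unparsable timestamp"),
        (lambda r: float(r["volume"]) > 0, "volume must be > 0 mL"),
        (lambda r: USG_MIN <= float(r["usg"]) <= USG_MAX,
         f"USG outside [{USG_MIN}, {USG_MAX}]"),
    ]
    df, errors = _validate_rows(df, checks)
    df["time"] = pd.to_datetime(df["time"])
    df["volume"] = df["volume"].astype(float)
    df["usg"] = df["usg"].astype(float)
    return df, errors


def read_assessments(path: str | Path) -> tuple[pd.DataFrame, list[RowError]]:
    """Read and validate a self-assessments table (one row per session)."""
    df = _read(path, ASSESSMENT_COLUMNS)
    checks = [
        (lambda r: r["session"] in ("morning", "afternoon"), "unknown session"),
        (lambda r: pd.notna(pd.Timestamp(r["assessment_time"])), "unparsable timestamp"),
        (lambda r: r["sex"] in ("female", "male"), "unknown sex"),
        (lambda r: float(r["reported_intake_24h"]) >= 0, "negative intake"),
        (lambda r: int(r["reported_void_count_24h"]) >= 0, "negative void count"),
        (lambda r: float(r["spot_volume"]) > 0, "spot volume must be > 0 mL"),
        (lambda r: 1 <= int(r["color_score"]) <= 7, "colour score outside 1..7"),
        (lambda r: float(r["thirst_vas_mm"]) >= 0, "negative VAS length"),
        (lambda r: float(r["void_duration_s"]) >= 0, "negative void duration"),
    ]
    df, errors = _validate_rows(df, checks)
    df["assessment_time"] = pd.to_datetime(df["assessment_time"])
    return df, errors


def read_bodymass(path: str | Path) -> tuple[pd.DataFrame, list[RowError]]:
    """Read and validate the three-day body-mass table."""
    df = _read(path, BODYMASS_COLUMNS)
    checks = [
        (lambda r: all(float(r[c]) > 0 for c in BODYMASS_COLUMNS[1:]),
         "body mass must be > 0 kg"),
    ]
    return _validate_rows(df, checks)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
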