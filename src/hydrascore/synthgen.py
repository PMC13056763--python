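"""Synthetic cohorts of 32-h void streams, diaries and self-assessments.

The generator is a statistical emulator, not a renal-physiology model.  A
single latent factor per participant — fluid-balance adequacy ``a``
(intake relative to the sex-specific reference need of 2697 mL for
females / 3697 mL for males, net of losses) — drives everything:

* latent 24-h USG = 1.0125 + intake_usg_slope * (a - 1) + Gaussian noise,
  clamped to the physiologic range.  1.0125 is the continuous boundary
  between the <= 1.012 and >= 1.013 reference classes, and the slope is
  <= 0, so USG decreases with adequacy and ``a = 1`` sits exactly on the
  low/high boundary;
* each marker taps its own dispersed copy of the factor,
  ``m_k = a * exp(eps_k)`` with eps_k ~ N(0, marker_dispersion_sd) —
  intake is one input to fluid balance, frequency/volume/colour reflect
  renal output — so every marker carries signal about USG that the others
  do not fully contain;
* every observable marker is a monotone map of its ``m_k`` calibrated so
  the model cut-off corresponds exactly to ``m_k = 1`` (intake at the
  sex-specific reference, void frequency 7, spot volume 250 mL, colour
  level 2/3 edge), plus marker-specific reporting noise.

With all noise scales at zero the 4-item score therefore classifies the
reference label perfectly by construction, and with the slope at zero the
markers carry no information about USG at all — the two anchor points the
evaluation chain is tested against.

Each participant's 32-h stream starts at ~08:00 on day 1 and yields two
24-h windows (ending at the 24-h morning and 32-h afternoon assessments)
that share the middle 16 h of voids.  No voids occur in the sleep block;
the first-morning void accumulates overnight and is the morning spot
sample, mirroring the larger morning spot volumes seen in field data.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import (
    COLOR_BREAKPOINTS,
    INTAKE_NEED_FEMALE_ML,
    INTAKE_NEED_MALE_ML,
    USG_LOW_BOUNDARY,
    USG_MAX,
    USG_MIN,
)
from .scoring import FEMALE, MALE

SPOT_CUTOFF_ML = 250.0
URINE_FLOW_ML_PER_S = 22.0  # nominal void flow used to derive durations
VOID_COUNT_EXPONENT = 0.8  # void frequency ~ rate * a**exponent

RACE_LEVELS = ("white", "asian", "american_indian", "pacific_islander", "mixed")
RACE_PROBS = (0.64, 0.22, 0.04, 0.01, 0.09)
HIRE_LEVELS = ("year", "seasonal", "not_applicable")
HIRE_PROBS = (0.365, 0.365, 0.27)


class ConfigError(ValueError):
    """Raised when a generator configuration field is invalid."""


@dataclass(frozen=True)
class SelfReportNoise:
    """Per-marker reporting-error scales (all zero => exact reporting)."""

    intake_cv: float = 0.12  # lognormal cv of each diary period
    void_count_sd: float = 0.9  # additive sd on the self-tallied count
    spot_volume_cv: float = 0.18  # lognormal cv of the spot volume
    morning_distortion_sd: float = 0.35  # lognormal adequacy drift of the
    # overnight-accumulated morning spot sample (volume and colour)
    duration_cv: float = 0.2  # lognormal cv of the timed void duration

    @classmethod
    def zero(cls) -> "SelfReportNoise":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)

    def validate(self) -> None:
        for name in ("intake_cv", "void_count_sd", "spot_volume_cv",
                     "morning_distortion_sd", "duration_cv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"self_report_noise.{name} must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults reproduce the development cohort's descriptive marginals:
    median daily intake ~4300 mL, 24-h urine volume ~2150 mL, void count
    7, 24-h USG ~1.011, morning/afternoon spot volumes ~450/~330 mL.
    """

    n_participants: int = 85
    female_fraction: float = 0.12
    seed: int = 0
    daily_intake_log_mean: float = math.log(4300.0)  # male-referenced, mL
    daily_intake_log_sd: float = 0.48
    intake_usg_slope: float = -0.008  # <= 0; USG units per unit adequacy
    usg_noise_sd: float = 0.002  # latent residual and per-void spread
    marker_dispersion_sd: float = 0.2  # lognormal sd of each marker's factor copy
    void_rate_per_day: float = 7.0
    spot_volume_mean_morning: float = 450.0  # mL at median adequacy
    spot_volume_mean_afternoon: float = 330.0
    color_noise: float = 0.15  # probability of a +/-1 level misreading
    self_report_noise: SelfReportNoise = field(default_factory=SelfReportNoise)
    urine_output_fraction: float = 0.5  # 24-h urine volume / daily intake
    urine_volume_cv: float = 0.12
    sleep_start_hour: float = 23.0  # local clock, no voids while asleep
    sleep_end_hour: float = 6.0
    start_date: str = "2024-06-01"

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigError("female_fraction must lie in [0, 1]")
        if self.daily_intake_log_sd <= 0:
            raise ConfigError("daily_intake_log_sd must be > 0")
        if self.intake_usg_slope > 0:
            raise ConfigError("intake_usg_slope must be <= 0")
        if self.usg_noise_sd < 0:
            raise ConfigError("usg_noise_sd must be >= 0")
        if self.marker_dispersion_sd < 0:
            raise ConfigError("marker_dispersion_sd must be >= 0")
        if self.void_rate_per_day <= 0:
            raise ConfigError("void_rate_per_day must be > 0")
        for name in ("spot_volume_mean_morning", "spot_volume_mean_afternoon"):
            if getattr(self, name) < SPOT_CUTOFF_ML:
                raise ConfigError(f"{name} must be >= {SPOT_CUTOFF_ML} mL")
        if not 0.0 <= self.color_noise <= 1.0:
            raise ConfigError("color_noise must lie in [0, 1]")
        if not 0 < self.urine_output_fraction <= 1:
            raise ConfigError("urine_output_fraction must lie in (0, 1]")
        if self.urine_volume_cv < 0:
            raise ConfigError("urine_volume_cv must be >= 0")
        if self.daily_intake_log_mean <= math.log(INTAKE_NEED_MALE_ML):
            raise ConfigError(
                "daily_intake_log_mean must exceed log of the male intake "
                "reference (spot-volume calibration anchors at median adequacy > 1)"
            )
        self.self_report_noise.validate()

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)

    # --- presets ---------------------------------------------------------
    @classmethod
    def zero_noise(cls, **kw) -> "GeneratorConfig":
        """All dispersion and reporting noise off: markers equal their
        latents and the 4-item score classifies the reference perfectly."""
        return cls(usg_noise_sd=0.0, color_noise=0.0, marker_dispersion_sd=0.0,
                   self_report_noise=SelfReportNoise.zero(), **kw)

    @classmethod
    def uncoupled(cls, **kw) -> "GeneratorConfig":
        """Markers carry no information about USG (slope = 0)."""
        return cls(intake_usg_slope=0.0, **kw)

    @classmethod
    def strong_coupling(cls, **kw) -> "GeneratorConfig":
        """High-signal cohort: steep adequacy->USG slope, small residual,
        and tight (but finite) marker reporting noise."""
        return cls(
            intake_usg_slope=-0.012,
            usg_noise_sd=0.0015,
            marker_dispersion_sd=0.25,
            color_noise=0.05,
            self_report_noise=SelfReportNoise(
                intake_cv=0.06, void_count_sd=0.5, spot_volume_cv=0.10,
                morning_distortion_sd=0.35, duration_cv=0.2,
            ),
            **kw,
        )


def color_from_usg(usg, noise: float = 0.0, rng: np.random.Generator | None = None):
    """Map USG to the 1..7 ordinal colour level of the 7-level chart.

    The base map is a monotone non-decreasing step function over the fixed
    breakpoint table (levels 1-2 cover USG <= 1.012).  With noise
    probability p, the level is perturbed one step up or down (equal odds)
    and clamped to 1..7.  USG outside [1.000, 1.040] is a domain error.
    """
    u = np.asarray(usg, dtype=float)
    if np.any(u < USG_MIN) or np.any(u > USG_MAX):
        raise ConfigError(f"USG outside physiologic range [{USG_MIN}, {USG_MAX}]")
    if not 0.0 <= noise <= 1.0:
        raise ConfigError("color noise must lie in [0, 1]")
    level = np.searchsorted(np.asarray(COLOR_BREAKPOINTS), u, side="left") + 1
    if noise > 0:
        if rng is None:
            raise ConfigError("a Generator is required when color noise > 0")
        flip = rng.random(level.shape) < noise
        step = rng.choice([-1, 1], size=level.shape)
        level = np.clip(level + flip * step, 1, 7)
    level = level.astype(int)
    return int(level) if np.isscalar(usg) else level


@dataclass
class SyntheticCohort:
    """Generated tables plus the latent per-participant ground truth."""

    config: GeneratorConfig
    participants: pd.DataFrame
    voids: pd.DataFrame
    diaries: pd.DataFrame
    assessments: pd.DataFrame
    bodymass: pd.DataFrame
    truth: pd.DataFrame
    latent: pd.DataFrame

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Serialize all tables as CSV; identical seeds give identical bytes."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("participants", "voids", "diaries", "assessments",
                     "bodymass", "truth"):
            path = out / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False)
            paths[name] = path
        return paths


def _allocate_counts(n_window: int) -> tuple[int, int]:
    """Split a per-window void count into edge/shared segment counts.

    Returns (edge, shared): ``edge`` voids fall in each non-overlapping 8-h
    segment and ``shared`` in the 16-h overlap, so both windows hold
    ``edge + shared = n_window`` voids.
    """
    edge = max(1, min(round(0.45 * n_window), n_window - 1))
    return edge, n_window - edge


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate one deterministic cohort from a validated configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    srn = config.self_report_noise

    mu_a = config.daily_intake_log_mean - math.log(INTAKE_NEED_MALE_ML)
    a_ref = math.exp(mu_a)
    gamma_m = math.log(config.spot_volume_mean_morning / SPOT_CUTOFF_ML) / math.log(a_ref)
    gamma_a = math.log(config.spot_volume_mean_afternoon / SPOT_CUTOFF_ML) / math.log(a_ref)

    sex = np.where(rng.random(n) < config.female_fraction, FEMALE, MALE)
    need = np.where(sex == FEMALE, INTAKE_NEED_FEMALE_ML, INTAKE_NEED_MALE_ML)
    adequacy = np.exp(rng.normal(mu_a, config.daily_intake_log_sd, n))
    # dispersed per-marker copies of the balance factor
    disp = config.marker_dispersion_sd
    m_intake, m_freq, m_spot, m_color = (
        adequacy * np.exp(rng.normal(0.0, disp, n) * (disp > 0)) for _ in range(4)
    )
    intake = m_intake * need
    truth_usg = np.clip(
        USG_LOW_BOUNDARY
        + config.intake_usg_slope * (adequacy - 1.0)
        + rng.normal(0.0, config.usg_noise_sd, n) * (config.usg_noise_sd > 0),
        USG_MIN,
        USG_MAX,
    )

    base = pd.Timestamp(config.start_date) + pd.Timedelta(hours=8)
    part_rows, void_rows, diary_rows, assess_rows = [], [], [], []
    bm_rows, truth_rows, latent_rows = [], [], []

    for i in range(n):
        pid = f"P{i + 1:04d}"
        a = float(adequacy[i])
        usg_i = float(truth_usg[i])
        start = base + pd.Timedelta(hours=float(rng.uniform(-1.0, 1.0)))
        t_morning = start + pd.Timedelta(hours=24)
        t_afternoon = start + pd.Timedelta(hours=32)

        # --- void schedule -------------------------------------------------
        n_window = max(3, int(math.floor(config.void_rate_per_day * float(m_freq[i]) ** VOID_COUNT_EXPONENT)))
        n_edge, n_shared = _allocate_counts(n_window)
        hours_a = np.sort(rng.uniform(0.02, 8.0, n_edge))
        hours_evening = np.sort(rng.uniform(8.0, 15.0, n_shared - 1))
        hour_wake = 22.0 + float(rng.uniform(0.0, 0.5))
        hours_c_other = np.sort(rng.uniform(24.05, 31.0, n_edge - 1))
        hour_spot_pm = 32.0 - float(rng.uniform(0.05, 0.4))

        # --- volumes -------------------------------------------------------
        v24 = (
            config.urine_output_fraction
            * intake[i]
            * math.exp(rng.normal(0.0, config.urine_volume_cv) * (config.urine_volume_cv > 0))
        )
        # The morning spot is the overnight-accumulated first void: its
        # volume and colour track a drifted copy of their factor copies.
        drift = math.exp(
            rng.normal(0.0, srn.morning_distortion_sd) * (srn.morning_distortion_sd > 0)
        )
        spot_m_latent = SPOT_CUTOFF_ML * (float(m_spot[i]) * drift) ** gamma_m
        spot_a_latent = SPOT_CUTOFF_ML * float(m_spot[i]) ** gamma_a
        spot_m = spot_m_latent * math.exp(rng.normal(0.0, srn.spot_volume_cv) * (srn.spot_volume_cv > 0))
        spot_a = spot_a_latent * math.exp(rng.normal(0.0, srn.spot_volume_cv) * (srn.spot_volume_cv > 0))

        vol_shared = max(0.45 * v24, spot_m + 30.0 * (n_shared - 1))
        vol_edge = max(v24 - vol_shared, spot_a + 10.0 * max(n_edge - 1, 1))
        vols_a = vol_edge * rng.dirichlet(np.ones(n_edge))
        vols_evening = (
            (vol_shared - spot_m) * rng.dirichlet(np.ones(n_shared - 1))
            if n_shared > 1
            else np.empty(0)
        )
        vols_c_other = (
            (vol_edge - spot_a) * rng.dirichlet(np.ones(n_edge - 1))
            if n_edge > 1
            else np.empty(0)
        )

        hours = np.concatenate([hours_a, hours_evening, [hour_wake], hours_c_other, [hour_spot_pm]])
        vols = np.concatenate([vols_a, vols_evening, [spot_m], vols_c_other, [spot_a]])
        usgs = np.clip(
            usg_i + rng.normal(0.0, config.usg_noise_sd, hours.size) * (config.usg_noise_sd > 0),
            USG_MIN,
            USG_MAX,
        )
        order = np.argsort(hours)
        for h, v, u in zip(hours[order], vols[order], usgs[order]):
            void_rows.append(
                {
                    "participant_id": pid,
                    "time": start + pd.Timedelta(hours=float(h)),
                    "volume": float(max(v, 1.0)),
                    "usg": float(u),
                }
            )
        spot_usg_m = float(usgs[hours == hour_wake][0])
        spot_usg_a = float(usgs[-1])

        # --- fluid diary ---------------------------------------------------
        shares = (8.0 / 17.0, 9.0 / 17.0, 8.0 / 17.0)
        period_names = ("day1_8h", "overnight_16h", "day2_8h")
        diary = []
        for name, share in zip(period_names, shares):
            vol = intake[i] * share * math.exp(
                rng.normal(0.0, srn.intake_cv) * (srn.intake_cv > 0)
            )
            diary.append(vol)
            diary_rows.append({"participant_id": pid, "period": name, "volume_ml": float(vol)})
        reported_intake = {"morning": diary[0] + diary[1], "afternoon": diary[1] + diary[2]}

        # --- self-assessments ---------------------------------------------
        proxy = USG_LOW_BOUNDARY + config.intake_usg_slope * (float(m_color[i]) - 1.0)
        proxy_morning = USG_LOW_BOUNDARY + config.intake_usg_slope * (float(m_color[i]) * drift - 1.0)
        proxy_by_session = {
            "morning": float(np.clip(proxy_morning, USG_MIN, USG_MAX)),
            "afternoon": float(np.clip(proxy, USG_MIN, USG_MAX)),
        }
        spot_by_session = {"morning": spot_m, "afternoon": spot_a}
        time_by_session = {"morning": t_morning, "afternoon": t_afternoon}
        thirst_mu = {"morning": 60.0, "afternoon": 38.0}
        thirst_sd = {"morning": 32.0, "afternoon": 25.0}
        colors = {}
        for session in ("morning", "afternoon"):
            count_noise = rng.normal(0.0, srn.void_count_sd) * (srn.void_count_sd > 0)
            reported_count = int(max(0, round(n_window + count_noise)))
            color = color_from_usg(
                np.array([proxy_by_session[session]]), config.color_noise, rng
            )[0]
            colors[session] = int(color)
            vas = float(np.clip(rng.normal(thirst_mu[session], thirst_sd[session]), 0.0, 175.0))
            duration = max(
                2.0,
                spot_by_session[session]
                / URINE_FLOW_ML_PER_S
                * math.exp(rng.normal(0.0, srn.duration_cv) * (srn.duration_cv > 0)),
            )
            assess_rows.append(
                {
                    "participant_id": pid,
                    "session": session,
                    "assessment_time": time_by_session[session],
                    "sex": sex[i],
                    "reported_intake_24h": float(reported_intake[session]),
                    "reported_void_count_24h": reported_count,
                    "spot_volume": float(spot_by_session[session]),
                    "color_score": int(color),
                    "thirst_vas_mm": vas,
                    "void_duration_s": float(duration),
                }
            )

        # --- body mass, covariates, truth ---------------------------------
        base_kg = 81.0 * math.exp(rng.normal(0.0, 0.105))
        bm_rows.append(
            {
                "participant_id": pid,
                "day1_kg": float(base_kg * (1 + rng.normal(0, 0.002))),
                "day2_kg": float(base_kg * (1 + rng.normal(0.0001, 0.0066))),
                "day3_kg": float(base_kg * (1 + rng.normal(0, 0.002))),
            }
        )
        part_rows.append(
            {
                "participant_id": pid,
                "sex": sex[i],
                "age": int(np.clip(round(math.exp(rng.normal(math.log(27.0), 0.22))), 18, 65)),
                "bmi": float(rng.normal(26.2, 3.2)),
                "race": rng.choice(RACE_LEVELS, p=RACE_PROBS),
                "hispanic": bool(rng.random() < 0.19),
                "hire_type": rng.choice(HIRE_LEVELS, p=HIRE_PROBS),
                "supplement_use": bool(rng.random() < 0.77),
                "medication_use": bool(rng.random() < 0.13),
                "alcohol_use": bool(rng.random() < 0.65),
                "nicotine_use": bool(rng.random() < 0.39),
                "population": "wlff" if rng.random() < 0.73 else "athlete",
                "collection_start": start,
            }
        )
        for session in ("morning", "afternoon"):
            truth_rows.append(
                {"participant_id": pid, "window": session, "truth_usg": usg_i}
            )
        latent_rows.append(
            {
                "participant_id": pid,
                "adequacy": a,
                "intake_ml": float(intake[i]),
                "truth_usg": usg_i,
                "void_count": n_window,
                "spot_volume_morning": spot_m_latent,
                "spot_volume_afternoon": spot_a_latent,
                "color_latent": color_from_usg(float(np.clip(proxy, USG_MIN, USG_MAX))),
                "spot_usg_morning": spot_usg_m,
                "spot_usg_afternoon": spot_usg_a,
            }
        )

    return SyntheticCohort(
        config=config,
        participants=pd.DataFrame(part_rows),
        voids=pd.DataFrame(void_rows),
        diaries=pd.DataFrame(diary_rows),
        assessments=pd.DataFrame(assess_rows),
        bodymass=pd.DataFrame(bm_rows),
        truth=pd.DataFrame(truth_rows),
        latent=pd.DataFrame(latent_rows),
    )
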