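"""Shared physical constants and fixed calibration tables.

Everything here is versioned by the package: the urine-colour breakpoint
table in particular is a design artifact of this implementation (a 7-level
monotone step map over the physiological USG range) and is referenced by
both the synthetic generator and the documentation.
"""

from __future__ import annotations

# Physiological range of urine specific gravity; values are unitless ratios
# of urine density to water density, recorded to 0.001 by refractometry.
USG_MIN = 1.000
USG_MAX = 1.040

# Reference cut-offs for classifying a 24-h urine collection.
# "low" separates optimal fluid intake (<= 1.012) from suboptimal (>= 1.013);
# "high" is the conventional underhydration threshold (>= 1.020).
USG_CUTOFF_LOW = 1.012
USG_CUTOFF_HIGH = 1.020

# Continuous boundary between the low/high classes under the low cut-off:
# USG below this value rounds (to 3 decimals) into the <= 1.012 class.
USG_LOW_BOUNDARY = 1.0125

# Daily fluid-intake adequacy references (mL), sex-specific; these double as
# the intake item cut-offs of the 4-item model.
INTAKE_NEED_FEMALE_ML = 2697.0
INTAKE_NEED_MALE_ML = 3697.0

# 7-level urine-colour chart: upper USG edge of levels 1..6 (level 7 is the
# remainder up to USG_MAX).  Chosen so levels 1-2 span USG <= 1.012 and
# level 3 starts above it, aligning the colour item cut-off (<= 2) with the
# low USG reference cut-off.  Version 1; do not reorder.
COLOR_BREAKPOINTS = (1.006, 1.0125, 1.017, 1.022, 1.027, 1.033)

# Thirst visual-analogue scale: full line length used as the percentage
# denominator, and the inclusive "not thirsty" threshold in percent.
THIRST_VAS_FULL_MM = 175.0
THIRST_NOT_THIRSTY_MAX_PCT = 40.0

# Void-duration rule: a void lasting at least this many seconds indicates a
# larger urine volume.
LONG_VOID_MIN_S = 16.0

# Body-mass rule: a decrease of at least this percentage from the two-day
# baseline suggests underhydration.
BODY_MASS_DROP_PCT = 1.0
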