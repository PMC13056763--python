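"""Published classification counts from the development cohort of the model.

The 4-item instrument was developed and validated in a cohort of n = 85
wildland firefighters and recreational athletes.  The development study
reported, for the combined model and for each individual item, the
TP/TN/FP/FN counts of the prediction against the 24-h USG reference at
both cut-offs and at both assessment times.  Those printed counts are
reproduced here as input data so the diagnostic-accuracy arithmetic
(sensitivity, specificity, accuracy) can be recomputed and checked
against the study's printed rates without access to the raw cohort.

Each row: (session, usg_cutoff, variable, auc, sensitivity_pct,
specificity_pct, tp, tn, fp, fn) where the AUC and rate columns are the
study's printed values and the four counts are the study's printed n.
"""

from __future__ import annotations

from typing import NamedTuple


class PublishedRow(NamedTuple):
    session: str
    cutoff: str
    variable: str
    auc: float
    sensitivity_pct: float
    specificity_pct: float
    tp: int
    tn: int
    fp: int
    fn: int


PUBLISHED_ROWS: tuple[PublishedRow, ...] = (
    # morning assessment, low cut-off (<= 1.012)
    PublishedRow("morning", "low", "model", 0.72, 66.7, 62.5, 32, 20, 12, 16),
    PublishedRow("morning", "low", "intake", 0.64, 66.7, 53.1, 32, 17, 15, 16),
    PublishedRow("morning", "low", "frequency", 0.65, 68.8, 59.4, 33, 19, 13, 15),
    PublishedRow("morning", "low", "volume", 0.53, 85.4, 21.9, 41, 7, 25, 7),
    PublishedRow("morning", "low", "color", 0.58, 60.4, 53.1, 29, 17, 15, 19),
    # afternoon assessment, low cut-off
    PublishedRow("afternoon", "low", "model", 0.85, 73.7, 75.9, 28, 22, 7, 10),
    PublishedRow("afternoon", "low", "intake", 0.71, 84.2, 58.6, 32, 17, 12, 6),
    PublishedRow("afternoon", "low", "frequency", 0.63, 63.2, 62.1, 24, 18, 11, 14),
    PublishedRow("afternoon", "low", "volume", 0.67, 68.4, 65.5, 26, 19, 10, 12),
    PublishedRow("afternoon", "low", "color", 0.68, 86.8, 51.7, 33, 15, 14, 5),
    # morning assessment, high cut-off (>= 1.020)
    PublishedRow("morning", "high", "model", 0.81, 59.7, 87.5, 43, 7, 1, 29),
    PublishedRow("morning", "high", "intake", 0.66, 59.7, 50.0, 43, 4, 4, 29),
    PublishedRow("morning", "high", "frequency", 0.69, 61.1, 75.0, 44, 6, 2, 28),
    PublishedRow("morning", "high", "volume", 0.59, 84.7, 37.5, 61, 3, 5, 11),
    PublishedRow("morning", "high", "color", 0.68, 58.3, 75.0, 42, 6, 2, 30),
    # afternoon assessment, high cut-off
    PublishedRow("afternoon", "high", "model", 0.86, 60.3, 90.0, 35, 9, 1, 23),
    PublishedRow("afternoon", "high", "intake", 0.65, 70.7, 60.0, 41, 6, 4, 17),
    PublishedRow("afternoon", "high", "frequency", 0.68, 58.6, 80.0, 34, 8, 2, 24),
    PublishedRow("afternoon", "high", "volume", 0.67, 60.3, 80.0, 35, 8, 2, 23),
    PublishedRow("afternoon", "high", "color", 0.72, 77.6, 70.0, 45, 7, 3, 13),
)

# The four headline (combined 4-item model) rows, in a fixed order.
MODEL_ROWS: tuple[PublishedRow, ...] = tuple(
    r for r in PUBLISHED_ROWS if r.variable == "model"
)
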