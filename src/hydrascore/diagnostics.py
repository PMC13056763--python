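"""Diagnostic-accuracy statistics for the hydration self-assessment model.

Covers the whole evaluation chain: 2x2 contingency tables with
sensitivity/specificity/accuracy, the rank (Mann-Whitney) AUC with the
conventional interpretation bands, rank-biserial and Cramer's V effect
sizes, Spearman correlation, and the paired/unpaired hypothesis tests.

Rates are reported as percentages to 1 decimal, rounding halves away from
zero to match clinical reporting convention; raw fractions are retained.
A rate whose denominator is zero is reported as an explicit ``None``
sentinel rather than an exception, so per-item tables with empty cells
remain printable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import HIGH, ITEM_NAMES, LOW

AUC_BANDS = (("excellent", 0.90), ("good", 0.80), ("fair", 0.70))


class DiagnosticsError(ValueError):
    """Raised for inputs on which a statistic is not defined."""


def round1(x: float) -> float:
    """Round to 1 decimal, halves away from zero (21.875 -> 21.9)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """TP/FP/FN/TN counts of a binary classifier against a reference."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DiagnosticsError("contingency counts must be non-negative")
        if self.total == 0:
            raise DiagnosticsError("contingency table must hold at least one pair")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def contingency(
    predicted: Sequence, reference: Sequence, positive=HIGH
) -> ContingencyTable:
    """Cross-tabulate paired predicted/reference labels.

    ``positive`` declares which label counts as the positive class (for the
    low USG cut-off the positive class is the high-concentration /
    suboptimal-intake group).
    """
    pred = np.asarray(predicted)
    ref = np.asarray(reference)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise DiagnosticsError("predicted and reference must be equal-length vectors")
    alphabet = set(pred.tolist()) | set(ref.tolist())
    if positive not in alphabet:
        raise DiagnosticsError(f"positive class {positive!r} absent from labels")
    if len(alphabet) > 2:
        raise DiagnosticsError(f"labels must be binary, got {sorted(map(str, alphabet))}")
    p = pred == positive
    r = ref == positive
    return ContingencyTable(
        tp=int(np.sum(p & r)),
        fp=int(np.sum(p & ~r)),
        fn=int(np.sum(~p & r)),
        tn=int(np.sum(~p & ~r)),
    )


def sens_spec_acc(ct: ContingencyTable) -> dict:
    """Sensitivity, specificity and accuracy as percentages (1 decimal).

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    accuracy = (TP+TN)/total; an undefined rate (zero denominator) is
    returned as None.  Raw fractions come back under ``*_raw`` keys.
    """

    def rate(num: int, den: int):
        return None if den == 0 else num / den

    sens = rate(ct.tp, ct.tp + ct.fn)
    spec = rate(ct.tn, ct.tn + ct.fp)
    acc = rate(ct.tp + ct.tn, ct.total)
    as_pct = lambda x: None if x is None else round1(100.0 * x)
    return {
        "sensitivity": as_pct(sens),
        "specificity": as_pct(spec),
        "accuracy": as_pct(acc),
        "sensitivity_raw": sens,
        "specificity_raw": spec,
        "accuracy_raw": acc,
    }


def auc_band(auc: float) -> str:
    for name, lo in AUC_BANDS:
        if auc >= lo:
            return name
    return "below"


def auc_rank(scores: Sequence[float], labels: Sequence, positive=HIGH) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation.

    Mid-ranks handle ties, so the value equals both the trapezoidal area
    under the empirical ROC curve and the probability that a random
    positive outranks a random negative with ties counted half.  Higher
    scores must indicate the positive class.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if s.shape != y.shape or s.ndim != 1:
        raise DiagnosticsError("scores and labels must be equal-length vectors")
    if n_pos == 0 or n_neg == 0:
        raise DiagnosticsError("AUC requires both classes present")
    ranks = stats.rankdata(s)
    rank_sum_pos = float(ranks[y].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


@dataclass(frozen=True)
class DiagnosticSummary:
    """AUC with its interpretation band plus the binary-prediction rates."""

    auc: float
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    table: ContingencyTable
    band: str = field(default="")

    def __post_init__(self) -> None:
        object.__setattr__(self, "band", auc_band(self.auc))


@dataclass(frozen=True)
class EffectSize:
    """A named effect size with its magnitude band and intermediates."""

    kind: str
    value: float | None
    magnitude_band: str
    intermediates: dict = field(default_factory=dict)


def rank_biserial(paired_diffs: Sequence[float]) -> EffectSize:
    """Rank-biserial correlation for paired differences.

    r_rb = (W+ - W-)/(W+ + W-), where W+ and W- are the Wilcoxon
    signed-rank sums over the nonzero differences (mid-ranks on tied
    magnitudes).  Banded small >= 0.1, medium >= 0.3, large >= 0.5 on the
    magnitude.  All-zero differences yield the undefined sentinel.
    """
    d = np.asarray(paired_diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return EffectSize("rank_biserial", None, "undefined")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    value = (w_pos - w_neg) / (w_pos + w_neg)
    mag = abs(value)
    band = "large" if mag >= 0.5 else "medium" if mag >= 0.3 else "small" if mag >= 0.1 else "negligible"
    return EffectSize("rank_biserial", value, band, {"w_pos": w_pos, "w_neg": w_neg})


def cramers_v(table) -> EffectSize:
    """Cramer's V = sqrt(chi2 / [n * (k - 1)]) for an r x c count table.

    chi2 is Pearson's statistic without continuity correction; k is the
    smaller table dimension.  Banded small < 0.1, medium 0.1-0.3,
    large > 0.3.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise DiagnosticsError("Cramer's V needs an r x c table with r, c >= 2")
    if t.sum() <= 0:
        raise DiagnosticsError("table grand total must be positive")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DiagnosticsError("table has an all-zero row or column margin")
    chi2 = float(stats.chi2_contingency(t, correction=False).statistic)
    n = float(t.sum())
    k = min(t.shape)
    value = float(np.sqrt(chi2 / (n * (k - 1))))
    band = "large" if value > 0.3 else "medium" if value >= 0.1 else "small"
    return EffectSize("cramers_v", value, band, {"chi2": chi2, "n": n, "k": k})


def spearman(x: Sequence[float], y: Sequence[float]) -> EffectSize:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise DiagnosticsError("spearman needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return EffectSize("spearman", None, "undefined")
    value = float(stats.spearmanr(x, y).statistic)
    mag = abs(value)
    band = "large" if mag >= 0.80 else "medium" if mag > 0.20 else "small"
    return EffectSize("spearman", value, band)


def paired_and_unpaired_tests(x, y=None, mode: str = "wilcoxon_signed_rank",
                              continuity_correction: bool = False) -> dict:
    """Two-sided hypothesis tests used in the evaluation chain.

    wilcoxon_signed_rank / mann_whitney use the normal approximation with
    tie correction; chi_square is Pearson's test on a count table (Yates
    correction optional); fisher_exact enumerates 2x2 tables exactly.
    Identical paired samples (no nonzero differences) yield the undefined
    sentinel {statistic: None, p_value: None}.
    """
    if mode == "wilcoxon_signed_rank":
        x = np.asarray(x, dtype=float)
        y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
        d = x - y
        if np.all(d == 0):
            return {"statistic": None, "p_value": None, "undefined": True}
        res = stats.wilcoxon(d, correction=continuity_correction, method="approx")
        return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}
    if mode == "mann_whitney":
        res = stats.mannwhitneyu(
            np.asarray(x, float), np.asarray(y, float),
            alternative="two-sided", method="asymptotic",
            use_continuity=continuity_correction,
        )
        return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}
    if mode == "chi_square":
        res = stats.chi2_contingency(np.asarray(x, float), correction=continuity_correction)
        return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}
    if mode == "fisher_exact":
        t = np.asarray(x, dtype=float)
        if t.shape != (2, 2):
            raise DiagnosticsError("Fisher's exact test needs a 2x2 table")
        res = stats.fisher_exact(t, alternative="two-sided")
        return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}
    raise DiagnosticsError(f"unknown test mode {mode!r}")


def evaluate_model(
    classified: pd.DataFrame,
    score_col: str = "total_score",
    positive=HIGH,
) -> dict:
    """Per-model and per-item diagnostic summaries of a classified cohort.

    The model row computes AUC on the graded 0-4 score and the rates from
    the dichotomised prediction (total >= 2); each item row treats the
    single 0/1 item as both its own graded score and its prediction.
    Expects the output of :func:`hydrascore.scoring.classify_cohort`.
    """
    ref = classified["reference_label"]
    # Higher scores always indicate the high-concentration class; orient
    # them toward whichever class is declared positive.
    sign = 1.0 if positive == HIGH else -1.0

    def summarize(scores, predicted) -> DiagnosticSummary:
        ct = contingency(predicted, ref, positive=positive)
        rates = sens_spec_acc(ct)
        return DiagnosticSummary(
            auc=auc_rank(sign * np.asarray(scores, dtype=float), ref, positive=positive),
            sensitivity=rates["sensitivity"],
            specificity=rates["specificity"],
            accuracy=rates["accuracy"],
            table=ct,
        )

    model = summarize(classified[score_col], classified["predicted_class"])
    items = {
        name: summarize(
            classified[name], np.where(classified[name] == 1, HIGH, LOW)
        )
        for name in ITEM_NAMES
    }
    return {"model": model, "items": items, "n": int(len(classified))}
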