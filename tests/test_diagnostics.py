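"""Accuracy statistics against independent oracles and published counts."""

import itertools

import numpy as np
import pytest

from hydrascore import (
    ContingencyTable,
    auc_rank,
    contingency,
    cramers_v,
    evaluate_model,
    paired_and_unpaired_tests,
    rank_biserial,
    sens_spec_acc,
    spearman,
)
from hydrascore.diagnostics import DiagnosticsError, auc_band, round1
from hydrascore.scoring import HIGH, LOW
from hydrascore.validation_counts import PUBLISHED_ROWS


def auc_by_pair_counting(scores, labels, positive=1):
    """Oracle: exhaustive concordant/tied pair enumeration."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == positive]
    neg = scores[np.asarray(labels) != positive]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (len(pos) * len(neg))


class TestContingency:
    def test_perfect_prediction_has_no_errors(self):
        labels = [HIGH, HIGH, LOW]
        ct = contingency(labels, labels, positive=HIGH)
        assert (ct.fp, ct.fn) == (0, 0) and (ct.tp, ct.tn) == (2, 1)

    def test_published_morning_low_counts_from_labels(self):
        """Reconstructing the published morning/low table from label vectors."""
        pred = [HIGH] * 44 + [LOW] * 36
        ref = [HIGH] * 32 + [LOW] * 12 + [HIGH] * 16 + [LOW] * 20
        ct = contingency(pred, ref, positive=HIGH)
        assert (ct.tp, ct.tn, ct.fp, ct.fn) == (32, 20, 12, 16)

    def test_counts_are_conserved(self):
        rng = np.random.default_rng(0)
        pred = rng.choice([HIGH, LOW], 100)
        ref = rng.choice([HIGH, LOW], 100)
        assert contingency(pred, ref).total == 100

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(DiagnosticsError):
            contingency([HIGH], [HIGH, LOW])

    def test_negative_counts_rejected(self):
        with pytest.raises(DiagnosticsError):
            ContingencyTable(tp=-1, fp=0, fn=0, tn=1)


class TestRates:
    def test_headline_sensitivity_and_specificity(self):
        out = sens_spec_acc(ContingencyTable(tp=32, tn=20, fp=12, fn=16))
        assert out["sensitivity"] == 66.7 and out["specificity"] == 62.5
        out = sens_spec_acc(ContingencyTable(tp=28, tn=22, fp=7, fn=10))
        assert out["sensitivity"] == 73.7 and out["specificity"] == 75.9

    def test_all_published_rows_close_to_printed_precision(self):
        """Every published TP/TN/FP/FN row reproduces its printed rates."""
        for row in PUBLISHED_ROWS:
            out = sens_spec_acc(
                ContingencyTable(tp=row.tp, tn=row.tn, fp=row.fp, fn=row.fn)
            )
            assert out["sensitivity"] == row.sensitivity_pct, row
            assert out["specificity"] == row.specificity_pct, row

    def test_perfect_classifier_rates(self):
        out = sens_spec_acc(ContingencyTable(tp=50, tn=50, fp=0, fn=0))
        assert (out["sensitivity"], out["specificity"], out["accuracy"]) == (
            100.0, 100.0, 100.0)

    def test_zero_denominator_yields_undefined_sentinel(self):
        out = sens_spec_acc(ContingencyTable(tp=0, tn=5, fp=5, fn=0))
        assert out["sensitivity"] is None and out["specificity"] == 50.0

    def test_half_away_from_zero_rounding(self):
        assert round1(21.875) == 21.9
        assert round1(68.75) == 68.8


class TestAuc:
    def test_perfect_separation_gives_one(self):
        assert auc_rank([1, 2, 3, 10, 11], [0, 0, 0, 1, 1], positive=1) == 1.0

    def test_pure_ties_give_half(self):
        assert auc_rank([5, 5, 5, 5], [0, 1, 0, 1], positive=1) == 0.5

    def test_small_example_matches_pair_counting(self):
        scores, labels = [0, 1, 2, 3, 4], [0, 0, 1, 0, 1]
        expected = auc_by_pair_counting(scores, labels)  # 5/6
        assert expected == pytest.approx(5 / 6)
        assert auc_rank(scores, labels, positive=1) == pytest.approx(expected, abs=1e-15)

    def test_single_class_is_an_error(self):
        with pytest.raises(DiagnosticsError):
            auc_rank([1, 2], [1, 1], positive=1)

    def test_random_instances_match_both_oracles(self):
        """Rank AUC == pair counting == trapezoidal ROC on tied data."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(10, 80))
            scores = rng.integers(0, 5, n).astype(float)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            mine = auc_rank(scores, labels, positive=1)
            assert mine == pytest.approx(auc_by_pair_counting(scores, labels), abs=1e-12)
            assert mine == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_interpretation_bands(self):
        assert auc_band(0.95) == "excellent"
        assert auc_band(0.80) == "good"
        assert auc_band(0.70) == "fair"
        assert auc_band(0.69) == "below"


class TestEffectSizes:
    def test_rank_biserial_extremes(self):
        assert rank_biserial([1, 2, 5]).value == 1.0
        assert rank_biserial([3, -3, 1, -1]).value == 0.0

    def test_rank_biserial_hand_ranks(self):
        # |d| = (3,1,2,2,5) -> ranks (4,1,2.5,2.5,5); W+ = 11.5, W- = 3.5
        es = rank_biserial([3, -1, 2, -2, 5])
        assert es.value == pytest.approx(8 / 15, abs=1e-15)
        assert es.intermediates == {"w_pos": 11.5, "w_neg": 3.5}
        assert es.magnitude_band == "large"

    def test_rank_biserial_all_zero_is_undefined(self):
        assert rank_biserial([0, 0]).value is None

    def test_cramers_v_extremes(self):
        assert cramers_v([[10, 0], [0, 10]]).value == pytest.approx(1.0)
        assert cramers_v(np.outer([30, 70], [0.4, 0.6])).value == pytest.approx(0.0, abs=1e-12)

    def test_cramers_v_hand_chi2(self):
        # chi2 of [[20,10],[5,25]] = 15.428...; V = sqrt(chi2/60)
        es = cramers_v([[20, 10], [5, 25]])
        chi2 = 2 * (7.5**2 / 12.5 + 7.5**2 / 17.5)
        assert es.value == pytest.approx(np.sqrt(chi2 / 60.0), abs=1e-12)
        assert es.magnitude_band == "large"

    def test_cramers_v_permutation_invariance(self):
        t = np.array([[8, 3, 9], [2, 7, 1]])
        base = cramers_v(t).value
        for perm in itertools.permutations(range(3)):
            assert cramers_v(t[:, perm]).value == pytest.approx(base, abs=1e-12)
        assert cramers_v(t[::-1]).value == pytest.approx(base, abs=1e-12)

    def test_cramers_v_degenerate_margins_rejected(self):
        with pytest.raises(DiagnosticsError):
            cramers_v([[1, 0], [1, 0]])

    def test_spearman_monotone_extremes_and_oracle(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, x).value == pytest.approx(1.0)
        assert spearman(x, [10, 8, 6, 4, 2]).value == pytest.approx(-1.0)
        rng = np.random.default_rng(3)
        a, b = rng.integers(0, 10, 20), rng.integers(0, 10, 20)
        from scipy.stats import rankdata

        oracle = np.corrcoef(rankdata(a), rankdata(b))[0, 1]
        assert spearman(a, b).value == pytest.approx(oracle, abs=1e-12)

    def test_spearman_constant_vector_undefined(self):
        assert spearman([1, 1, 1], [1, 2, 3]).value is None


class TestHypothesisTests:
    def test_identical_paired_samples_are_undefined(self):
        out = paired_and_unpaired_tests([1, 2, 3], [1, 2, 3], mode="wilcoxon_signed_rank")
        assert out.get("undefined") and out["p_value"] is None

    def test_fisher_exact_diagonal_table(self):
        from math import comb

        out = paired_and_unpaired_tests([[5, 0], [0, 5]], mode="fisher_exact")
        assert out["p_value"] == pytest.approx(2 / comb(10, 5), abs=1e-12)

    def test_mann_whitney_full_separation_statistic(self):
        out = paired_and_unpaired_tests([10, 11, 12], [1, 2, 3, 4], mode="mann_whitney")
        assert out["statistic"] == 12.0  # n1 * n2

    def test_unknown_mode_rejected(self):
        with pytest.raises(DiagnosticsError):
            paired_and_unpaired_tests([1], mode="bogus")


class TestEvaluateModel:
    def test_zero_noise_model_is_perfect_and_items_weaker_or_equal(
        self, zero_noise_classified
    ):
        ev = evaluate_model(zero_noise_classified)
        assert ev["model"].auc == 1.0
        for item in ev["items"].values():
            assert item.auc <= ev["model"].auc + 1e-12

    def test_summary_band_is_consistent(self, default_classified):
        ev = evaluate_model(default_classified)
        assert ev["model"].band == auc_band(ev["model"].auc)
        ct = ev["model"].table
        assert ct.total == ev["n"]
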