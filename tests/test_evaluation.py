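import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylfusion.evaluation import (
    ConfusionCounts,
    MetricReport,
    UndefinedMetricError,
    accuracy,
    confusion,
    f1,
    mcc,
    report_from_scores,
    roc_auc,
    sensitivity,
    specificity,
)


def brute_force_metrics(c: ConfusionCounts) -> dict:
    """Independent per-sample oracle: expand counts into outcome vectors
    and compute every metric by its definition, without the formulas."""
    y = [1] * c.tp + [0] * c.tn + [0] * c.fp + [1] * c.fn
    p = [1] * c.tp + [0] * c.tn + [1] * c.fp + [0] * c.fn
    n = len(y)
    correct = sum(yi == pi for yi, pi in zip(y, p))
    pos_truth = [i for i in range(n) if y[i] == 1]
    neg_truth = [i for i in range(n) if y[i] == 0]
    out = {"accuracy": correct / n}
    if pos_truth:
        out["sensitivity"] = sum(p[i] == 1 for i in pos_truth) / len(pos_truth)
    if neg_truth:
        out["specificity"] = sum(p[i] == 0 for i in neg_truth) / len(neg_truth)
    called_pos = [i for i in range(n) if p[i] == 1]
    union = set(pos_truth) | set(called_pos)
    inter = set(pos_truth) & set(called_pos)
    if union:
        out["f1_paper_eq4"] = len(inter) / len(union)  # Jaccard of positive calls
        prec = len(inter) / len(called_pos) if called_pos else 0.0
        rec = len(inter) / len(pos_truth) if pos_truth else 0.0
        out["f1_standard"] = (
            0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
        )
    # MCC as the Pearson correlation of the two binary vectors
    ybar, pbar = sum(y) / n, sum(p) / n
    num = sum((yi - ybar) * (pi - pbar) for yi, pi in zip(y, p))
    den = math.sqrt(
        sum((yi - ybar) ** 2 for yi in y) * sum((pi - pbar) ** 2 for pi in p)
    )
    out["mcc"] = 0.0 if den == 0 else num / den
    return out


def pair_counting_auc(labels, scores):
    """Exhaustive concordant-pair AUC (ties count one half)."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_definition_and_total(self):
        c = confusion([1, 1, 0, 0], [1, 0, 1, 0])
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)
        assert c.total == 4

    def test_perfect_predictions_have_no_errors(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert c.fp == c.fn == 0

    def test_swapping_arguments_transposes_fp_and_fn(self, rng):
        y = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        a, b = confusion(y, p), confusion(p, y)
        assert (a.fp, a.fn) == (b.fn, b.fp)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])
        with pytest.raises(ValueError):
            confusion([1, 2], [1, 0])


class TestFormulas:
    @pytest.mark.parametrize(
        "metric, counts, expected",
        [
            (accuracy, (50, 50, 0, 0), 1.0),
            (accuracy, (3, 4, 1, 2), 0.7),
            (accuracy, (25, 25, 25, 25), 0.5),
            (sensitivity, (10, 0, 0, 0), 1.0),
            (sensitivity, (0, 0, 0, 10), 0.0),
            (sensitivity, (3, 0, 0, 2), 0.6),
            (specificity, (0, 10, 0, 0), 1.0),
            (specificity, (0, 4, 1, 0), 0.8),
            (specificity, (5, 0, 5, 0), 0.0),
            (mcc, (25, 25, 25, 25), 0.0),
            (mcc, (50, 50, 0, 0), 1.0),
        ],
    )
    def test_direct_substitution(self, metric, counts, expected):
        tp, tn, fp, fn = counts
        assert metric(ConfusionCounts(tp, tn, fp, fn)) == pytest.approx(expected)

    def test_mcc_hand_arithmetic_example(self):
        # (3·4 − 1·2) / √(4·5·5·6) = 10/√600
        c = ConfusionCounts(tp=3, tn=4, fp=1, fn=2)
        assert mcc(c) == pytest.approx(10 / math.sqrt(600))
        assert mcc(c) == pytest.approx(0.4082, abs=1e-4)

    @pytest.mark.parametrize(
        "variant, expected", [("paper_eq4", 1 / 3), ("standard", 0.5)]
    )
    def test_f1_variants(self, variant, expected):
        assert f1(ConfusionCounts(1, 0, 1, 1), variant) == pytest.approx(expected)

    def test_f1_perfect_case_is_1_under_both_variants(self):
        c = ConfusionCounts(tp=5, tn=5, fp=0, fn=0)
        assert f1(c, "standard") == f1(c, "paper_eq4") == 1.0

    def test_undefined_metrics_raise_instead_of_returning_zero(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity(ConfusionCounts(0, 5, 5, 0))
        with pytest.raises(UndefinedMetricError):
            specificity(ConfusionCounts(5, 0, 0, 5))
        with pytest.raises(UndefinedMetricError):
            f1(ConfusionCounts(0, 5, 0, 0))

    def test_mcc_zero_denominator_convention(self):
        # an all-positive predictor on an all-positive truth: TN+FP = TN+FN = 0
        assert mcc(ConfusionCounts(5, 0, 0, 0)) == 0.0

    def test_mcc_invariant_under_class_swap(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(0, 100, 4)
            assert mcc(ConfusionCounts(tp, tn, fp, fn)) == pytest.approx(
                mcc(ConfusionCounts(tn, tp, fn, fp)), abs=1e-12
            )


class TestOracleEquivalence:
    def test_200_random_confusion_tables_match_per_sample_oracle(self, rng):
        checked = 0
        while checked < 200:
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 101, 4))
            if tp + tn + fp + fn == 0:
                continue
            c = ConfusionCounts(tp, tn, fp, fn)
            oracle = brute_force_metrics(c)
            assert accuracy(c) == pytest.approx(oracle["accuracy"], abs=1e-12)
            if "sensitivity" in oracle:
                assert sensitivity(c) == pytest.approx(oracle["sensitivity"], abs=1e-12)
            if "specificity" in oracle:
                assert specificity(c) == pytest.approx(oracle["specificity"], abs=1e-12)
            if "f1_standard" in oracle:
                assert f1(c, "standard") == pytest.approx(oracle["f1_standard"], abs=1e-12)
                assert f1(c, "paper_eq4") == pytest.approx(oracle["f1_paper_eq4"], abs=1e-12)
            assert mcc(c) == pytest.approx(oracle["mcc"], abs=1e-12)
            checked += 1


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([1, 0], [0.9, 0.1]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([1, 0, 1, 0], [0.5] * 4) == 0.5

    def test_four_point_example(self):
        # 3 of 4 positive/negative pairs concordant
        assert roc_auc([1, 1, 0, 0], [0.8, 0.4, 0.6, 0.2]) == 0.75

    def test_single_class_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([1, 1], [0.2, 0.8])

    @given(st.integers(0, 2**32 - 1), st.integers(4, 50), st.booleans())
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_pair_counting(self, seed, n, with_ties):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = rng.random(n)
        if with_ties:
            scores = np.round(scores, 1)  # force score ties
        assert roc_auc(labels, scores) == pytest.approx(
            pair_counting_auc(labels, scores), abs=1e-12
        )

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        labels = rng.integers(0, 2, 500)
        labels[0], labels[1] = 0, 1
        scores = np.round(rng.random(500), 2)
        assert roc_auc(labels, scores) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_class_relabelling_complements_auc(self, rng):
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        scores = rng.random(100)
        a = roc_auc(labels, scores)
        assert roc_auc(1 - labels, -scores) == pytest.approx(a, abs=1e-12)
        assert roc_auc(1 - labels, scores) == pytest.approx(1 - a, abs=1e-12)


class TestReports:
    def test_perfect_scores_give_all_ones(self):
        r = report_from_scores([1, 0, 1, 0], [0.9, 0.1, 0.8, 0.2])
        assert (r.accuracy, r.f1, r.sensitivity, r.specificity, r.mcc, r.auc) == (
            1.0, 1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_all_positive_predictor_on_balanced_set(self):
        r = report_from_scores([1, 0, 1, 0], [0.9, 0.9, 0.8, 0.8])
        assert r.accuracy == 0.5
        assert r.sensitivity == 1.0
        assert r.specificity == 0.0

    def test_relabelling_swaps_sensitivity_and_specificity(self, rng):
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        scores = rng.random(200)
        a = report_from_scores(labels, scores)
        b = report_from_scores(1 - labels, 1 - scores)
        assert b.sensitivity == pytest.approx(a.specificity)
        assert b.specificity == pytest.approx(a.sensitivity)

    def test_single_class_set_reports_none_not_zero(self):
        r = report_from_scores([1, 1, 1], [0.9, 0.2, 0.8])
        assert r.specificity is None and r.auc is None
        assert r.sensitivity == pytest.approx(2 / 3)

    def test_variant_is_stamped_and_round_trips(self):
        r = report_from_scores([1, 0], [0.9, 0.1], f1_variant="paper_eq4")
        assert r.f1_variant_used == "paper_eq4"
        assert MetricReport.from_dict(r.to_dict()) == r
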