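"""Metric implementations against brute-force oracles; fold aggregation."""

import numpy as np
import pytest

from afedge.evaluation import (
    ConfusionMatrix,
    MetricsReport,
    aggregate_confusions,
    compute_confusion,
    compute_metrics,
    summarize_folds,
)

# ---------------------------------------------------------------------------
# Brute-force oracles, written straight from the definitions
# ---------------------------------------------------------------------------


def brute_confusion(t, p):
    tp = sum(1 for a, b in zip(t, p) if a == 1 and b == 1)
    fp = sum(1 for a, b in zip(t, p) if a == 0 and b == 1)
    tn = sum(1 for a, b in zip(t, p) if a == 0 and b == 0)
    fn = sum(1 for a, b in zip(t, p) if a == 1 and b == 0)
    return tp, fp, tn, fn


def brute_macro_prf(t, p):
    precisions, recalls, f1s = [], [], []
    for cls in (0, 1):
        tp = sum(1 for a, b in zip(t, p) if a == cls and b == cls)
        pred = sum(1 for b in p if b == cls)
        true = sum(1 for a in t if a == cls)
        prec = tp / pred if pred else 0.0
        rec = tp / true if true else 0.0
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return np.mean(precisions), np.mean(recalls), np.mean(f1s)


def brute_auc(t, scores):
    """Pairwise probability that an AF window outscores an SR window (midrank ties)."""
    pos = np.asarray([s for a, s in zip(t, scores) if a == 1])
    neg = np.asarray([s for a, s in zip(t, scores) if a == 0])
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


class TestComputeConfusion:
    def test_direct_count(self):
        cm = compute_confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        cm = compute_confusion([1, 0, 1], [1, 0, 1])
        assert cm.fp == 0 and cm.fn == 0

    def test_degenerate_all_negative_predictor(self):
        t = [0, 1] * 10
        cm = compute_confusion(t, [0] * 20)
        assert cm.tp == 0 and cm.fn == 10

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            compute_confusion([0, 1], [0])


class TestComputeMetrics:
    def test_hand_computed_macro_averages(self):
        cm = ConfusionMatrix(tp=50, fp=10, tn=40, fn=0)
        rep = compute_metrics(cm)
        assert rep.accuracy == pytest.approx(0.9)
        assert rep.precision == pytest.approx((50 / 60 + 1.0) / 2, abs=1e-9)
        assert rep.recall == pytest.approx((1.0 + 40 / 50) / 2, abs=1e-9)

    def test_perfect_separation_gives_auc_one(self):
        t = np.array([0] * 5 + [1] * 5)
        s = np.array([0.1] * 5 + [0.9] * 5)
        rep = compute_metrics(compute_confusion(t, (s > 0.5).astype(int)), s, t)
        assert rep.auc_roc == pytest.approx(1.0)

    def test_label_independent_scores_give_chance_auc(self):
        rng = np.random.default_rng(0)
        t = rng.integers(0, 2, 4000)
        s = rng.random(4000)
        rep = compute_metrics(compute_confusion(t, (s > 0.5).astype(int)), s, t)
        assert rep.auc_roc == pytest.approx(0.5, abs=0.05)

    def test_single_class_reports_missing_auc(self):
        t = np.ones(6, dtype=int)
        s = np.linspace(0, 1, 6)
        rep = compute_metrics(compute_confusion(t, t), s, t)
        assert rep.auc_roc is None

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_matches_brute_force_on_random_prediction_sets(self):
        """1,000 random label/score sets: exact counts, 1e-9 on every ratio."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(10, 60)
            t = rng.integers(0, 2, n)
            if len(np.unique(t)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # rounding forces score ties
            p = (scores > 0.5).astype(int)
            cm = compute_confusion(t, p)
            assert (cm.tp, cm.fp, cm.tn, cm.fn) == brute_confusion(t, p)
            rep = compute_metrics(cm, scores, t)
            bp, br, bf = brute_macro_prf(t, p)
            assert rep.accuracy == pytest.approx(np.mean(t == p), abs=1e-9)
            assert rep.precision == pytest.approx(bp, abs=1e-9)
            assert rep.recall == pytest.approx(br, abs=1e-9)
            assert rep.f1 == pytest.approx(bf, abs=1e-9)
            assert rep.auc_roc == pytest.approx(brute_auc(t, scores), abs=1e-9)

    def test_balanced_symmetric_predictions_align_all_metrics(self):
        """On balanced truth with symmetric errors, macro metrics equal accuracy."""
        rng = np.random.default_rng(7)
        t = np.repeat([0, 1], 500)
        flip = rng.random(1000) < 0.05  # same error rate in both classes
        p = np.where(flip, 1 - t, t)
        scores = np.where(p == 1, 0.9, 0.1)
        rep = compute_metrics(compute_confusion(t, p), scores, t)
        assert abs(rep.precision - rep.accuracy) < 0.01
        assert abs(rep.recall - rep.accuracy) < 0.01
        assert abs(rep.f1 - rep.accuracy) < 0.01


class TestAggregateConfusions:
    def test_linearity(self):
        cm = ConfusionMatrix(1, 2, 3, 4)
        total = aggregate_confusions([cm] * 5)
        assert (total.tp, total.fp, total.tn, total.fn) == (5, 10, 15, 20)

    def test_single_matrix_identity(self):
        cm = ConfusionMatrix(3, 1, 4, 1)
        assert aggregate_confusions([cm]) == cm

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            aggregate_confusions([])

    def test_commutes_with_pooled_counting(self):
        """Fold-summed matrices equal one matrix over the pooled predictions."""
        rng = np.random.default_rng(3)
        t_all, p_all, cms = [], [], []
        for _ in range(5):
            n = rng.integers(30, 80)
            t = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            cms.append(compute_confusion(t, p))
            t_all.append(t)
            p_all.append(p)
        pooled = compute_confusion(np.concatenate(t_all), np.concatenate(p_all))
        assert aggregate_confusions(cms) == pooled

    def test_row_normalized_rates_match_pooled_rates(self):
        rng = np.random.default_rng(8)
        cms = []
        t_all, p_all = [], []
        for _ in range(5):
            t = rng.integers(0, 2, 100)
            p = np.where(rng.random(100) < 0.9, t, 1 - t)
            cms.append(compute_confusion(t, p))
            t_all.append(t)
            p_all.append(p)
        rates = aggregate_confusions(cms).row_normalized()
        t_cat, p_cat = np.concatenate(t_all), np.concatenate(p_all)
        tpr = np.mean(p_cat[t_cat == 1] == 1)
        tnr = np.mean(p_cat[t_cat == 0] == 0)
        assert rates[1, 1] == pytest.approx(tpr, abs=1e-12)
        assert rates[0, 0] == pytest.approx(tnr, abs=1e-12)


class TestSummarizeFolds:
    def _report(self, acc):
        return MetricsReport(acc, acc, acc, acc, acc, 0.1)

    def test_identical_reports_have_zero_std(self):
        s = summarize_folds([self._report(0.97)] * 5)
        assert s.std["accuracy"] == 0.0
        assert s.mean["accuracy"] == pytest.approx(0.97)

    def test_two_point_closed_form(self):
        s = summarize_folds([self._report(0.9), self._report(1.0)])
        assert s.mean["accuracy"] == pytest.approx(0.95)
        assert s.std["accuracy"] == pytest.approx(np.sqrt(0.005), abs=1e-9)

    def test_mean_bounded_by_extremes(self):
        accs = [0.91, 0.95, 0.99, 0.97, 0.93]
        s = summarize_folds([self._report(a) for a in accs])
        assert min(accs) <= s.mean["accuracy"] <= max(accs)

    def test_fewer_than_two_reports_error(self):
        with pytest.raises(ValueError):
            summarize_folds([self._report(0.9)])

    def test_missing_auc_skipped_not_crashed(self):
        r1 = MetricsReport(0.9, 0.9, 0.9, 0.9, None, 0.1)
        r2 = MetricsReport(1.0, 1.0, 1.0, 1.0, None, 0.1)
        s = summarize_folds([r1, r2])
        assert "auc_roc" not in s.mean and "accuracy" in s.mean
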