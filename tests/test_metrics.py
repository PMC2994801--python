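"""Threshold metrics, ROC/AUC, threshold sweeps, AUC-difference test."""

import math

import numpy as np
import pytest
from scipy.stats import rankdata

from betaturn.metrics import (
    ConfusionCounts,
    auc_difference_test,
    confusion,
    mcc,
    metric_set,
    ppv,
    q_total,
    roc_auc,
    roc_curve,
    sensitivity,
    specificity,
    threshold_sweep,
)


def naive_confusion(scores, labels, threshold):
    tp = fp = tn = fn = 0
    for s, y in zip(scores, labels):
        call = s >= threshold
        if call and y:
            tp += 1
        elif call and not y:
            fp += 1
        elif not call and not y:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def mann_whitney_auc(scores, labels):
    """Normalized U statistic with half credit for ties (rank formulation)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    ranks = rankdata(scores)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


class TestConfusion:
    def test_basic_counts(self):
        c = confusion([0.9, 0.4], [1, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)

    def test_score_at_threshold_counts_positive(self):
        c = confusion([0.5], [0])
        assert c.fp == 1

    def test_matches_naive_loop(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 60))
            scores = rng.random(n)
            labels = rng.integers(0, 2, size=n)
            t = float(rng.random())
            c = confusion(scores, labels, t)
            assert (c.tp, c.fp, c.tn, c.fn) == tuple(
                naive_confusion(scores, labels, t)[i] for i in (0, 1, 2, 3)
            )

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            confusion([], [])


class TestThresholdMetrics:
    def test_perfect_and_inverted_mcc(self):
        assert mcc(ConfusionCounts(5, 0, 5, 0)) == pytest.approx(1.0)
        assert mcc(ConfusionCounts(0, 5, 0, 5)) == pytest.approx(-1.0)

    def test_mcc_formula_value(self):
        c = ConfusionCounts(tp=3, fp=1, tn=4, fn=2)
        assert mcc(c) == pytest.approx(10 / math.sqrt(600))

    def test_undefined_mcc_is_nan_not_zero(self):
        assert math.isnan(mcc(ConfusionCounts(0, 0, 5, 5)))

    def test_percent_metrics(self):
        c = ConfusionCounts(tp=3, fp=1, tn=4, fn=2)
        assert q_total(c) == pytest.approx(70.0)
        assert ppv(c) == pytest.approx(75.0)
        assert sensitivity(c) == pytest.approx(60.0)
        assert specificity(c) == pytest.approx(80.0)
        assert ppv(ConfusionCounts(3, 0, 4, 2)) == pytest.approx(100.0)

    def test_random_counts_match_reimplementation(self, rng):
        for _ in range(200):
            tp, fp, tn, fn = (int(x) for x in rng.integers(1, 50, size=4))
            c = ConfusionCounts(tp, fp, tn, fn)
            assert q_total(c) == pytest.approx(100 * (tp + tn) / (tp + fp + tn + fn), abs=1e-12)
            assert ppv(c) == pytest.approx(100 * tp / (tp + fp), abs=1e-12)
            assert sensitivity(c) == pytest.approx(100 * tp / (tp + fn), abs=1e-12)
            assert specificity(c) == pytest.approx(100 * tn / (tn + fp), abs=1e-12)
            expected = (tp * tn - fp * fn) / math.sqrt(
                (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            )
            assert mcc(c) == pytest.approx(expected, abs=1e-12)

    def test_mcc_invariant_under_joint_swap(self, rng):
        for _ in range(100):
            tp, fp, tn, fn = (int(x) for x in rng.integers(1, 50, size=4))
            assert mcc(ConfusionCounts(tp, fp, tn, fn)) == pytest.approx(
                mcc(ConfusionCounts(tn, fn, tp, fp)), abs=1e-12
            )


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(1.0)

    def test_all_tied_scores(self):
        _, auc = roc_auc([0.5] * 10, [1, 0] * 5)
        assert auc == pytest.approx(0.5)

    def test_matches_mann_whitney(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 80))
            scores = np.round(rng.random(n), 2)  # rounded to force ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-10)

    def test_matches_reference_library(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(50):
            scores = rng.random(60)
            labels = rng.integers(0, 2, size=60)
            if labels.sum() in (0, 60):
                continue
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-10)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(100)
        labels = rng.integers(0, 2, size=100)
        _, a = roc_auc(scores, labels)
        _, b = roc_auc(np.exp(3 * scores) - 1, labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_curve_endpoints(self, rng):
        pts = roc_curve(rng.random(50), rng.integers(0, 2, size=50))
        assert pts["fpr"].iloc[0] == 0.0 and pts["tpr"].iloc[0] == 0.0
        assert pts["fpr"].iloc[-1] == 1.0 and pts["tpr"].iloc[-1] == 1.0


class TestThresholdSweep:
    def test_coarse_grid_contains_expected_thresholds(self, rng):
        df = threshold_sweep(rng.random(50), rng.integers(0, 2, size=50), step=0.5)
        assert list(df["threshold"]) == [0.0, 0.5, 1.0]

    def test_q_total_at_argmax_beats_default(self, rng):
        scores = rng.random(400)
        labels = rng.random(400) < 0.25
        labels[:2] = [True, False]
        df = threshold_sweep(scores, labels)
        best_t = df.attrs["best_q_total_threshold"]
        q_at_best = df.loc[np.isclose(df["threshold"], best_t), "q_total"].iloc[0]
        q_at_half = df.loc[np.isclose(df["threshold"], 0.5), "q_total"].iloc[0]
        assert q_at_best >= q_at_half

    def test_imbalanced_scores_favor_higher_q_threshold(self):
        """~25% positives with overlapping scores: accuracy wants a stricter
        cutoff than the correlation-optimal one (on average over seeds)."""
        t_mcc, t_q = [], []
        for seed in range(5):
            r = np.random.default_rng(seed)
            n = 4000
            y = r.random(n) < 0.25
            scores = np.where(y, r.beta(5, 3, n), r.beta(3, 5, n))
            df = threshold_sweep(scores, y)
            t_mcc.append(df.attrs["best_mcc_threshold"])
            t_q.append(df.attrs["best_q_total_threshold"])
        assert all(q >= m for q, m in zip(t_q, t_mcc))
        assert np.mean(t_q) > np.mean(t_mcc)


class TestAucDifference:
    def test_identical_scores_give_null_result(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        z, p = auc_difference_test(scores, scores, labels)
        assert z == 0.0 and p == 1.0

    def test_large_effect_is_significant(self, rng):
        n = 1000
        labels = rng.integers(0, 2, size=n)
        perfect = labels + rng.random(n) * 0.01
        random_scores = rng.random(n)
        _, p = auc_difference_test(perfect, random_scores, labels)
        assert p < 0.001

    def test_symmetric_p_under_swap(self, rng):
        a, b = rng.random(200), rng.random(200)
        labels = rng.integers(0, 2, size=200)
        z1, p1 = auc_difference_test(a, b, labels)
        z2, p2 = auc_difference_test(b, a, labels)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)


def test_metric_set_bundles_all_quantities(rng):
    scores = rng.random(200)
    labels = rng.integers(0, 2, size=200)
    ms = metric_set(scores, labels, threshold=0.5)
    assert ms.counts.total == 200
    assert -1 <= ms.mcc <= 1
    assert 0 <= ms.auc <= 1
    row = ms.to_row()
    assert set(row) >= {"mcc", "q_total", "ppv", "sensitivity", "specificity", "auc"}
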