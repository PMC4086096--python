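"""Metrics and the repeated-CV / hold-out protocol, against brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddicpi import (
    aupr,
    auroc,
    confusion_metrics,
    gen_planted_world,
    holdout_validate,
    max_f_threshold,
    pseudo_r2,
    repeated_cv,
)
from ddicpi.errors import DdicpiError, UndefinedMetricError


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation under test)
# ---------------------------------------------------------------------------


def bf_auroc(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = sum(1.0 if p > n else 0.5 if p == n else 0.0
                for p in pos for n in neg)
    return total / (len(pos) * len(neg))


def bf_aupr(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    ap, prev_recall = 0.0, 0.0
    n_pos = labels.sum()
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        precision = tp / pred.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def bf_max_f(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    best_f, best_t = -1.0, None
    for t in sorted(set(scores)):
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        f = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        if f > best_f:
            best_f, best_t = f, float(t)
    return best_t, best_f


SCORE_POOL = np.array([0.05, 0.2, 0.35, 0.5, 0.5, 0.65, 0.8, 0.9, 0.95,
                       0.1, 0.4, 0.7])


class TestRankingMetrics:
    def test_perfect_and_null_auroc(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        rng = np.random.default_rng(0)
        s = rng.random(20000)
        y = rng.integers(0, 2, 20000)
        assert auroc(s, y) == pytest.approx(0.5, abs=0.02)

    def test_hand_case_with_tie(self):
        s = [0.9, 0.8, 0.8, 0.4, 0.3, 0.2]
        y = [1, 1, 0, 1, 0, 0]
        # 7.5 of 9 drug-pair orderings concordant (tie counts 1/2)
        assert auroc(s, y) == pytest.approx(5 / 6)
        assert auroc(s, y) == pytest.approx(bf_auroc(s, y))

    def test_perfect_and_baseline_aupr(self):
        assert aupr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        rng = np.random.default_rng(1)
        s = rng.random(20000)
        y = (rng.random(20000) < 0.3).astype(int)
        assert aupr(s, y) == pytest.approx(y.mean(), abs=0.02)

    def test_hand_case_average_precision(self):
        s = [0.9, 0.7, 0.6, 0.4, 0.2]
        y = [1, 0, 1, 1, 0]
        assert aupr(s, y) == pytest.approx(1 / 3 + 2 / 9 + 1 / 4)
        assert aupr(s, y) == pytest.approx(bf_aupr(s, y))

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auroc([0.1, 0.2], [1, 1])
        with pytest.raises(UndefinedMetricError):
            aupr([0.1, 0.2], [0, 0])

    def test_exhaustive_small_instances_match_brute_force(self):
        # every label pattern with both classes, n <= 12, tie-rich scores
        for n in range(2, 13):
            scores = SCORE_POOL[:n]
            for pattern in itertools.product((0, 1), repeat=n):
                y = np.array(pattern)
                if y.min() == y.max():
                    continue
                assert auroc(scores, y) == pytest.approx(bf_auroc(scores, y))
                assert aupr(scores, y) == pytest.approx(bf_aupr(scores, y))

    @given(st.data())
    @settings(max_examples=40, derandomize=True)
    def test_auroc_invariant_under_monotone_transform(self, data):
        n = data.draw(st.integers(4, 30))
        rng = np.random.default_rng(n)
        s = rng.normal(size=n)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        base = auroc(s, y)
        assert auroc(np.exp(s), y) == pytest.approx(base)
        assert auroc(3 * s - 7, y) == pytest.approx(base)


class TestMaxFThreshold:
    def test_separable_case_returns_scanned_threshold(self):
        s = np.array([0.9, 0.8, 0.2, 0.1])
        y = np.array([1, 1, 0, 0])
        t, metrics = max_f_threshold(s, y)
        assert t == 0.8
        assert metrics.f1 == 1.0

    def test_anti_ranked_degenerate_case(self):
        # all positives below all negatives: predict-all-positive is best,
        # F = 2P / (2P + N) at the minimum threshold
        s = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        y = np.array([1, 1, 1, 0, 0])
        t, metrics = max_f_threshold(s, y)
        assert t == 0.1
        assert metrics.f1 == pytest.approx(6 / 8)

    def test_eight_point_hand_case(self):
        s = [0.95, 0.85, 0.7, 0.65, 0.5, 0.45, 0.3, 0.1]
        y = [1, 1, 0, 1, 1, 0, 0, 0]
        t, metrics = max_f_threshold(s, y)
        assert (t, metrics.f1) == (0.5, pytest.approx(8 / 9))
        assert (t, metrics.f1) == (bf_max_f(s, y)[0],
                                   pytest.approx(bf_max_f(s, y)[1]))

    def test_exhaustive_small_instances(self):
        for n in range(2, 11):
            scores = SCORE_POOL[:n]
            for pattern in itertools.product((0, 1), repeat=n):
                y = np.array(pattern)
                if y.min() == y.max():
                    continue
                t, metrics = max_f_threshold(scores, y)
                bt, bf = bf_max_f(scores, y)
                assert t == bt
                assert metrics.f1 == pytest.approx(bf)


class TestPseudoR2:
    def test_limits(self):
        assert pseudo_r2([1, 0, 1, 0], [1, 0, 1, 0]) == pytest.approx(1.0)
        assert pseudo_r2([0.4] * 4, [1, 0, 1, 0]) == 0.0

    def test_hand_case(self):
        s = [0.8, 0.7, 0.6, 0.4, 0.3, 0.1]
        y = [1, 1, 0, 1, 0, 0]
        assert pseudo_r2(s, y) == pytest.approx(0.38755980861244016)


class TestConfusionMetrics:
    @given(st.integers(0, 10_000))
    @settings(max_examples=30, derandomize=True)
    def test_consistent_with_one_confusion_table(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 60)
        s = rng.random(n)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        t = float(rng.random())
        m = confusion_metrics(s, y, t)
        pred = s >= t
        tp = np.sum(pred & (y == 1)); fp = np.sum(pred & (y == 0))
        fn = np.sum(~pred & (y == 1)); tn = np.sum(~pred & (y == 0))
        assert m.accuracy == pytest.approx((tp + tn) / n)
        assert m.precision == pytest.approx(tp / (tp + fp) if tp + fp else 0.0)
        assert m.sensitivity == pytest.approx(tp / (tp + fn) if tp + fn else 0.0)
        assert m.specificity == pytest.approx(tn / (tn + fp) if tn + fp else 0.0)


class TestRepeatedCV:
    def test_recovers_oracle_on_planted_world(self, default_world):
        w = default_world
        report = repeated_cv(w.X, w.pairs.labels, k=10, repeats=5,
                             lam=1.0, base_seed=100)
        assert abs(report.mean["auroc"] - w.oracle_auroc) < 0.03

    def test_shuffled_labels_give_null_auroc(self, default_world):
        w = default_world
        y = np.random.default_rng(0).permutation(w.pairs.labels)
        report = repeated_cv(w.X[:600], y[:600], k=5, repeats=2,
                             lam=1.0, base_seed=0)
        assert 0.45 <= report.mean["auroc"] <= 0.55

    def test_deterministic_replay(self, default_world):
        w = default_world
        X, y = w.X[:400], w.pairs.labels[:400]
        a = repeated_cv(X, y, k=5, repeats=2, lam=1.0, base_seed=3)
        b = repeated_cv(X, y, k=5, repeats=2, lam=1.0, base_seed=3)
        assert a.to_dict() == b.to_dict()

    def test_aggregates_recomputable_from_per_repeat_values(self, default_world):
        w = default_world
        report = repeated_cv(w.X[:600], w.pairs.labels[:600], k=5, repeats=3,
                             lam=1.0, base_seed=1)
        for metric in ("auroc", "aupr", "accuracy", "r2"):
            vals = np.array([getattr(r, metric) for r in report.per_repeat])
            assert report.mean[metric] == pytest.approx(vals.mean())
            assert report.sd[metric] == pytest.approx(vals.std(ddof=1))
        assert len(report.per_repeat) == 3
        assert len(report.thresholds) == 3

    def test_too_small_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        y = np.array([1] * 3 + [0] * 17)
        with pytest.raises(DdicpiError):
            repeated_cv(X, y, k=10, repeats=1)


class TestHoldoutValidate:
    def test_recovers_oracle_auroc(self, default_world):
        # the 1000-pair hold-out half makes a single split noisy (AUROC
        # se ~0.013), so recovery is judged on the mean over split seeds
        w = default_world
        rocs = [
            holdout_validate(w.X, w.pairs.labels, k=10, repeats=3,
                             lam=1.0, seed=seed)[0].auroc
            for seed in range(3)
        ]
        assert abs(np.mean(rocs) - w.oracle_auroc) < 0.03

    def test_no_anti_learning_and_deterministic(self, default_world):
        w = default_world
        X, y = w.X[:800], w.pairs.labels[:800]
        m1, cv1 = holdout_validate(X, y, k=5, repeats=2, lam=1.0, seed=5)
        m2, cv2 = holdout_validate(X, y, k=5, repeats=2, lam=1.0, seed=5)
        assert m1.to_dict() == m2.to_dict()
        assert cv1.to_dict() == cv2.to_dict()
        # threshold used on the hold-out half is the mean CV threshold
        assert m1.threshold == pytest.approx(np.mean(cv1.thresholds))

    def test_training_half_scores_at_least_holdout_on_average(self, default_world):
        w = default_world
        X, y = w.X, w.pairs.labels
        diffs = []
        for seed in range(4):
            hold, cv = holdout_validate(X, y, k=5, repeats=2, lam=1.0,
                                        seed=seed)
            diffs.append(cv.mean["auroc"] - hold.auroc)
        assert np.mean(diffs) > -0.02  # CV estimate not systematically worse
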