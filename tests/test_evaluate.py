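import itertools
import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from whistlekit.annotations import WhistleAnnotation
from whistlekit.evaluate import (
    ConfusionCounts,
    confusion,
    contour_qa,
    match_detections,
    metrics_from_counts,
    roc_auc,
    run_cv,
    stratified_kfold,
    train_final,
)
from whistlekit.nn import Dense, Flatten, ReLU, Sequential, Softmax
from whistlekit.nn.network import TrainingConfig
from whistlekit.spectrogram import SpectrogramImage


class TestConfusion:
    def test_perfect_agreement(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 1, 0, 0)

    def test_total_disagreement(self):
        c = confusion([1, 1, 0, 0], [0, 0, 1, 1])
        assert c.tp == 0 and c.tn == 0 and c.fp == 2 and c.fn == 2

    def test_mixed_example(self):
        c = confusion((1, 1, 0, 0), (1, 0, 0, 1))
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_all_16_patterns_match_enumeration(self):
        # exhaustive check against direct pair counting
        for truth in itertools.product([0, 1], repeat=4):
            for pred in itertools.product([0, 1], repeat=4):
                c = confusion(truth, pred)
                expected = {
                    (1, 1): 0, (0, 0): 0, (0, 1): 0, (1, 0): 0
                }
                for t, p in zip(truth, pred):
                    expected[(t, p)] += 1
                assert c.tp == expected[(1, 1)]
                assert c.tn == expected[(0, 0)]
                assert c.fp == expected[(0, 1)]
                assert c.fn == expected[(1, 0)]
                assert c.total == 4

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        t = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        perm = rng.permutation(50)
        a, b = confusion(t, p), confusion(t[perm], p[perm])
        assert (a.tp, a.tn, a.fp, a.fn) == (b.tp, b.tn, b.fp, b.fn)

    def test_label_validation(self):
        with pytest.raises(ValueError):
            confusion([0, 2], [0, 1])
        with pytest.raises(ValueError):
            confusion([0, 1], [0])


class TestMetricsFromCounts:
    def test_reference_miss_rate(self):
        # a detector that misses 2,139 of 2,657 whistles has 19.5% recall
        m = metrics_from_counts(ConfusionCounts(tp=518, fn=2139, tn=100, fp=10))
        assert m.as_percent_strings()["recall"] == "19.5%"
        assert m.recall == pytest.approx(518 / 2657)

    def test_perfect_classifier(self):
        m = metrics_from_counts(ConfusionCounts(tp=50, tn=50))
        assert m.accuracy == m.precision == m.recall == 1.0
        assert m.fpr == 0.0

    def test_zero_denominator_is_nan_not_zero(self):
        m = metrics_from_counts(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert math.isnan(m.precision)
        assert m.as_percent_strings()["precision"] == "n/a"
        assert not math.isnan(m.recall)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1)


def auc_brute_force(y, s):
    """O(n^2) concordance: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        roc = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert roc.auc == 1.0

    def test_uninformative_scores(self):
        roc = roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert roc.auc == pytest.approx(0.5)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        s = rng.random(100)
        roc = roc_auc(y, s)
        assert roc.fpr_points[0] == 0.0 and roc.tpr_points[0] == 0.0
        assert roc.fpr_points[-1] == 1.0 and roc.tpr_points[-1] == 1.0
        assert np.all(np.diff(roc.fpr_points) >= 0)
        assert np.all(np.diff(roc.tpr_points) >= 0)

    def test_matches_concordance_oracle_with_ties(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        s = np.round(rng.random(200), 2)  # force ties
        assert roc_auc(y, s).auc == pytest.approx(auc_brute_force(y, s), abs=1e-9)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 300)
        y[:2] = [0, 1]
        s = rng.random(300)
        assert roc_auc(y, s).auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


def whistle(t0, t1):
    return WhistleAnnotation(t0, t1, "whistle")


class TestMatchDetections:
    def test_covering_detection_is_tp(self):
        c = match_detections([(0.0, 10.0)], [whistle(2.0, 3.0)])
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_tiny_overlap_fails_and_detection_becomes_fp(self):
        c = match_detections([(0.0, 0.01)], [whistle(0.0, 1.0)])
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_no_detections(self):
        c = match_detections([], [whistle(0, 1), whistle(2, 3)])
        assert (c.fn, c.fp, c.tp) == (2, 0, 0)

    def test_one_detection_validates_multiple_truths(self):
        c = match_detections([(0.0, 5.0)], [whistle(1, 2), whistle(3, 4)])
        assert c.tp == 2 and c.fp == 0

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            match_detections([(1.0, 1.0)], [whistle(0, 1)])

    def test_monotone_in_overlap_threshold(self):
        rng = np.random.default_rng(4)
        truths = [whistle(t, t + rng.uniform(0.2, 0.6)) for t in rng.uniform(0, 20, 15)]
        dets = [(t, t + rng.uniform(0.05, 0.8)) for t in rng.uniform(0, 20, 20)]
        tps = [match_detections(dets, truths, f).tp for f in (0.01, 0.05, 0.2, 0.5, 0.9)]
        assert all(a >= b for a, b in zip(tps, tps[1:]))


class TestContourQA:
    def make_spec(self, values_db):
        arr = np.asarray(values_db, dtype=float)
        freqs = np.linspace(3000, 20000, arr.shape[0])
        times = np.linspace(0, 0.8, arr.shape[1])
        return SpectrogramImage(arr, freqs, times)

    def test_stable_in_band_contour_passes(self):
        spec = self.make_spec(np.full((40, 10), -50.0))
        contour = np.column_stack((np.linspace(0, 0.5, 5), np.full(5, 10000.0),
                                   np.zeros(5)))
        ann = WhistleAnnotation(0.0, 0.5, "whistle", contour=contour)
        verdict = contour_qa(ann, spec)
        assert verdict["bandwidth_ok"] and verdict["intensity_ok"]
        assert verdict["intensity_variance_db2"] == pytest.approx(0.0)

    def test_out_of_band_contour_fails_bandwidth(self):
        spec = self.make_spec(np.full((40, 10), -50.0))
        contour = np.array([[0.0, 2500.0, 0.0], [0.1, 10000.0, 0.0]])
        ann = WhistleAnnotation(0.0, 0.2, "whistle", contour=contour)
        assert not contour_qa(ann, spec)["bandwidth_ok"]

    def test_variance_matches_hand_computation(self):
        # alternating +/-10 dB frames along a constant-frequency contour
        values = np.zeros((40, 8))
        values[:, ::2] = 10.0
        values[:, 1::2] = -10.0
        spec = self.make_spec(values)
        times = spec.times[:8]
        contour = np.column_stack((times, np.full(8, 10000.0), np.zeros(8)))
        ann = WhistleAnnotation(0.0, 0.8, "whistle", contour=contour)
        v = contour_qa(ann, spec, var_limit_db2=50.0)
        assert v["intensity_variance_db2"] == pytest.approx(100.0)
        assert not contour_qa(ann, spec, var_limit_db2=25.0)["intensity_ok"]

    def test_missing_contour_rejected(self):
        spec = self.make_spec(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="contour"):
            contour_qa(WhistleAnnotation(0, 1, "whistle"), spec)


class TestStratifiedKFold:
    def test_balanced_ten_items(self):
        plan = stratified_kfold([0] * 5 + [1] * 5, k=5, seed=0)
        y = np.array([0] * 5 + [1] * 5)
        for fold in range(5):
            _, test = plan.fold_indices(fold)
            assert len(test) == 2
            assert y[test].sum() == 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold([1] * 10, k=5)

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            stratified_kfold([0] * 10 + [1] * 3, k=5)

    def test_uneven_counts_within_one_of_proportional(self):
        y = np.array([0] * 61 + [1] * 42)
        plan = stratified_kfold(y, k=5, seed=1)
        sizes, zeros, ones = [], [], []
        for fold in range(5):
            _, test = plan.fold_indices(fold)
            sizes.append(len(test))
            zeros.append(int((y[test] == 0).sum()))
            ones.append(int((y[test] == 1).sum()))
        assert set(sizes) <= {20, 21}
        assert max(zeros) - min(zeros) <= 1
        assert max(ones) - min(ones) <= 1
        assert sum(sizes) == 103

    def test_balance_invariant_on_random_label_vectors(self):
        rng = np.random.default_rng(7)
        for trial in range(100):
            n = int(rng.integers(20, 200))
            y = rng.integers(0, 2, n)
            if min((y == 0).sum(), (y == 1).sum()) < 5:
                continue
            plan = stratified_kfold(y, k=5, seed=trial)
            for cls in (0, 1):
                counts = [int((y[plan.assignments == f] == cls).sum()) for f in range(5)]
                assert max(counts) - min(counts) <= 1
            # every item in exactly one fold
            assert np.all((plan.assignments >= 0) & (plan.assignments < 5))

    def test_matches_sklearn_fold_size_behavior(self):
        # independent reference: same per-fold class-count multiset
        y = np.array([0] * 23 + [1] * 17)
        plan = stratified_kfold(y, k=5, seed=0)
        ours = sorted(
            tuple(int((y[plan.assignments == f] == c).sum()) for c in (0, 1))
            for f in range(5)
        )
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        theirs = sorted(
            tuple(int((y[test] == c).sum()) for c in (0, 1))
            for _, test in skf.split(np.zeros(len(y)), y)
        )
        assert ours == theirs

    def test_deterministic_per_seed(self):
        y = np.random.default_rng(0).integers(0, 2, 50)
        a = stratified_kfold(y, k=5, seed=3)
        b = stratified_kfold(y, k=5, seed=3)
        np.testing.assert_array_equal(a.assignments, b.assignments)


def dense_builder(seed):
    return Sequential([Dense(16), ReLU(), Dense(2), Softmax()]).build((10,), seed=seed)


class TestRunCV:
    @pytest.fixture(scope="class")
    def linear_task(self):
        # easy, well-separated task: points near the boundary removed
        rng = np.random.default_rng(9)
        x = rng.standard_normal((400, 10)).astype(np.float32)
        w = rng.standard_normal(10)
        margin = np.abs(x @ w) > 1.0
        x = x[margin][:100]
        y = ((x @ w) > 0).astype(int)
        return x, y

    def test_easy_task_high_mean_accuracy(self, linear_task):
        x, y = linear_task
        cfg = TrainingConfig(learning_rate=1e-2, max_epochs=30, batch_size=16,
                             validation_fraction=0.0, seed=0)
        out = run_cv(x, y, dense_builder, cfg, k=5, seed=0)
        assert out["mean_accuracy"] >= 0.9
        assert len(out["fold_accuracy"]) == 5

    def test_fold_assignments_deterministic(self, linear_task):
        x, y = linear_task
        cfg = TrainingConfig(learning_rate=1e-2, max_epochs=2, batch_size=16, seed=0)
        a = run_cv(x, y, dense_builder, cfg, k=2, seed=5)
        b = run_cv(x, y, dense_builder, cfg, k=2, seed=5)
        np.testing.assert_array_equal(a["fold_plan"].assignments,
                                      b["fold_plan"].assignments)

    def test_two_folds_on_four_items(self):
        x = np.array([[0.0], [0.0], [1.0], [1.0]], dtype=np.float32)
        y = np.array([0, 1, 0, 1])
        cfg = TrainingConfig(learning_rate=1e-2, max_epochs=1, batch_size=2,
                             validation_fraction=0.0, seed=0)
        builder = lambda seed: Sequential([Dense(2), Softmax()]).build((1,), seed=seed)
        out = run_cv(x, y, builder, cfg, k=2, seed=0)
        for fold in range(2):
            _, test = out["fold_plan"].fold_indices(fold)
            assert len(test) == 2


class TestTrainFinal:
    def test_checkpoint_reload_reproduces_predictions(self, tmp_path):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((40, 10)).astype(np.float32)
        y = (x[:, 0] > 0).astype(int)
        cfg = TrainingConfig(learning_rate=1e-2, max_epochs=5, batch_size=8, seed=1)
        ckpt = tmp_path / "final.npz"
        model, history = train_final(x, y, dense_builder, cfg, checkpoint_path=ckpt)
        assert history["stopped_epoch"] <= cfg.max_epochs - 1
        assert min(history["val_loss"]) <= history["val_loss"][0]
        clone = dense_builder(99)
        clone.load_weights(ckpt)
        np.testing.assert_array_equal(model.predict_proba(x), clone.predict_proba(x))

    def test_empty_dataset_rejected(self):
        cfg = TrainingConfig(seed=0)
        with pytest.raises(ValueError, match="empty"):
            train_final(np.empty((0, 10)), np.empty(0), dense_builder, cfg)
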