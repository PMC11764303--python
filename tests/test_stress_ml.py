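"""Feature extraction, K-means pseudo-labeling, SVM training and the
evaluation metrics, cross-checked against independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn import metrics as skm

from conftest import make_trace
from edastress.preprocess import phasic_component
from edastress.scr_events import detect_events
from edastress.stress_ml import (
    FEATURE_NAMES,
    MLConfig,
    evaluate,
    extract_features,
    features_frame,
    kmeans_stress_clusters,
    train_classifier,
)
from edastress.synthetic_data import SCRShape, simulate_trace


class TestExtractFeatures:
    def test_flat_trace(self):
        tr = make_trace(np.full(30, 3.0))
        fv = extract_features(tr, phasic_component(tr), [])
        assert fv.peak_amplitude == 0.0 and fv.peak_width == 0.0
        assert fv.mean_gsr == pytest.approx(3.0)

    def test_simulated_bump_features_match_injection(self):
        shape = SCRShape(stimulus_time=10, latency=3, amplitude=2.51, rise_time=22, recovery_half_time=30)
        sim = simulate_trace([shape], tonic_baseline=4.48, noise_sd=0.0)
        ph = phasic_component(sim.trace)
        events = detect_events(sim.trace, ph)
        fv = extract_features(sim.trace, ph, events)
        assert fv.peak_amplitude == pytest.approx(2.51, rel=0.05)
        assert fv.amp_minus_mean == pytest.approx(
            np.max(sim.trace.conductance) - np.mean(sim.trace.conductance), abs=0.1
        )
        assert fv.phasic_max == pytest.approx(np.nanmax(ph.phasic))

    def test_features_frame_normalized_columns(self):
        tr1 = make_trace(np.full(30, 3.0))
        tr2 = make_trace(np.full(30, 6.0))
        fvs = [extract_features(t, phasic_component(t), []) for t in (tr1, tr2)]
        df = features_frame(fvs)
        for name in FEATURE_NAMES:
            assert df[f"{name}_norm"].between(0, 1).all()
        assert df["mean_gsr_norm"].tolist() == [0.0, 1.0]


def brute_force_two_partition(points):
    """Independent oracle: the 2-partition minimizing within-cluster SSE."""
    pts = np.asarray(points, dtype=float)
    best, best_sse = None, np.inf
    for mask in itertools.product([0, 1], repeat=len(pts)):
        mask = np.array(mask, dtype=bool)
        if mask.all() or not mask.any():
            continue
        sse = ((pts[mask] - pts[mask].mean()) ** 2).sum() + (
            (pts[~mask] - pts[~mask].mean()) ** 2
        ).sum()
        if sse < best_sse:
            best, best_sse = mask, sse
    return best


class TestKMeans:
    def test_one_dimensional_toy_matches_brute_force(self):
        pts = np.array([0.1, 0.15, 2.0, 2.2])
        labels, centroids = kmeans_stress_clusters(pts[:, None], seed=0)
        oracle = brute_force_two_partition(pts)
        # stressed cluster (label 1) is the one with larger amplitudes
        expected = oracle if pts[oracle].mean() > pts[~oracle].mean() else ~oracle
        np.testing.assert_array_equal(labels.astype(bool), expected)
        assert centroids[1, 0] > centroids[0, 0]

    def test_separated_blobs_and_reorder_invariance(self):
        rng = np.random.default_rng(4)
        low = rng.normal([0.2, 0.1], 0.05, (10, 2))
        high = rng.normal([2.0, 1.0], 0.05, (10, 2))
        X = np.vstack([low, high])
        labels, _ = kmeans_stress_clusters(X, seed=0)
        np.testing.assert_array_equal(labels, np.r_[np.zeros(10), np.ones(10)])
        perm = rng.permutation(20)
        labels_perm, _ = kmeans_stress_clusters(X[perm], seed=0)
        np.testing.assert_array_equal(labels_perm, labels[perm])

    def test_identical_points_degenerate(self):
        with pytest.raises(ValueError, match="distinct"):
            kmeans_stress_clusters(np.ones((5, 2)), seed=0)


class TestTrainClassifier:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.2, (15, 2)), rng.normal(3, 0.2, (15, 2))])
        y = np.r_[np.zeros(15), np.ones(15)]
        model = train_classifier(X, y, MLConfig(kernel="linear", seed=0))
        assert (model.predict(X) == y).mean() == 1.0

    def test_rbf_beats_linear_on_xor(self):
        rng = np.random.default_rng(1)
        centers = np.array([[0, 0], [1, 1], [0, 1], [1, 0]])
        X = np.vstack([rng.normal(c, 0.08, (12, 2)) for c in centers])
        y = np.r_[np.zeros(24), np.ones(24)]
        rbf = train_classifier(X, y, MLConfig(kernel="rbf", seed=0))
        lin = train_classifier(X, y, MLConfig(kernel="linear", seed=0))
        assert rbf.best_score_ > lin.best_score_
        assert rbf.best_score_ > 0.9

    def test_duplicated_points_leave_boundary_unchanged(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.3, (10, 2)), rng.normal(2, 0.3, (10, 2))])
        y = np.r_[np.zeros(10), np.ones(10)]
        cfg = MLConfig(kernel="rbf", gamma=2.0, grid_search=False)
        probe = rng.uniform(-1, 3, (50, 2))
        p1 = train_classifier(X, y, cfg).predict(probe)
        p2 = train_classifier(np.vstack([X, X]), np.r_[y, y], cfg).predict(probe)
        np.testing.assert_array_equal(p1, p2)

    def test_nusvm_variants_fit(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.4, (20, 2)), rng.normal(1.5, 0.4, (20, 2))])
        y = np.r_[np.zeros(20), np.ones(20)]
        for nu in (0.02, 0.2):
            model = train_classifier(X, y, MLConfig(kernel="rbf", gamma=2.0, nu=nu))
            assert (model.predict(X) == y).mean() > 0.9

    def test_swapped_class_distributions_swap_fractions(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.3, (20, 2))
        b = rng.normal(2, 0.3, (20, 2))
        probe = rng.uniform(-1, 3, (200, 2))
        cfg = MLConfig(kernel="rbf", gamma=2.0, grid_search=False)
        X = np.vstack([a, b])
        f1 = train_classifier(X, np.r_[np.zeros(20), np.ones(20)], cfg).predict(probe).mean()
        f2 = train_classifier(X, np.r_[np.ones(20), np.zeros(20)], cfg).predict(probe).mean()
        assert f1 + f2 == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_classifier(np.random.default_rng(0).normal(size=(10, 2)), np.zeros(10))


class TestEvaluate:
    def test_perfect_predictions(self):
        m = evaluate([1, 0, 1, 0], [1, 0, 1, 0])
        assert m.precision == m.recall == m.f1 == m.accuracy == 1.0

    def test_balanced_errors(self):
        # tp=1, fp=1, fn=1, tn=1
        m = evaluate([1, 1, 0, 0], [1, 0, 1, 0])
        assert (m.tp, m.fp, m.fn, m.tn) == (1, 1, 1, 1)
        assert m.precision == m.recall == m.f1 == 0.5

    def test_no_positives_predicted_convention(self):
        m = evaluate([0, 0, 0], [1, 1, 0])
        assert m.precision == 0.0 and m.f1 == 0.0 and m.recall == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate([1, 0], [1])

    @given(
        st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1, max_size=40)
    )
    @settings(deadline=None, max_examples=100)
    def test_agrees_with_sklearn_and_bounds(self, pairs):
        pred = np.array([p for p, _ in pairs])
        truth = np.array([t for _, t in pairs])
        m = evaluate(pred, truth)
        assert m.precision == pytest.approx(
            skm.precision_score(truth, pred, zero_division=0)
        )
        assert m.recall == pytest.approx(skm.recall_score(truth, pred, zero_division=0))
        assert m.f1 == pytest.approx(skm.f1_score(truth, pred, zero_division=0))
        assert m.accuracy == pytest.approx(skm.accuracy_score(truth, pred))
        assert m.f1 <= max(m.precision, m.recall) + 1e-12
        assert 0.0 <= m.accuracy <= 1.0
        if m.precision and m.recall:
            harmonic = 2 / (1 / m.precision + 1 / m.recall)
            assert m.f1 == pytest.approx(harmonic)
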