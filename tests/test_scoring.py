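"""Metric values against closed forms and double-loop reference
implementations, plus the orientation and permutation-invariance
properties every score must satisfy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octood import (DirichletOutput, PredictionStack, aggregate_stack,
                    fit_centers, fit_gaussians, score_cosine,
                    score_dirichlet_u, score_entropy, score_mahalanobis,
                    score_mp, score_rbp, score_uh, score_us,
                    temperature_softmax)

ONEHOT = np.array([1.0, 0.0, 0.0, 0.0])
UNIFORM4 = np.full(4, 0.25)


class TestProbabilityMetrics:
    @pytest.mark.parametrize("p,expected", [
        (ONEHOT, 0.0),
        (UNIFORM4, 0.75),
        (np.array([0.6, 0.4, 0.0, 0.0]), 0.4),
    ])
    def test_mp(self, p, expected):
        assert score_mp(p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("p,expected", [
        (ONEHOT, 0.0),
        (UNIFORM4, np.log(4)),
        (np.array([0.5, 0.5, 0.0, 0.0]), np.log(2)),
    ])
    def test_entropy(self, p, expected):
        assert score_entropy(p) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("evidence,expected", [
        (np.zeros(4), 1.0),        # zero evidence -> maximal uncertainty
        (np.array([4.0, 0, 0, 0]), 0.5),
        (np.array([96.0, 0, 0, 0]), 0.04),
    ])
    def test_dirichlet_u(self, evidence, expected):
        assert score_dirichlet_u(evidence) == pytest.approx(expected, abs=1e-12)
        assert score_dirichlet_u(DirichletOutput(evidence)) == pytest.approx(expected)

    @pytest.mark.parametrize("p,expected", [
        (np.array([0.0, 0.0, 0.0, 0.0, 1.0]), 1.0),
        (np.array([0.4, 0.3, 0.2, 0.1, 0.0]), 0.0),
        (np.full(5, 0.2), 0.2),
    ])
    def test_rbp(self, p, expected):
        assert score_rbp(p) == pytest.approx(expected, abs=1e-12)

    def test_temperature_softmax(self):
        f = np.array([2.0, 0.0])
        assert np.allclose(temperature_softmax(f, 1.0),
                           np.exp(f) / np.exp(f).sum())
        assert temperature_softmax(f, 2.0) == pytest.approx(
            [0.7311, 0.2689], abs=1e-4)
        assert np.allclose(temperature_softmax(f, 1e9), [0.5, 0.5], atol=1e-8)
        # argmax preserved for any positive temperature
        g = np.array([0.3, 2.5, -1.0, 0.9])
        for T in (0.5, 1, 10, 1000):
            assert temperature_softmax(g, T).argmax() == g.argmax()
        with pytest.raises(ValueError):
            temperature_softmax(f, 0.0)

    @given(st.permutations(range(4)))
    @settings(deadline=None, max_examples=24)
    def test_entropy_invariant_under_class_permutation(self, perm):
        p = np.array([0.55, 0.25, 0.15, 0.05])
        assert score_entropy(p[list(perm)]) == pytest.approx(score_entropy(p))


class TestFeatureMetrics:
    def test_cosine_trivial_and_hand_values(self):
        centers = fit_centers(
            np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]]),
            np.array(["a", "a", "b", "b"]))
        assert score_cosine(np.array([1.0, 0.0]), centers) == pytest.approx(0.0)
        x = np.array([1.0, 1.0]) / np.sqrt(2)
        assert score_cosine(x, centers) == pytest.approx(1 - 1 / np.sqrt(2),
                                                         abs=1e-9)

    def test_cosine_zero_norm_rejected(self):
        centers = fit_centers(np.array([[1.0, 0.0]]), np.array(["a"]))
        with pytest.raises(ValueError, match="zero-norm"):
            score_cosine(np.zeros(2), centers)

    def test_mahalanobis_identity_covariance_equals_euclidean(self):
        # two classes, zero-mean isotropic clouds -> distance to closer mean
        rng = np.random.default_rng(0)
        model_input = rng.normal(0, 1, (4000, 2))
        labels = np.array(["a", "b"] * 2000)
        model = fit_gaussians(model_input, labels, shrinkage=0.0)
        model.means = np.array([[0.0, 0.0], [100.0, 100.0]])
        model.covariance = np.eye(2)
        model.precision = np.eye(2)
        assert score_mahalanobis(np.array([3.0, 4.0]), model) == pytest.approx(5.0)
        assert score_mahalanobis(np.array([0.0, 0.0]), model) == pytest.approx(0.0)

    def test_mahalanobis_diagonal_closed_form(self):
        model = fit_gaussians(np.random.default_rng(1).normal(0, 1, (100, 2)),
                              np.array(["a"] * 100), shrinkage=0.1)
        model.means = np.zeros((1, 2))
        model.covariance = np.diag([4.0, 1.0])
        model.precision = np.diag([0.25, 1.0])
        assert score_mahalanobis(np.array([2.0, 0.0]), model) == pytest.approx(1.0)

    def test_singular_covariance_without_shrinkage_raises(self):
        # fewer samples than dimensions -> singular empirical covariance
        feats = np.random.default_rng(2).normal(0, 1, (5, 10))
        labels = np.array(["a"] * 5)
        with pytest.raises(ValueError, match="shrinkage"):
            fit_gaussians(feats, labels, shrinkage=0.0)
        fit_gaussians(feats, labels, shrinkage=0.1)  # shrunk works

    def test_double_loop_reference_equivalence(self):
        """Vectorized scores agree with naive per-sample/per-class loops."""
        rng = np.random.default_rng(3)
        feats = rng.normal(0, 1, (60, 10))
        labels = rng.choice(["a", "b", "c"], size=60)
        x = rng.normal(0, 1, (20, 10))
        centers = fit_centers(feats, labels)
        gauss = fit_gaussians(feats, labels, shrinkage=0.1)
        cos = score_cosine(x, centers)
        mah = score_mahalanobis(x, gauss)
        for i in range(len(x)):
            sims = []
            dists = []
            for j, c in enumerate(centers.classes):
                v = centers.centers[j]
                sims.append(x[i] @ v / (np.linalg.norm(x[i]) * np.linalg.norm(v)))
                diff = x[i] - gauss.means[j]
                dists.append(np.sqrt(diff @ gauss.precision @ diff))
            assert cos[i] == pytest.approx(1 - max(sims), abs=1e-8)
            assert mah[i] == pytest.approx(min(dists), abs=1e-8)


class TestStackMetrics:
    def test_identical_onehot_rows_score_zero(self):
        stack = PredictionStack(np.tile(ONEHOT, (5, 1)))
        assert score_us(stack) == pytest.approx(0.0, abs=1e-12)
        assert score_uh(stack) == pytest.approx(0.0, abs=1e-12)

    def test_us_population_variance_value(self):
        stack = PredictionStack(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert score_us(stack) == pytest.approx(0.25)

    def test_uncertain_rows_score_higher_than_confident(self):
        confident = PredictionStack(np.tile(ONEHOT, (6, 1)))
        uniform = PredictionStack(np.tile(UNIFORM4, (6, 1)))
        assert score_uh(uniform) > score_uh(confident)

    @given(st.permutations(range(5)))
    @settings(deadline=None, max_examples=20)
    def test_row_order_invariance(self, perm):
        rng = np.random.default_rng(4)
        p = rng.dirichlet(np.ones(4), size=5)
        a, b = PredictionStack(p), PredictionStack(p[list(perm)])
        assert score_us(a) == pytest.approx(score_us(b))
        assert score_uh(a) == pytest.approx(score_uh(b))

    def test_aggregate_stack(self):
        rows = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert np.allclose(aggregate_stack(PredictionStack(rows)), [0.5, 0.5])
        same = np.tile(np.array([0.7, 0.3]), (4, 1))
        assert np.allclose(aggregate_stack(PredictionStack(same)), [0.7, 0.3])

    def test_stack_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PredictionStack(np.array([[0.5, 0.4], [0.5, 0.5]]))
        with pytest.raises(ValueError, match="N >= 2"):
            score_us(PredictionStack(np.array([[1.0, 0.0]])))


class TestOrientation:
    """Every metric scores a textbook in-distribution case strictly below
    the corresponding maximal-uncertainty case."""

    def test_probability_metrics(self):
        for fn in (score_mp, score_entropy):
            assert fn(ONEHOT) < fn(UNIFORM4)
        assert score_dirichlet_u(np.array([50.0, 0, 0, 0])) < score_dirichlet_u(
            np.zeros(4))
        assert score_rbp(np.array([0.9, 0.05, 0.03, 0.01, 0.01])) < score_rbp(
            np.array([0.05, 0.05, 0.05, 0.05, 0.8]))

    def test_feature_metrics(self):
        feats = np.vstack([np.tile([1.0, 0.0], (30, 1)),
                           np.tile([0.0, 1.0], (30, 1))])
        feats += np.random.default_rng(0).normal(0, 0.05, feats.shape)
        labels = np.array(["a"] * 30 + ["b"] * 30)
        centers = fit_centers(feats, labels)
        gauss = fit_gaussians(feats, labels, shrinkage=0.1)
        on_center = feats[:30].mean(axis=0)
        off = np.array([-1.0, -1.0])
        assert score_cosine(on_center, centers) < score_cosine(off, centers)
        assert score_mahalanobis(on_center, gauss) < score_mahalanobis(off, gauss)
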