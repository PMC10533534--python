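"""Evaluation statistics against brute-force oracles: pairwise AUC
enumeration (with ties), the balanced bootstrap's reduction property,
monotone-transform invariance, exact rank-sum enumeration, and the
cluster cosine distances."""

import numpy as np
import pytest

from octood import (auc, balanced_bootstrap_auc, cluster_cosine_distances,
                    macro_auc, wilcoxon_compare)


def brute_force_auc(inliers, outliers):
    """O(n*m) Mann-Whitney probability with ties counted 1/2."""
    wins = 0.0
    for o in outliers:
        for i in inliers:
            wins += 1.0 if o > i else (0.5 if o == i else 0.0)
    return wins / (len(inliers) * len(outliers))


class TestAUC:
    def test_examples(self):
        assert auc([0.0, 0.1], [0.5, 0.9]) == 1.0
        assert auc([0.3, 0.7], [0.3, 0.7]) == 0.5
        assert auc([0.1, 0.2], [0.15, 0.3]) == pytest.approx(0.75)

    def test_agrees_with_pairwise_enumeration_including_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n, m = rng.integers(2, 30, size=2)
            # coarse grid forces plenty of ties
            a = rng.choice(np.linspace(0, 1, 7), size=n)
            b = rng.choice(np.linspace(0, 1, 7), size=m)
            assert auc(a, b) == pytest.approx(brute_force_auc(a, b), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.choice(np.linspace(0, 1, 9), size=40)
        b = rng.choice(np.linspace(0, 1, 9), size=25)
        base = auc(a, b)
        pooled = np.unique(np.concatenate([a, b]))
        for _ in range(50):
            # random strictly increasing map defined on the pooled values
            steps = rng.uniform(0.1, 3.0, size=len(pooled))
            table = dict(zip(pooled, np.cumsum(steps)))
            fa = np.array([table[v] for v in a])
            fb = np.array([table[v] for v in b])
            assert auc(fa, fb) == pytest.approx(base, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            auc([], [0.5])


class TestBalancedBootstrap:
    def test_single_class_reduces_exactly_to_plain_auc(self):
        rng = np.random.default_rng(2)
        inl = rng.random(30)
        out = rng.random(17)
        mean, sd = balanced_bootstrap_auc(inl, {"only": out}, n_boot=10, seed=0)
        assert mean == pytest.approx(auc(inl, out), abs=1e-15)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_fully_separated_gives_one_with_zero_spread(self):
        inl = np.linspace(0, 0.4, 20)
        by_class = {"a": np.linspace(0.6, 1, 9), "b": np.linspace(0.5, 0.9, 30)}
        mean, sd = balanced_bootstrap_auc(inl, by_class, seed=3)
        assert mean == 1.0 and sd == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        inl = rng.random(25)
        by_class = {"a": rng.random(10), "b": rng.random(40)}
        r1 = balanced_bootstrap_auc(inl, by_class, seed=9)
        r2 = balanced_bootstrap_auc(inl, by_class, seed=9)
        assert r1 == r2

    def test_mean_lies_between_per_class_extremes(self):
        rng = np.random.default_rng(5)
        inl = rng.normal(0, 1, 50)
        by_class = {"a": rng.normal(0.3, 1, 12), "b": rng.normal(1.5, 1, 60)}
        mean, _ = balanced_bootstrap_auc(inl, by_class, seed=1)
        per = [auc(inl, v) for v in by_class.values()]
        assert min(per) - 0.05 <= mean <= max(per) + 0.05

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="no scores"):
            balanced_bootstrap_auc([0.1], {"a": []})


class TestMacroAUC:
    def test_perfect_classifier_scores_one(self):
        labels = np.array([0, 1, 2, 3] * 5)
        probs = np.eye(4)[labels]
        assert macro_auc(probs, labels) == 1.0

    def test_binary_macro_equals_plain_auc(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 2, 40)
        p1 = rng.random(40)
        probs = np.column_stack([1 - p1, p1])
        ref = auc(p1[labels == 0], p1[labels == 1])
        assert macro_auc(probs, labels) == pytest.approx(ref)

    def test_random_probabilities_near_half(self):
        # permutation oracle: with label-independent scores the expected
        # one-vs-rest AUC is 0.5; check a 3-sigma band at n=500
        rng = np.random.default_rng(7)
        labels = np.repeat(np.arange(4), 125)
        probs = rng.dirichlet(np.ones(4), size=500)
        got = macro_auc(probs, labels)
        # per-class AUC sd ~ sqrt(1/12 * (1/125 + 1/375)) ~ 0.03
        assert abs(got - 0.5) < 3 * 0.03

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            macro_auc(np.eye(3)[[0, 1, 0]], np.array([0, 1, 0]))


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        p = wilcoxon_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_exact_enumeration_small_samples(self):
        # fully separated n=m=3: 2 of the 20 rank assignments are as
        # extreme -> two-sided p = 0.1
        assert wilcoxon_compare([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1,
                                                                       abs=1e-10)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(8)
        a, b = rng.random(6), rng.random(9)
        assert wilcoxon_compare(a, b) == pytest.approx(wilcoxon_compare(b, a))

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 40)
        b = rng.normal(1, 1, 40)
        p = wilcoxon_compare(a, b)
        assert 0 < p < 0.01


class TestClusterCosineDistances:
    def test_trivial_and_hand_values(self):
        inl = np.tile([1.0, 0.0], (10, 1))
        labels = np.array(["normal"] * 10 + ["DME"] * 5 + ["RVO"] * 5)
        out_same = np.tile([1.0, 0.0], (5, 1))
        out_orth = np.tile([0.0, 1.0], (5, 1))
        feats = np.vstack([inl, out_same, out_orth])
        d = cluster_cosine_distances(feats, labels)
        assert d["DME"] == pytest.approx(0.0, abs=1e-12)
        assert d["RVO"] == pytest.approx(1.0, abs=1e-12)

    def test_hand_trigonometry(self):
        feats = np.vstack([np.tile([1.0, 0.0], (4, 1)),
                           np.tile([0.6, 0.8], (4, 1))])
        labels = np.array(["normal"] * 4 + ["DME"] * 4)
        d = cluster_cosine_distances(feats, labels)
        assert d["DME"] == pytest.approx(0.4, abs=1e-12)
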