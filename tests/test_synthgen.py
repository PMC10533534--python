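"""Generator contracts: determinism, taxonomy, intensity hygiene,
patient-wise splitting, and the pixel-space similarity geometry the
whole benchmark rests on."""

import itertools

import numpy as np
import pytest

from octood import (ALL_CLASSES, INLIER_CLASSES, LABEL_ROLE, NEAR_OOD_CLASSES,
                    DatasetConfig, generate_dataset, render_image)


def _render_many(label, n, seed=0, cfg=None):
    rng = np.random.default_rng(seed)
    return np.stack([render_image(label, rng, cfg).pixels for _ in range(n)])


class TestRenderImage:
    @pytest.mark.parametrize("label", ALL_CLASSES)
    def test_deterministic_given_rng_state(self, label):
        a = render_image(label, np.random.default_rng(42))
        b = render_image(label, np.random.default_rng(42))
        assert np.array_equal(a.pixels, b.pixels)
        assert a.label == label and a.role == LABEL_ROLE[label]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            render_image("glaucoma", np.random.default_rng(0))

    def test_taxonomy_has_fixed_role_counts(self):
        roles = list(LABEL_ROLE.values())
        assert roles.count("inlier") == 4
        assert roles.count("nearOOD") == 3
        assert roles.count("farOOD") == 1

    def test_intensities_in_unit_interval_with_little_clipping(self):
        clipped = []
        for label in ALL_CLASSES:
            imgs = _render_many(label, 25, seed=3)
            assert imgs.min() >= 0.0 and imgs.max() <= 1.0
            clipped.append(((imgs == 0.0) | (imgs == 1.0)).mean())
        assert np.mean(clipped) < 0.05

    def test_side_is_configurable(self):
        cfg = DatasetConfig(side=48)
        img = render_image("normal", np.random.default_rng(0), cfg)
        assert img.pixels.shape == (48, 48)


@pytest.fixture(scope="module")
def class_correlations():
    n = 100
    flats = {lab: _render_many(lab, n, seed=11).reshape(n, -1)
             for lab in ALL_CLASSES}
    normed = {}
    for lab, f in flats.items():
        c = f - f.mean(axis=1, keepdims=True)
        normed[lab] = c / np.linalg.norm(c, axis=1, keepdims=True)
    corr = {}
    for a, b in itertools.combinations_with_replacement(ALL_CLASSES, 2):
        m = float((normed[a] @ normed[b].T).mean())
        corr[(a, b)] = corr[(b, a)] = m
    return corr


class TestSimilarityGeometry:
    """Brute-force mean pairwise Pearson correlations between classes.

    The fluid-bearing classes (nAMD, DME, RVO) must be mutually closer
    than any of them is to the atrophy-like classes (GA, Stargardt),
    and the far-OOD texture must be farther from every retinal analog
    than any inlier/near-OOD pair is from each other.
    """

    def test_fluid_classes_mutually_closer_than_to_atrophy(self, class_correlations):
        fluid = ("nAMD", "DME", "RVO")
        atrophy = ("GA", "Stargardt")
        mutual = min(class_correlations[(a, b)]
                     for a, b in itertools.combinations(fluid, 2))
        cross = max(class_correlations[(a, b)] for a in fluid for b in atrophy)
        assert mutual > cross

    def test_namd_closer_to_dme_than_to_stargardt(self, class_correlations):
        assert (class_correlations[("nAMD", "DME")]
                > class_correlations[("nAMD", "Stargardt")])

    def test_far_ood_is_farthest_from_all_retinal_classes(self, class_correlations):
        far_max = max(class_correlations[("farOOD", lab)]
                      for lab in ALL_CLASSES if lab != "farOOD")
        near_min = min(class_correlations[(a, b)]
                       for a in INLIER_CLASSES for b in NEAR_OOD_CLASSES)
        assert far_max < near_min


class TestGenerateDataset:
    def test_split_fractions_are_exact_for_round_counts(self):
        ds = generate_dataset(DatasetConfig(images_per_class=100, side=32, seed=0))
        for cls in INLIER_CLASSES:
            counts = {name: len(s.by_label(cls))
                      for name, s in ds.splits.items()}
            assert (counts["train"], counts["val"], counts["test"]) == (70, 15, 15)

    def test_same_config_reproduces_identical_dataset(self):
        cfg = DatasetConfig(images_per_class=12, side=32, seed=5)
        a, b = generate_dataset(cfg), generate_dataset(cfg)
        for name in ("train", "val", "test", "pool"):
            sa, sb = a.split(name), b.split(name)
            assert np.array_equal(sa.pixels, sb.pixels)
            assert np.array_equal(sa.subject_ids, sb.subject_ids)

    def test_subjects_never_straddle_splits(self):
        ds = generate_dataset(DatasetConfig(images_per_class=20, side=32,
                                            images_per_subject=2, seed=1))
        seen: dict[str, str] = {}
        for name, s in ds.splits.items():
            for sid in s.subject_ids:
                assert seen.setdefault(sid, name) == name
        # multi-image subjects really have 2 images in one split
        counts = {}
        for s in ds.splits.values():
            for sid in s.subject_ids:
                counts[sid] = counts.get(sid, 0) + 1
        assert set(counts.values()) == {2}

    def test_roles_by_split(self):
        ds = generate_dataset(DatasetConfig(images_per_class=12, side=32, seed=2))
        assert set(ds.train.roles) == {"inlier"}
        assert set(ds.val.roles) == {"inlier"}
        assert set(ds.pool.roles) == {"nearOOD"}
        assert {"inlier", "nearOOD", "farOOD"} <= set(ds.test.roles)

    def test_counts_too_small_for_fractions_raise(self):
        with pytest.raises(ValueError, match="too few"):
            generate_dataset(DatasetConfig(images_per_class=3, side=32, seed=0))

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            DatasetConfig(split_fractions=(0.5, 0.2, 0.2)).validate()
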