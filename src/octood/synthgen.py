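"""Synthetic retinal-cross-section image generator.

The study this package supports needs a dataset with a very specific
*similarity geometry* rather than anatomical realism: four inlier classes
(normal, iAMD-analog with drusen-like bumps, nAMD-analog with fluid-like
dark blobs plus bumps, GA-analog with an atrophy-like thinned/brightened
region), three near-OOD classes that echo inlier features (DME- and
RVO-analogs carry fluid blobs like the nAMD-analog; the Stargardt-analog
carries atrophy like the GA-analog but no bumps), and one far-OOD class
with a texturally disjoint radial pattern standing in for a different
imaging modality.

All images are single-channel with intensities in [0, 1]. Every image
belongs to a subject; subjects — not images — are assigned to splits, so
no subject ever straddles a split boundary. Generation is a pure function
of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "INLIER_CLASSES",
    "NEAR_OOD_CLASSES",
    "FAR_OOD_CLASS",
    "ALL_CLASSES",
    "LABEL_ROLE",
    "DatasetConfig",
    "SyntheticImage",
    "ImageSet",
    "SplitDataset",
    "render_image",
    "generate_dataset",
]

# Fixed label -> role taxonomy (4 inlier, 3 near-OOD, 1 far-OOD).
INLIER_CLASSES: tuple[str, ...] = ("normal", "iAMD", "nAMD", "GA")
NEAR_OOD_CLASSES: tuple[str, ...] = ("DME", "RVO", "Stargardt")
FAR_OOD_CLASS: str = "farOOD"
ALL_CLASSES: tuple[str, ...] = INLIER_CLASSES + NEAR_OOD_CLASSES + (FAR_OOD_CLASS,)

LABEL_ROLE: dict[str, str] = {
    **{c: "inlier" for c in INLIER_CLASSES},
    **{c: "nearOOD" for c in NEAR_OOD_CLASSES},
    FAR_OOD_CLASS: "farOOD",
}


@dataclass
class DatasetConfig:
    """Knobs of the generator.

    ``images_per_class`` counts *subjects* per class (each subject
    contributes ``images_per_subject`` images). Inlier subjects are split
    patient-wise into train/val/test by ``split_fractions``; near-OOD
    subjects are split into an exposure pool (available for few-shot
    outlier exposure and validation-time OOD tuning) and a held-out test
    portion; far-OOD subjects all go to test.
    """

    images_per_class: int = 200
    images_per_subject: int = 1
    side: int = 64
    layer_contrast: float = 0.40
    drusen_amplitude: float = 1.0
    fluid_blob_scale: float = 1.0
    atrophy_depth: float = 0.55
    noise_sigma: float = 0.03
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    exposure_pool_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.images_per_class < 0 or self.images_per_subject < 1:
            raise ValueError("image counts must be non-negative (>=1 per subject)")
        if self.side < 16:
            raise ValueError("side must be >= 16")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError(
                f"split fractions must sum to 1, got {self.split_fractions}"
            )
        if any(f < 0 for f in self.split_fractions):
            raise ValueError("split fractions must be non-negative")
        if not 0.0 <= self.exposure_pool_fraction <= 1.0:
            raise ValueError("exposure_pool_fraction must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["split_fractions"] = list(self.split_fractions)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "DatasetConfig":
        d = dict(d)
        if "split_fractions" in d:
            d["split_fractions"] = tuple(d["split_fractions"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class SyntheticImage:
    pixels: np.ndarray  # (side, side) float64 in [0, 1]
    label: str
    role: str
    subject_id: str


# ----------------------------------------------------------------------
# rendering primitives
# ----------------------------------------------------------------------


def _scale(cfg: DatasetConfig) -> float:
    return cfg.side / 64.0


def _band_background(rng: np.random.Generator, cfg: DatasetConfig):
    """Layered-band background shared by every retinal-analog class.

    Returns (image, top, bot): per-column top/bottom row of the tissue
    band, which the class-specific operators deform.
    """
    s = cfg.side
    k = _scale(cfg)
    img = np.full((s, s), 0.06)
    top0 = s * 0.30 + rng.uniform(-2, 2) * k
    thickness = s * 0.38 + rng.uniform(-3, 3) * k
    amp = rng.uniform(1.0, 3.0) * k
    freq = rng.uniform(0.8, 1.6)
    phase = rng.uniform(0, 2 * np.pi)

    x = np.arange(s)
    top = top0 + amp * np.sin(2 * np.pi * freq * x / s + phase)
    bot = top + thickness

    yy = np.arange(s)[:, None].astype(float)
    tissue = (yy >= top) & (yy < bot)
    base = 0.06 + cfg.layer_contrast * rng.uniform(0.95, 1.05)
    # mild inner->outer gradient inside the band
    depth = np.clip((yy - top) / np.maximum(thickness, 1.0), 0, 1)
    img = np.where(tissue, base + 0.06 * depth, img)
    # bright inner surface line
    ilm = (yy >= top) & (yy < top + 1.5 * k)
    img = np.where(ilm, base + 0.18, img)
    # bright outer band (pigment-epithelium analog)
    rpe = (yy >= bot - 3.0 * k) & (yy < bot)
    img = np.where(rpe, 0.85 + rng.uniform(-0.02, 0.02), img)
    return img, top, bot


def _add_bumps(img, top, bot, rng, cfg, n_range=(2, 4)):
    """Bright dome-shaped bumps riding on the outer band (drusen analog)."""
    s = cfg.side
    k = _scale(cfg)
    yy = np.arange(s)[:, None].astype(float)
    n = rng.integers(n_range[0], n_range[1] + 1)
    for _ in range(n):
        cx = rng.uniform(0.1 * s, 0.9 * s)
        w = rng.uniform(3.0, 6.0) * k
        h = cfg.drusen_amplitude * rng.uniform(3.0, 5.5) * k
        x = np.arange(s)
        rel = (x - cx) / w
        dome = np.where(np.abs(rel) < 1, h * np.sqrt(np.clip(1 - rel**2, 0, 1)), 0.0)
        lifted = (yy >= bot - 3.0 * k - dome) & (yy < bot) & (dome > 0)
        img = np.where(lifted, 0.85, img)
    return img


def _add_blobs(img, top, bot, rng, cfg, n_range, rx_range, ry_range):
    """Dark elliptic blobs inside the band (intra/subretinal fluid analog)."""
    s = cfg.side
    k = _scale(cfg)
    yy = np.arange(s)[:, None].astype(float)
    xx = np.arange(s)[None, :].astype(float)
    lo, hi = n_range
    n = rng.integers(lo, hi + 1)
    thickness = np.mean(bot - top)
    for _ in range(n):
        cx = rng.uniform(0.12 * s, 0.88 * s)
        cyrel = rng.uniform(0.30, 0.75)
        cy = np.interp(cx, np.arange(s), top) + cyrel * thickness
        rx = rng.uniform(*rx_range) * k * cfg.fluid_blob_scale
        ry = rng.uniform(*ry_range) * k * cfg.fluid_blob_scale
        d2 = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2
        soft = np.clip(1.0 - d2, 0, 1)  # quadratic soft edge
        img = img - 0.75 * (img - 0.10) * soft
    return img


def _add_atrophy(img, top, bot, rng, cfg, depth_mult=1.0, width_range=(0.25, 0.45)):
    """Thin the band over an interval and brighten beneath it
    (atrophy with increased light penetration)."""
    s = cfg.side
    k = _scale(cfg)
    yy = np.arange(s)[:, None].astype(float)
    x = np.arange(s)
    wid = rng.uniform(*width_range) * s
    x0 = rng.uniform(0.05 * s, 0.95 * s - wid)
    rel = (x - (x0 + wid / 2)) / (wid / 2)
    profile = np.clip(1 - rel**2, 0, 1)  # smooth-edged region weight
    depth = cfg.atrophy_depth * depth_mult
    thickness = bot - top
    new_top = top + depth * thickness * profile
    # erase the vacated inner tissue back to background
    vacated = (yy >= top) & (yy < new_top)
    img = np.where(vacated, 0.06, img)
    # hyper-transmission below the outer band inside the region
    below = (yy >= bot) & (yy < bot + 6.0 * k) & (profile[None, :] > 0.3)
    img = np.where(below, img + 0.30 * profile[None, :], img)
    return img


def _far_ood_texture(rng: np.random.Generator, cfg: DatasetConfig):
    """Radial disc-and-vessel pattern with no horizontal band structure."""
    s = cfg.side
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    cy = s * rng.uniform(0.40, 0.60)
    cx = s * rng.uniform(0.40, 0.60)
    r = np.hypot(yy - cy, xx - cx)
    theta = np.arctan2(yy - cy, xx - cx)
    img = np.full((s, s), 0.50)
    img -= 0.35 * np.clip(r / (0.75 * s) - 0.55, 0, 1)  # vignette
    # bright disc offset from the centre
    dy = s * 0.18 * rng.uniform(0.6, 1.2) * rng.choice([-1, 1])
    dx = s * 0.18 * rng.uniform(0.6, 1.2) * rng.choice([-1, 1])
    rd = np.hypot(yy - (cy + dy), xx - (cx + dx))
    img += 0.38 * np.clip(1 - rd / (0.11 * s), 0, 1)
    # dark radial vessel streaks
    nves = rng.integers(5, 9)
    phase = rng.uniform(0, 2 * np.pi)
    streak = np.maximum(0, np.sin(nves * theta + phase)) ** 12
    img -= 0.22 * streak * np.clip(r / (0.2 * s), 0, 1)
    return np.clip(img, 0.02, 0.95)


def render_image(
    label: str, rng: np.random.Generator, config: DatasetConfig | None = None
) -> SyntheticImage:
    """Render one image of class ``label`` using ``rng``.

    The draw order inside each class branch is fixed, so an identical rng
    state reproduces the image bit for bit.
    """
    cfg = config or DatasetConfig()
    cfg.validate()
    if label not in ALL_CLASSES:
        raise ValueError(f"unknown label {label!r}; expected one of {ALL_CLASSES}")

    if label == FAR_OOD_CLASS:
        img = _far_ood_texture(rng, cfg)
    else:
        img, top, bot = _band_background(rng, cfg)
        if label == "normal":
            pass
        elif label == "iAMD":
            img = _add_bumps(img, top, bot, rng, cfg, n_range=(4, 7))
        elif label == "nAMD":
            img = _add_blobs(img, top, bot, rng, cfg,
                             n_range=(2, 3), rx_range=(5.0, 9.0), ry_range=(3.5, 6.0))
            img = _add_bumps(img, top, bot, rng, cfg, n_range=(1, 3))
        elif label == "GA":
            img = _add_atrophy(img, top, bot, rng, cfg)
            img = _add_bumps(img, top, bot, rng, cfg, n_range=(1, 3))
        elif label == "DME":
            img = _add_blobs(img, top, bot, rng, cfg,
                             n_range=(2, 4), rx_range=(2.5, 4.5), ry_range=(2.5, 4.5))
        elif label == "RVO":
            img = _add_blobs(img, top, bot, rng, cfg,
                             n_range=(3, 5), rx_range=(4.0, 7.0), ry_range=(1.5, 2.5))
        elif label == "Stargardt":
            img = _add_atrophy(img, top, bot, rng, cfg,
                               depth_mult=0.85, width_range=(0.35, 0.55))

    if cfg.noise_sigma > 0:
        img = img + rng.normal(0.0, cfg.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return SyntheticImage(pixels=img, label=label, role=LABEL_ROLE[label],
                          subject_id="")


# ----------------------------------------------------------------------
# dataset containers and patient-wise splitting
# ----------------------------------------------------------------------


@dataclass
class ImageSet:
    """Column-oriented batch of images with aligned metadata arrays."""

    pixels: np.ndarray        # (n, side, side)
    labels: np.ndarray        # (n,) str
    roles: np.ndarray         # (n,) str
    subject_ids: np.ndarray   # (n,) str

    def __len__(self) -> int:
        return len(self.labels)

    def select(self, mask: np.ndarray) -> "ImageSet":
        return ImageSet(self.pixels[mask], self.labels[mask],
                        self.roles[mask], self.subject_ids[mask])

    def by_label(self, label: str) -> "ImageSet":
        return self.select(self.labels == label)

    def by_role(self, role: str) -> "ImageSet":
        return self.select(self.roles == role)

    @staticmethod
    def concatenate(sets: Iterable["ImageSet"]) -> "ImageSet":
        sets = [s for s in sets if len(s)]
        return ImageSet(
            np.concatenate([s.pixels for s in sets]),
            np.concatenate([s.labels for s in sets]),
            np.concatenate([s.roles for s in sets]),
            np.concatenate([s.subject_ids for s in sets]),
        )

    @staticmethod
    def empty(side: int) -> "ImageSet":
        z = np.empty((0,), dtype=object)
        return ImageSet(np.empty((0, side, side)), z.copy(), z.copy(), z.copy())

    def to_manifest(self) -> pd.DataFrame:
        return pd.DataFrame({
            "label": self.labels, "role": self.roles,
            "subject_id": self.subject_ids,
        })


@dataclass
class SplitDataset:
    """Patient-wise split dataset.

    ``train``/``val``/``test`` follow the usual meaning; ``pool`` holds
    near-OOD subjects reserved for few-shot outlier exposure and
    validation-time OOD hyperparameter tuning, strictly disjoint from the
    near-OOD part of ``test``.
    """

    train: ImageSet
    val: ImageSet
    test: ImageSet
    pool: ImageSet
    config: DatasetConfig = field(default_factory=DatasetConfig)

    def split(self, name: str) -> ImageSet:
        return getattr(self, name)

    @property
    def splits(self) -> dict[str, ImageSet]:
        return {"train": self.train, "val": self.val,
                "test": self.test, "pool": self.pool}

    def manifest(self) -> pd.DataFrame:
        frames = []
        for name, s in self.splits.items():
            df = s.to_manifest()
            df.insert(0, "split", name)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _split_counts(n: int, fractions: tuple[float, ...]) -> list[int]:
    counts = [int(round(f * n)) for f in fractions[:-1]]
    counts.append(n - sum(counts))
    for f, c in zip(fractions, counts):
        if f > 0 and c < 1:
            raise ValueError(
                f"{n} subjects are too few to honor split fractions {fractions}"
            )
        if c < 0:
            raise ValueError(
                f"rounded split counts {counts} invalid for fractions {fractions}"
            )
    return counts


def generate_dataset(config: DatasetConfig | None = None) -> SplitDataset:
    """Generate the full patient-wise-split dataset.

    Inlier subjects -> train/val/test; near-OOD subjects -> exposure pool
    + test; far-OOD subjects -> test only. Deterministic in
    ``config.seed``.
    """
    cfg = config or DatasetConfig()
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    # one child sequence per class keeps classes independent of each other
    class_seqs = dict(zip(ALL_CLASSES, root.spawn(len(ALL_CLASSES))))

    parts: dict[str, list[ImageSet]] = {k: [] for k in ("train", "val", "test", "pool")}

    for label in ALL_CLASSES:
        n_subj = cfg.images_per_class
        if n_subj == 0:
            continue
        seq = class_seqs[label]
        split_rng = np.random.default_rng(seq.spawn(1)[0])
        subj_seqs = seq.spawn(n_subj)

        # patient-wise split assignment
        order = split_rng.permutation(n_subj)
        if label in INLIER_CLASSES:
            counts = _split_counts(n_subj, cfg.split_fractions)
            names = ["train", "val", "test"]
        elif label in NEAR_OOD_CLASSES:
            n_pool = int(round(cfg.exposure_pool_fraction * n_subj))
            counts = [n_pool, n_subj - n_pool]
            names = ["pool", "test"]
        else:
            counts = [n_subj]
            names = ["test"]

        assign = np.empty(n_subj, dtype=object)
        start = 0
        for name, c in zip(names, counts):
            assign[order[start:start + c]] = name
            start += c

        for split_name in names:
            idx = [i for i in range(n_subj) if assign[i] == split_name]
            if not idx:
                continue
            imgs, labels, roles, sids = [], [], [], []
            for i in idx:
                sid = f"{label}-s{i:04d}"
                subj_rng = np.random.default_rng(subj_seqs[i])
                for _ in range(cfg.images_per_subject):
                    im = render_image(label, subj_rng, cfg)
                    imgs.append(im.pixels)
                    labels.append(label)
                    roles.append(LABEL_ROLE[label])
                    sids.append(sid)
            parts[split_name].append(ImageSet(
                np.stack(imgs), np.array(labels, dtype=object),
                np.array(roles, dtype=object), np.array(sids, dtype=object)))

    made = {k: (ImageSet.concatenate(v) if v else ImageSet.empty(cfg.side))
            for k, v in parts.items()}
    return SplitDataset(config=cfg, **made)
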