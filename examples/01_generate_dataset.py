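"""Generate a small synthetic dataset and inspect its structure.

The generator emulates a retinal cross-section classification problem:
four inlier classes (normal, iAMD, nAMD, GA analogs), three near-OOD
disease analogs (DME, RVO, Stargardt) that share visual features with
specific inliers, and one texturally disjoint far-OOD class. Subjects,
not images, are assigned to splits.
"""

from collections import Counter

from octood import DatasetConfig, generate_dataset

ds = generate_dataset(DatasetConfig(images_per_class=40, seed=0))

for name, part in ds.splits.items():
    counts = Counter(part.labels)
    print(f"{name:5s}  {len(part):4d} images  {dict(sorted(counts.items()))}")

print("\nEach line shows a split and its per-class image counts: inliers "
      "are split 70/15/15 across train/val/test, near-OOD classes are "
      "split between the exposure pool and the test set, and the far-OOD "
      "class appears only at test time.")
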