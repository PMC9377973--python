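"""Synthetic imbalanced datasets with controllable class counts and overlap.

Features are drawn from isotropic Gaussians, one per class, so that class
imbalance (the per-class counts) and sample difficulty (the overlap between
class clouds, set by ``spread``) can be controlled independently — the two
axes the double-balanced loss addresses.  The default imbalance profile
mirrors the class tallies of the white-light colonoscopy lesion collection
that motivates the method: 1709 images in three classes
(adenoma 1048, polyp 381, cancer 280), split 8:2 into 1367 training and 342
test images with per-class training counts {adenoma 838, cancer 224,
polyp 305}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .balance import ClassCounts

__all__ = [
    "DatasetSpec",
    "LabeledDataset",
    "generate",
    "default_centers",
    "colonoscopy_train_profile",
    "colonoscopy_collection_profile",
    "split_8_2",
]

# Per-class image tallies of the colonoscopy lesion collection (full set and
# its 8:2 training split).  Order fixes the integer label encoding.
_COLLECTION = {"adenoma": 1048, "cancer": 280, "polyp": 381}
_TRAIN = {"adenoma": 838, "cancer": 224, "polyp": 305}


def colonoscopy_train_profile() -> ClassCounts:
    """Training-split class counts {adenoma 838, cancer 224, polyp 305}."""
    return ClassCounts.from_mapping(_TRAIN)


def colonoscopy_collection_profile() -> ClassCounts:
    """Full-collection class counts {adenoma 1048, cancer 280, polyp 381}."""
    return ClassCounts.from_mapping(_COLLECTION)


def default_centers(k: int, dim: int, separation: float = 2.0) -> np.ndarray:
    """k class centers evenly spaced on a circle of radius ``separation``.

    The circle lives in the first two feature dimensions (the first one if
    dim == 1); remaining coordinates are zero.
    """
    if dim < 1:
        raise ValueError("dim must be at least 1")
    centers = np.zeros((k, dim))
    angles = 2.0 * np.pi * np.arange(k) / k
    centers[:, 0] = separation * np.cos(angles)
    if dim > 1:
        centers[:, 1] = separation * np.sin(angles)
    return centers


@dataclass(frozen=True)
class DatasetSpec:
    """Recipe for one synthetic dataset.

    ``spread`` is the isotropic standard deviation of every class cloud and
    is the difficulty dial: with centers 2 units from the origin the default
    1.5 gives moderate overlap (pairwise Bayes error about 0.12 for
    neighbouring classes), so a linear classifier is well off ceiling and
    imbalance effects are visible.
    """

    counts: ClassCounts
    dim: int = 2
    spread: float = 1.5
    separation: float = 2.0
    class_centers: np.ndarray | None = field(default=None, repr=False)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be positive")
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        centers = self.class_centers
        if centers is None:
            centers = default_centers(self.counts.k, self.dim, self.separation)
        centers = np.asarray(centers, dtype=float)
        if centers.shape != (self.counts.k, self.dim):
            raise ValueError(
                f"class_centers must have shape ({self.counts.k}, {self.dim})"
            )
        if self.counts.k > 1:
            d = centers[:, None, :] - centers[None, :, :]
            off = ~np.eye(self.counts.k, dtype=bool)
            if np.min(np.linalg.norm(d, axis=-1)[off]) == 0:
                raise ValueError("class centers must be distinct")
        object.__setattr__(self, "class_centers", centers)

    @property
    def k(self) -> int:
        return self.counts.k

    @property
    def n(self) -> int:
        return self.counts.total


@dataclass(frozen=True)
class LabeledDataset:
    features: np.ndarray
    labels: np.ndarray
    spec: DatasetSpec

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    def class_tallies(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.spec.k)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.features, columns=[f"x{i}" for i in range(self.features.shape[1])]
        )
        df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def generate(spec: DatasetSpec) -> LabeledDataset:
    """Draw the dataset described by ``spec``; exact tallies, seeded.

    Class ``i`` is an isotropic Gaussian at ``class_centers[i]`` with scale
    ``spread``.  Rows are shuffled so class blocks do not survive into
    mini-batches.
    """
    rng = np.random.default_rng(spec.seed)
    parts_x, parts_y = [], []
    for i, n_i in enumerate(spec.counts.counts):
        parts_x.append(
            rng.normal(loc=spec.class_centers[i], scale=spec.spread, size=(n_i, spec.dim))
        )
        parts_y.append(np.full(n_i, i, dtype=int))
    X = np.concatenate(parts_x)
    y = np.concatenate(parts_y)
    order = rng.permutation(X.shape[0])
    return LabeledDataset(X[order], y[order], spec)


def split_8_2(ds: LabeledDataset, seed: int = 0) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified 8:2 split with per-class train size ``round(0.8 * n_i)``.

    Rounding to the nearest integer (half away from zero) is what makes the
    colonoscopy bookkeeping recombine exactly: 0.8 * 381 = 304.8 -> 305
    polyps in training, giving the 1367/342 totals.
    """
    if ds.n < 5:
        raise ValueError("need at least 5 samples for an 8:2 split")
    tallies = ds.class_tallies()
    if np.any(tallies < 2):
        raise ValueError("every class needs at least 2 samples to stratify")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for i in range(ds.spec.k):
        idx = np.flatnonzero(ds.labels == i)
        idx = rng.permutation(idx)
        n_train = int(np.floor(0.8 * idx.size + 0.5))
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.sort(np.concatenate(test_idx))

    def _subset(idx: np.ndarray) -> LabeledDataset:
        sub_counts = ClassCounts(
            ds.spec.counts.labels,
            tuple(int(c) for c in np.bincount(ds.labels[idx], minlength=ds.spec.k)),
        )
        sub_spec = DatasetSpec(
            counts=sub_counts,
            dim=ds.spec.dim,
            spread=ds.spec.spread,
            separation=ds.spec.separation,
            class_centers=ds.spec.class_centers,
            seed=ds.spec.seed,
        )
        return LabeledDataset(ds.features[idx], ds.labels[idx], sub_spec)

    return _subset(train_idx), _subset(test_idx)
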