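"""Synthetic data with planted ground truth.

Every stage of the pipeline is testable offline through three generators:

* :func:`make_feature_table` — a labeled table with three kinds of columns:
  *informative* features whose class-conditional means are separated by a
  controllable effect size, *redundant* features that are noisy copies of
  informative ones, and pure standard-normal *noise* features.  The returned
  ground truth says exactly which columns carry signal, so relevance-ranking
  and subset-recovery claims can be checked, not eyeballed.
* :func:`make_images` — small labeled images with class-dependent structure
  (horizontal gratings, vertical gratings, a centered Gaussian blob) plus
  additive pixel noise, standing in for radiographic inputs.
* :func:`make_confusion_fixture` — label/prediction pairs with a known
  corruption rate for exercising the metric suite.

All generators are pure functions of their spec: the seed is part of the
spec, and identical specs give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from PIL import Image

from .image_prep import ImageRecord
from .table import CategoricalSeries, FeatureTable

__all__ = [
    "SyntheticTableSpec",
    "SyntheticImageSpec",
    "GroundTruth",
    "make_feature_table",
    "make_images",
    "make_confusion_fixture",
    "write_images",
]


@dataclass
class SyntheticTableSpec:
    """Planted-table parameters.

    ``effect_size`` (delta) is the separation between adjacent class means of
    an informative feature, in units of the within-class noise SD ``noise_sd``
    (sigma).  Defaults give a 3-class, 60-feature table with 8 informative
    and 4 redundant columns at delta = 1.5 — small enough for minute-scale
    tests, hard enough that selection matters.
    """

    n_samples: int = 300
    n_features: int = 60
    n_informative: int = 8
    n_redundant: int = 4
    n_classes: int = 3
    effect_size: float = 1.5
    noise_sd: float = 1.0
    redundancy_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative + self.n_redundant > self.n_features:
            raise ValueError("informative + redundant features exceed n_features")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd <= 0 or self.redundancy_noise_sd < 0:
            raise ValueError("noise SDs must be positive (redundancy SD may be 0)")
        if self.n_samples < self.n_classes:
            raise ValueError("need at least one sample per class")


@dataclass
class SyntheticImageSpec:
    """Planted-image parameters; intensities are on the 8-bit [0, 255] scale."""

    n_per_class: int = 10
    height: int = 64
    width: int = 64
    n_classes: int = 3
    pattern: Literal["gratings", "blobs"] = "gratings"
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError("image dimensions must be at least 8")
        if self.n_per_class < 4:
            raise ValueError("need at least 4 images per class")
        if self.n_classes not in (2, 3):
            raise ValueError("image generator supports 2 or 3 classes")
        if self.pattern not in ("gratings", "blobs"):
            raise ValueError(f"unknown pattern: {self.pattern!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """Which columns of a planted table carry signal."""

    informative: list[int]
    redundant: list[int]
    noise: list[int]
    redundant_sources: dict[int, int]

    def signal_features(self) -> list[int]:
        return sorted(self.informative + self.redundant)


def make_feature_table(spec: SyntheticTableSpec) -> tuple[FeatureTable, GroundTruth]:
    """Generate the planted table and its ground-truth column lists.

    Class sizes are balanced (remainders go to the lowest-indexed classes).
    Informative feature j places class c's mean at
    ``effect_size * noise_sd * perm_j(c) - centered``, where ``perm_j`` is a
    per-feature random permutation of class ranks — every informative feature
    separates the classes by the same effect size but along its own class
    ordering, so no two are simple copies.  Redundant features add
    ``N(0, redundancy_noise_sd)`` to a cyclically chosen informative column.
    """
    rng = np.random.default_rng(spec.seed)
    n, f, c = spec.n_samples, spec.n_features, spec.n_classes

    base = n // c
    sizes = [base + (1 if i < n % c else 0) for i in range(c)]
    labels = np.concatenate([np.full(sz, i, dtype=np.int64) for i, sz in enumerate(sizes)])

    informative = list(range(spec.n_informative))
    redundant = list(range(spec.n_informative, spec.n_informative + spec.n_redundant))
    noise = list(range(spec.n_informative + spec.n_redundant, f))

    X = np.empty((n, f))
    offsets = (np.arange(c) - (c - 1) / 2.0) * spec.effect_size * spec.noise_sd
    for j in informative:
        class_means = offsets[rng.permutation(c)]
        X[:, j] = class_means[labels] + rng.normal(0.0, spec.noise_sd, size=n)
    sources: dict[int, int] = {}
    for idx, j in enumerate(redundant):
        src = informative[idx % len(informative)]
        sources[j] = src
        X[:, j] = X[:, src] + rng.normal(0.0, spec.redundancy_noise_sd, size=n)
    for j in noise:
        X[:, j] = rng.normal(0.0, 1.0, size=n)

    table = FeatureTable(
        X=X,
        y=CategoricalSeries(labels, c),
        feature_ids=[f"f{j}" for j in range(f)],
        class_names=[f"class{i}" for i in range(c)],
    )
    return table, GroundTruth(informative, redundant, noise, sources)


_CLASS_LABELS = ("grating_h", "grating_v", "blob")


def _base_pattern(spec: SyntheticImageSpec, class_idx: int) -> np.ndarray:
    h, w = spec.height, spec.width
    rows = np.arange(h)[:, None] * np.ones((1, w))
    cols = np.ones((h, 1)) * np.arange(w)[None, :]
    period = 8.0
    if class_idx == 0:  # horizontal stripes
        base = np.sin(2 * np.pi * rows / period)
    elif class_idx == 1:  # vertical stripes
        base = np.sin(2 * np.pi * cols / period)
    else:  # centered Gaussian blob
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        sigma = min(h, w) / 4.0
        base = 2.0 * np.exp(-(((rows - cy) ** 2) + ((cols - cx) ** 2)) / (2 * sigma**2)) - 1.0
    return 127.5 + 100.0 * base  # map [-1, 1] into [27.5, 227.5]


def make_images(spec: SyntheticImageSpec) -> list[ImageRecord]:
    """Class-dependent base pattern plus independent Gaussian pixel noise.

    With ``noise_sd=0`` all images of a class are identical.  Intensities are
    clipped to [0, 255] and stored as uint8.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ImageRecord] = []
    for ci in range(spec.n_classes):
        base = _base_pattern(spec, ci)
        label = _CLASS_LABELS[ci]
        for i in range(spec.n_per_class):
            noisy = base + rng.normal(0.0, spec.noise_sd, size=base.shape)
            pixels = np.clip(np.round(noisy), 0, 255).astype(np.uint8)
            records.append(ImageRecord(pixels=pixels, label=label, id=f"{label}/{i:03d}.png"))
    return records


def write_images(records: list[ImageRecord], out_dir: str | Path) -> None:
    """Write records as PNG files in class-named subdirectories."""
    root = Path(out_dir)
    for rec in records:
        path = root / rec.id
        path.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(np.asarray(rec.pixels, dtype=np.uint8)).save(path)


def make_confusion_fixture(
    n_classes: int, n: int, error_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced labels with predictions corrupted at a known rate.

    Each prediction is independently flipped with probability ``error_rate``
    to a uniformly chosen *wrong* class, so the expected accuracy is exactly
    ``1 - error_rate``.
    """
    if not 0 <= error_rate <= 1:
        raise ValueError("error_rate must lie in [0, 1]")
    base = n // n_classes
    sizes = [base + (1 if i < n % n_classes else 0) for i in range(n_classes)]
    y_true = np.concatenate([np.full(sz, i, dtype=np.int64) for i, sz in enumerate(sizes)])
    y_pred = y_true.copy()
    flip = rng.random(n) < error_rate
    for i in np.nonzero(flip)[0]:
        wrong = [c for c in range(n_classes) if c != y_true[i]]
        y_pred[i] = wrong[rng.integers(len(wrong))]
    return y_true, y_pred
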