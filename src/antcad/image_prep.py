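"""Image loading and pre-processing ahead of feature extraction.

The auto-encoder path converts images to grayscale (ITU-R BT.601 luma),
resizes them to 64 x 64 with bilinear interpolation (anti-aliased when
shrinking), flattens row-major to a 4096-vector, and scales intensities to
[0, 1].  The CNN-adapter path resizes RGB images to the input resolution a
registered backbone expects (227 for the AlexNet-style profile, 224 for the
others) and delegates feature extraction to the registered callable —
pre-trained weights are never bundled; only the width contract is enforced
(alexnet 4096, googlenet 1000, resnet50 2048, densenet201 1920).

Train/test partitioning is stratified per class at a configurable fraction
(default 80-20) with either floor or nearest rounding of the train count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
from PIL import Image
from skimage.transform import resize as _skimage_resize

from .table import CategoricalSeries, FeatureTable

__all__ = [
    "ImageRecord",
    "PrepConfig",
    "load_image_dir",
    "to_grayscale",
    "resize_image",
    "vectorize",
    "normalize_pixels",
    "stratified_split",
    "records_to_table",
    "register_backbone",
    "cnn_feature_adapter",
    "KNOWN_BACKBONE_DIMS",
]

logger = logging.getLogger(__name__)

GRAY_WEIGHTS = (0.299, 0.587, 0.114)  # ITU-R BT.601 luma
IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}

#: Feature widths of the supported pre-trained backbones (contract only).
KNOWN_BACKBONE_DIMS = {
    "alexnet": 4096,
    "googlenet": 1000,
    "resnet50": 2048,
    "densenet201": 1920,
}

TARGET_SHAPES = {
    "ae_gray_64": (64, 64),
    "cnn_rgb_227": (227, 227),
    "cnn_rgb_224": (224, 224),
}


@dataclass
class ImageRecord:
    """One image with its class label and identifier."""

    pixels: np.ndarray
    label: str
    id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be H x W or H x W x 3")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image dimensions must be positive")
        if not np.all(np.isfinite(np.asarray(self.pixels, dtype=float))):
            raise ValueError("pixel intensities must be finite")


@dataclass
class PrepConfig:
    """Pre-processing and split settings.

    ``split_rounding`` selects how the per-class train count is rounded from
    ``train_fraction * n_class``: ``floor_train`` or ``nearest_train``.
    """

    target: Literal["ae_gray_64", "cnn_rgb_227", "cnn_rgb_224"] = "ae_gray_64"
    normalize: bool = True
    train_fraction: float = 0.8
    split_rounding: Literal["floor_train", "nearest_train"] = "nearest_train"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target not in TARGET_SHAPES:
            raise ValueError(f"unknown prep target: {self.target!r}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie strictly in (0, 1)")
        if self.split_rounding not in ("floor_train", "nearest_train"):
            raise ValueError(f"unknown split_rounding: {self.split_rounding!r}")


def load_image_dir(path: str | Path) -> list[ImageRecord]:
    """Read class-named subdirectories of PNG/JPEG files.

    Records come back in deterministic lexicographic (class, filename) order,
    labeled by subdirectory name.  Unreadable files are skipped with a logged
    warning; an entirely empty dataset is an error.
    """
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"{root} is not a directory")
    records: list[ImageRecord] = []
    for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for file in sorted(class_dir.iterdir()):
            if file.suffix.lower() not in IMAGE_SUFFIXES:
                continue
            try:
                with Image.open(file) as im:
                    pixels = np.asarray(im.convert("RGB") if im.mode not in ("L", "RGB") else im)
            except Exception as exc:  # corrupt or truncated file
                logger.warning("skipping unreadable image %s: %s", file, exc)
                continue
            records.append(
                ImageRecord(pixels=pixels, label=class_dir.name, id=f"{class_dir.name}/{file.name}")
            )
    if not records:
        raise ValueError(f"no readable images found under {root}")
    return records


def to_grayscale(record: ImageRecord) -> ImageRecord:
    """BT.601 luma conversion 0.299 R + 0.587 G + 0.114 B.

    Integer inputs are rounded back to integers (e.g. pure red 255 maps to
    luma 76.245 and stores as 76); an already-grayscale record passes
    through unchanged.
    """
    if record.pixels.ndim == 2:
        return record
    rgb = np.asarray(record.pixels, dtype=float)
    gray = rgb[..., 0] * GRAY_WEIGHTS[0] + rgb[..., 1] * GRAY_WEIGHTS[1] + rgb[..., 2] * GRAY_WEIGHTS[2]
    if np.issubdtype(record.pixels.dtype, np.integer):
        gray = np.round(gray).astype(record.pixels.dtype)
    return ImageRecord(pixels=gray, label=record.label, id=record.id)


def resize_image(record: ImageRecord, height: int, width: int) -> ImageRecord:
    """Bilinear resize to exactly ``height x width``, anti-aliased on downscale."""
    if height < 1 or width < 1:
        raise ValueError("target dimensions must be positive")
    pixels = np.asarray(record.pixels, dtype=float)
    shape = (height, width) if pixels.ndim == 2 else (height, width, pixels.shape[2])
    shrinking = height < pixels.shape[0] or width < pixels.shape[1]
    out = _skimage_resize(
        pixels, shape, order=1, mode="edge", anti_aliasing=shrinking, preserve_range=True
    )
    return ImageRecord(pixels=out, label=record.label, id=record.id)


def vectorize(record: ImageRecord) -> np.ndarray:
    """Row-major flattening of a single-channel image to a length H*W vector."""
    if record.pixels.ndim != 2:
        raise ValueError("vectorize requires a single-channel image")
    return np.asarray(record.pixels, dtype=float).reshape(-1)


def normalize_pixels(values: np.ndarray) -> np.ndarray:
    """Map 8-bit intensities [0, 255] onto [0, 1]."""
    return np.asarray(values, dtype=float) / 255.0


def records_to_table(
    records: Sequence[ImageRecord],
    config: PrepConfig,
    classes: Sequence[str] | None = None,
) -> FeatureTable:
    """Apply the full pre-processing chain and assemble a labeled table.

    For the auto-encoder target: grayscale -> resize -> vectorize
    (-> normalize).  Class names map to integer codes in sorted label order;
    pass ``classes`` explicitly to share one encoding across several subsets
    (e.g. train and test partitions).
    """
    if not records:
        raise ValueError("no records to process")
    h, w = TARGET_SHAPES[config.target]
    rows = []
    for rec in records:
        if config.target == "ae_gray_64":
            rec = resize_image(to_grayscale(rec), h, w)
            vec = vectorize(rec)
        else:
            rec = resize_image(rec, h, w)
            vec = np.asarray(rec.pixels, dtype=float).reshape(-1)
        rows.append(normalize_pixels(vec) if config.normalize else vec)
    X = np.vstack(rows)
    if classes is None:
        classes = sorted({r.label for r in records})
    else:
        classes = list(classes)
        missing = {r.label for r in records} - set(classes)
        if missing:
            raise ValueError(f"records carry labels outside the class list: {sorted(missing)}")
    lookup = {c: i for i, c in enumerate(classes)}
    y = CategoricalSeries(np.array([lookup[r.label] for r in records]), len(classes))
    return FeatureTable(
        X=X,
        y=y,
        feature_ids=[f"p{j}" for j in range(X.shape[1])],
        sample_ids=[r.id for r in records],
        class_names=classes,
    )


def _train_count(n_class: int, config: PrepConfig) -> int:
    raw = config.train_fraction * n_class
    if config.split_rounding == "floor_train":
        return int(np.floor(raw))
    return int(np.floor(raw + 0.5))  # round half up, not banker's


def stratified_split(
    records: Sequence[ImageRecord], config: PrepConfig
) -> tuple[list[ImageRecord], list[ImageRecord]]:
    """Per-class seeded shuffle, then split at the rounded train count.

    Every class needs at least two records so both partitions can be
    non-empty somewhere.  The same seed reproduces the same membership;
    counts depend only on class sizes and the rounding rule.
    """
    by_class: dict[str, list[ImageRecord]] = {}
    for rec in records:
        by_class.setdefault(rec.label, []).append(rec)
    for label, group in by_class.items():
        if len(group) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 records")
    rng = np.random.default_rng(config.seed)
    train: list[ImageRecord] = []
    test: list[ImageRecord] = []
    for label in sorted(by_class):
        group = by_class[label]
        order = rng.permutation(len(group))
        n_train = _train_count(len(group), config)
        train.extend(group[i] for i in order[:n_train])
        test.extend(group[i] for i in order[n_train:])
    return train, test


def write_split_manifest(
    train: Sequence[ImageRecord], test: Sequence[ImageRecord], path: str | Path
) -> None:
    """Two-column plain-text manifest: record id, partition."""
    lines = [f"{r.id}\ttrain" for r in train] + [f"{r.id}\ttest" for r in test]
    Path(path).write_text("\n".join(lines) + "\n")


# --- CNN backbone adapter -------------------------------------------------

_BACKBONES: dict[str, tuple[Callable[[np.ndarray], np.ndarray], int]] = {}


def register_backbone(
    name: str, fn: Callable[[np.ndarray], np.ndarray], width: int | None = None
) -> None:
    """Register an external feature extractor under ``name``.

    ``fn`` maps a batch of images (n x H x W x C) to an n x width feature
    matrix.  For the known pre-trained names the width must match the
    published feature dimensionality.
    """
    if width is None:
        if name not in KNOWN_BACKBONE_DIMS:
            raise ValueError(f"width required for unknown backbone {name!r}")
        width = KNOWN_BACKBONE_DIMS[name]
    if name in KNOWN_BACKBONE_DIMS and width != KNOWN_BACKBONE_DIMS[name]:
        raise ValueError(
            f"backbone {name!r} must produce {KNOWN_BACKBONE_DIMS[name]} features, got {width}"
        )
    _BACKBONES[name] = (fn, width)


def cnn_feature_adapter(
    records: Sequence[ImageRecord], backbone_name: str
) -> FeatureTable:
    """Run a registered backbone over records and return its feature table."""
    if backbone_name not in _BACKBONES:
        raise KeyError(
            f"backbone {backbone_name!r} is not registered; "
            f"registered: {sorted(_BACKBONES) or 'none'}"
        )
    fn, width = _BACKBONES[backbone_name]
    batch = np.stack([np.asarray(r.pixels, dtype=float) for r in records])
    features = np.asarray(fn(batch), dtype=float)
    if features.shape != (len(records), width):
        raise ValueError(
            f"backbone {backbone_name!r} returned shape {features.shape}, "
            f"expected ({len(records)}, {width})"
        )
    classes = sorted({r.label for r in records})
    lookup = {c: i for i, c in enumerate(classes)}
    y = CategoricalSeries(np.array([lookup[r.label] for r in records]), len(classes))
    return FeatureTable(
        X=features,
        y=y,
        feature_ids=[f"{backbone_name}_{j}" for j in range(width)],
        sample_ids=[r.id for r in records],
        class_names=classes,
    )
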