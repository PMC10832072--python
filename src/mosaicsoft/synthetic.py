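"""Synthetic 3-class lesion-image generator and stratified dataset splitting.

Real clinical photographs of the kind this method targets (small lesions on a
larger organ, heavy class imbalance) are rarely shareable, so the package
carries a generator that emulates their structure: an object-on-background
photo (a filled ellipse on a dark surround) carrying one small
class-discriminative motif per image, with lesions allowed to touch the image
border — the situation that motivates saliency-aware cropping in the first
place.  Class counts follow a configurable imbalance ratio, by default
372 : 141 : 1297.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import draw as skdraw

__all__ = [
    "LabeledImage",
    "SyntheticDatasetConfig",
    "ConfigurationError",
    "StratificationError",
    "allocate_counts",
    "generate_dataset",
    "split_dataset",
    "save_dataset",
    "load_dataset",
    "images_to_arrays",
]

#: default class ratio: cancer-like minority, rarer-still minority, large majority
DEFAULT_RATIO = (372.0, 141.0, 1297.0)


class ConfigurationError(ValueError):
    """Raised for an invalid generator configuration."""


class StratificationError(ValueError):
    """Raised when a split would leave a class empty in some partition."""


@dataclass(frozen=True)
class LabeledImage:
    """An RGB image with a hard class label and a stable identifier.

    ``pixels`` is an H x W x 3 uint8 array; images must be at least 32 pixels
    on each side so that 2x2 mosaic quadrants stay non-degenerate.
    """

    pixels: np.ndarray
    label: int
    id: str

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3, got shape {p.shape}")
        if p.shape[0] < 32 or p.shape[1] < 32:
            raise ValueError("images must be at least 32x32 pixels")
        if self.label < 0:
            raise ValueError("label must be a nonnegative class index")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class SyntheticDatasetConfig:
    """Configuration of the synthetic lesion-image dataset.

    Parameters
    ----------
    n_total:
        Total number of images, allocated to classes proportionally to
        ``imbalance_ratio`` with largest-remainder rounding.  Mutually
        exclusive with ``n_per_class``.
    n_per_class:
        Shorthand for a dataset of ``n_per_class * n_classes`` images
        allocated by the ratio; with the balanced ratio this is simply the
        per-class count.
    image_size:
        Side of the square images in pixels (>= 32).
    imbalance_ratio:
        Relative class frequencies; entries >= 0, at least two positive.
    lesion_size_range:
        Lesion diameter as a fraction of image width, ``(min, max)`` within
        (0, 1).
    edge_placement_prob:
        Probability that a lesion is placed touching an image border.
    noise_sigma:
        Standard deviation of additive Gaussian pixel noise (0-255 scale).
    seed:
        Seed for all randomness in the generator.
    """

    n_total: int | None = None
    n_per_class: int | None = None
    image_size: int = 96
    imbalance_ratio: tuple[float, ...] = DEFAULT_RATIO
    lesion_size_range: tuple[float, float] = (0.14, 0.30)
    edge_placement_prob: float = 0.3
    noise_sigma: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        ratio = np.asarray(self.imbalance_ratio, dtype=float)
        if np.any(ratio < 0) or np.sum(ratio > 0) < 2:
            raise ConfigurationError(
                "imbalance_ratio entries must be >= 0 with at least two positive"
            )
        lo, hi = self.lesion_size_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError("lesion_size_range must satisfy 0 < min <= max < 1")
        if self.image_size < 32:
            raise ConfigurationError("image_size must be >= 32")
        if (self.n_total is None) == (self.n_per_class is None):
            raise ConfigurationError("specify exactly one of n_total / n_per_class")
        if not (0.0 <= self.edge_placement_prob <= 1.0):
            raise ConfigurationError("edge_placement_prob must be in [0, 1]")

    @property
    def n_classes(self) -> int:
        return len(self.imbalance_ratio)

    def class_counts(self) -> np.ndarray:
        total = (
            self.n_total
            if self.n_total is not None
            else self.n_per_class * self.n_classes
        )
        return allocate_counts(total, self.imbalance_ratio)


def allocate_counts(total: int, ratio: tuple[float, ...]) -> np.ndarray:
    """Allocate ``total`` items to classes proportionally to ``ratio``.

    Largest-remainder rounding: floors of the exact quotas, with the leftover
    items given to the classes with the largest fractional remainders.  The
    result always sums to ``total`` exactly.
    """
    ratio_arr = np.asarray(ratio, dtype=float)
    quotas = total * ratio_arr / ratio_arr.sum()
    counts = np.floor(quotas).astype(int)
    remainders = quotas - counts
    leftover = total - counts.sum()
    # ties broken toward the lower class index (stable sort on -remainder)
    for idx in np.argsort(-remainders, kind="stable")[:leftover]:
        counts[idx] += 1
    return counts


# ---------------------------------------------------------------------------
# image synthesis

_BG_SURROUND = np.array([30.0, 26.0, 28.0])
_BG_OBJECT = np.array([178.0, 118.0, 118.0])
_BLOB_COLOR = np.array([45.0, 8.0, 12.0])  # class 0: dark irregular blob
_RING_COLOR = np.array([250.0, 240.0, 120.0])  # class 1: light ring
_SPECKLE_COLOR = np.array([235.0, 235.0, 235.0])  # class 2: bright speckle field


def _object_mask(size: int, rng: np.random.Generator) -> tuple[np.ndarray, tuple]:
    """Filled ellipse foreground; returns (mask, (cy, cx, ay, ax))."""
    cy = size / 2 + rng.uniform(-0.03, 0.03) * size
    cx = size / 2 + rng.uniform(-0.03, 0.03) * size
    ay = rng.uniform(0.32, 0.42) * size
    ax = rng.uniform(0.36, 0.46) * size
    rr, cc = skdraw.ellipse(cy, cx, ay, ax, shape=(size, size))
    mask = np.zeros((size, size), dtype=bool)
    mask[rr, cc] = True
    return mask, (cy, cx, ay, ax)


def _lesion_center(
    size: int,
    ellipse: tuple,
    diameter: float,
    edge: bool,
    rng: np.random.Generator,
) -> tuple[float, float]:
    if edge:
        # center close enough to a border that the lesion touches it
        side = rng.integers(4)
        margin = diameter / 2 * rng.uniform(0.2, 0.8)
        along = rng.uniform(0.2, 0.8) * size
        if side == 0:
            return margin, along
        if side == 1:
            return size - 1 - margin, along
        if side == 2:
            return along, margin
        return along, size - 1 - margin
    cy, cx, ay, ax = ellipse
    theta = rng.uniform(0, 2 * np.pi)
    r = np.sqrt(rng.uniform()) * 0.8
    return cy + r * ay * np.sin(theta), cx + r * ax * np.cos(theta)


def _paint(img: np.ndarray, rr, cc, color: np.ndarray, alpha: float = 1.0) -> None:
    img[rr, cc] = (1 - alpha) * img[rr, cc] + alpha * color


def _draw_motif(
    img: np.ndarray,
    label: int,
    center: tuple[float, float],
    diameter: float,
    rng: np.random.Generator,
) -> None:
    size = img.shape[0]
    cy, cx = center
    radius = diameter / 2
    # lesions vary in contrast: faint presentations are the hard cases
    strength = rng.uniform(0.6, 1.0)
    if label == 0:
        # irregular dark blob: star-shaped polygon with perturbed radii
        angles = np.linspace(0, 2 * np.pi, 13)[:-1]
        radii = radius * (1.0 + rng.uniform(-0.35, 0.35, size=angles.size))
        rr, cc = skdraw.polygon(
            cy + radii * np.sin(angles), cx + radii * np.cos(angles), shape=(size, size)
        )
        _paint(img, rr, cc, _BLOB_COLOR + rng.normal(0, 4, 3), alpha=strength)
    elif label == 1:
        # bright annulus: outer disk minus inner disk
        outer = np.zeros((size, size), dtype=bool)
        rr, cc = skdraw.disk((cy, cx), radius, shape=(size, size))
        outer[rr, cc] = True
        inner = np.zeros((size, size), dtype=bool)
        rr, cc = skdraw.disk((cy, cx), max(1.0, radius * 0.55), shape=(size, size))
        inner[rr, cc] = True
        ring = outer & ~inner
        _paint(img, *np.nonzero(ring), _RING_COLOR + rng.normal(0, 4, 3), alpha=strength)
    else:
        # near-plain appearance: a field of small bright speckles
        n_dots = rng.integers(16, 26)
        dot_r = max(1.2, diameter / 12)
        for _ in range(n_dots):
            theta = rng.uniform(0, 2 * np.pi)
            r = np.sqrt(rng.uniform()) * radius
            rr, cc = skdraw.disk(
                (cy + r * np.sin(theta), cx + r * np.cos(theta)),
                dot_r,
                shape=(size, size),
            )
            _paint(img, rr, cc, _SPECKLE_COLOR + rng.normal(0, 6, 3), alpha=strength)


def _render_image(label: int, config: SyntheticDatasetConfig, rng: np.random.Generator) -> np.ndarray:
    size = config.image_size
    img = np.empty((size, size, 3), dtype=float)
    img[:] = _BG_SURROUND + rng.normal(0, 2, 3)
    mask, ellipse = _object_mask(size, rng)
    _paint(img, *np.nonzero(mask), _BG_OBJECT + rng.normal(0, 5, 3))

    diameter = rng.uniform(*config.lesion_size_range) * size
    edge = rng.uniform() < config.edge_placement_prob
    center = _lesion_center(size, ellipse, diameter, edge, rng)
    _draw_motif(img, label, center, diameter, rng)

    if config.noise_sigma > 0:
        img += rng.normal(0, config.noise_sigma, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_dataset(config: SyntheticDatasetConfig) -> list[LabeledImage]:
    """Generate the synthetic dataset described by ``config``.

    Deterministic given ``config.seed``: the same configuration yields
    byte-identical pixel arrays.  Images are returned grouped by class
    (class 0 first), each containing exactly one class motif.
    """
    counts = config.class_counts()
    seq = np.random.SeedSequence(config.seed)
    children = seq.spawn(int(counts.sum()))
    images: list[LabeledImage] = []
    i = 0
    for label, n in enumerate(counts):
        for _ in range(int(n)):
            rng = np.random.default_rng(children[i])
            images.append(
                LabeledImage(
                    pixels=_render_image(label, config, rng),
                    label=label,
                    id=f"syn_{i:05d}_c{label}",
                )
            )
            i += 1
    return images


# ---------------------------------------------------------------------------
# splitting

def split_dataset(
    images: list[LabeledImage],
    test_frac: float = 0.1,
    val_frac: float = 0.3,
    seed: int = 0,
) -> tuple[list[LabeledImage], list[LabeledImage], list[LabeledImage]]:
    """Split into (train, val, test), stratified by class.

    The test partition is drawn first so that per-class proportions reflect
    the full dataset: each class contributes ``floor(n_c * test_frac)``
    images (at least one when the class is large enough to spare one).  The
    remainder is split into validation and training with ``val_frac`` going
    to validation, allocated per class by largest remainder so that every
    image lands in exactly one partition.  Deterministic given ``seed``.
    """
    if not (0 < test_frac < 1 and 0 < val_frac < 1):
        raise ValueError("fractions must lie in (0, 1)")
    labels = np.array([im.label for im in images])
    classes = np.unique(labels)
    rng = np.random.default_rng(seed)

    test_idx: list[int] = []
    rest_idx_per_class: dict[int, np.ndarray] = {}
    for c in classes:
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        n_test = int(np.floor(idx.size * test_frac))
        if n_test == 0 and idx.size >= 3:
            n_test = 1
        test_idx.extend(idx[:n_test].tolist())
        rest_idx_per_class[int(c)] = idx[n_test:]

    rest_sizes = {c: v.size for c, v in rest_idx_per_class.items()}
    n_rest = sum(rest_sizes.values())
    target_val = int(round(n_rest * val_frac))
    quotas = {c: rest_sizes[c] * val_frac for c in rest_sizes}
    val_counts = {c: int(np.floor(q)) for c, q in quotas.items()}
    leftover = target_val - sum(val_counts.values())
    order = sorted(quotas, key=lambda c: quotas[c] - val_counts[c], reverse=True)
    for c in order:
        if leftover <= 0:
            break
        if val_counts[c] < rest_sizes[c]:
            val_counts[c] += 1
            leftover -= 1

    val_idx: list[int] = []
    train_idx: list[int] = []
    for c, idx in rest_idx_per_class.items():
        val_idx.extend(idx[: val_counts[c]].tolist())
        train_idx.extend(idx[val_counts[c] :].tolist())

    parts = (train_idx, val_idx, test_idx)
    for c in classes:
        n_c = int(np.sum(labels == c))
        if n_c >= 3 and any(
            not np.any(labels[np.array(p, dtype=int)] == c) if p else True
            for p in parts
        ):
            raise StratificationError(
                f"class {c} has {n_c} images but would be absent from a partition; "
                "use more data or different fractions"
            )

    return (
        [images[i] for i in sorted(train_idx)],
        [images[i] for i in sorted(val_idx)],
        [images[i] for i in sorted(test_idx)],
    )


# ---------------------------------------------------------------------------
# manifest I/O (CSV with header path,label,split; images as PNG)

def save_dataset(
    images: list[LabeledImage],
    out_dir: str | Path,
    splits: dict[str, str] | None = None,
) -> Path:
    """Write PNG images plus ``manifest.csv`` (columns path,label,split).

    ``splits`` maps image id to a partition name; absent ids get "all".
    Returns the manifest path.
    """
    from PIL import Image

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "split"])
        for im in images:
            rel = f"images/{im.id}.png"
            Image.fromarray(im.pixels).save(out / rel)
            split = (splits or {}).get(im.id, "all")
            writer.writerow([rel, im.label, split])
    return manifest


def load_dataset(
    manifest_path: str | Path,
) -> tuple[list[LabeledImage], list[str]]:
    """Read a manifest written by :func:`save_dataset`.

    Returns the images and the parallel list of split names.
    """
    from PIL import Image

    manifest = Path(manifest_path)
    base = manifest.parent
    images: list[LabeledImage] = []
    splits: list[str] = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            path = base / row["path"]
            pixels = np.asarray(Image.open(path).convert("RGB"))
            images.append(
                LabeledImage(pixels=pixels, label=int(row["label"]), id=path.stem)
            )
            splits.append(row.get("split", "all"))
    return images, splits


def images_to_arrays(images: list[LabeledImage]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a list of equally sized images into (X, y) arrays."""
    X = np.stack([im.pixels for im in images]).astype(np.uint8)
    y = np.array([im.label for im in images], dtype=int)
    return X, y
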