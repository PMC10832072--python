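"""Mosaic synthesis with area-proportional soft labels.

A mosaic training image is a 2x2 grid of representative patches cut from
four source images: one per class plus one extra from a uniformly random
class, so every class is present in every mosaic.  The grid's split point is
drawn uniformly on the unit square conditioned on one quadrant covering more
than half of the image, which keeps a dominant class in each mosaic; which
class receives that dominant quadrant is drawn from a configurable
allocation, the knob that lets minority classes be oversampled by area.
The training label of a mosaic is the probability vector of exact fractional
areas each class occupies in the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from mosaicsoft.cam import BoundingBox, extract_roi
from mosaicsoft.synthetic import LabeledImage

__all__ = [
    "QUADRANTS",
    "SplitPoint",
    "QuadrantPatch",
    "MosaicSpec",
    "SoftLabel",
    "MosaicConfig",
    "DegenerateQuadrantError",
    "sample_split_point",
    "assign_quadrants",
    "synthesize_mosaic",
    "compute_soft_label",
    "build_mosaic_dataset",
]

#: quadrant ids in row-major order: top-left, top-right, bottom-left, bottom-right
QUADRANTS = ("TL", "TR", "BL", "BR")


class DegenerateQuadrantError(ValueError):
    """A quadrant would be empty after rounding to pixel boundaries."""


@dataclass(frozen=True)
class SplitPoint:
    """The 2x2 grid cut of the unit square: fx splits width, fy height.

    The left column has fractional width ``fx`` and the top row fractional
    height ``fy``.  Points produced by :func:`sample_split_point` additionally
    satisfy the majority constraint (largest quadrant area > 1/2).
    """

    fx: float
    fy: float

    def __post_init__(self) -> None:
        if not (0.0 < self.fx < 1.0 and 0.0 < self.fy < 1.0):
            raise ValueError("split fractions must lie strictly inside (0, 1)")

    def quadrant_areas(self) -> dict[str, float]:
        fx, fy = self.fx, self.fy
        return {
            "TL": fx * fy,
            "TR": (1 - fx) * fy,
            "BL": fx * (1 - fy),
            "BR": (1 - fx) * (1 - fy),
        }

    @property
    def max_area(self) -> float:
        return max(self.quadrant_areas().values())

    @property
    def largest_quadrant(self) -> str:
        areas = self.quadrant_areas()
        return max(QUADRANTS, key=lambda q: areas[q])

    @property
    def satisfies_majority(self) -> bool:
        return self.max_area > 0.5


@dataclass(frozen=True)
class QuadrantPatch:
    """One quadrant's content: source class, source image id, crop box."""

    class_index: int
    image_id: str
    crop: BoundingBox


@dataclass(frozen=True)
class MosaicSpec:
    """Everything that determines one mosaic image and its soft label."""

    split: SplitPoint
    quadrants: dict[str, QuadrantPatch]
    output_size: int

    def __post_init__(self) -> None:
        if set(self.quadrants) != set(QUADRANTS):
            raise ValueError(f"quadrants must be exactly {QUADRANTS}")

    def quadrant_classes(self) -> tuple[int, int, int, int]:
        return tuple(self.quadrants[q].class_index for q in QUADRANTS)


@dataclass(frozen=True)
class SoftLabel:
    """Length-K probability vector; entries >= 0 summing to 1."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("soft label must be a probability vector summing to 1")


@dataclass
class MosaicConfig:
    """Configuration of the mosaic dataset builder.

    ``n_images`` synthesized mosaics (1,200 by default), ``output_size``
    pixels per side, ``oversample_allocation`` the per-class probability of
    receiving the dominant quadrant (uniform when None), and ``seed`` for
    all randomness of the builder.
    """

    n_images: int = 1200
    oversample_allocation: tuple[float, ...] | None = None
    output_size: int = 96
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 0:
            raise ValueError("n_images must be >= 0")
        if self.oversample_allocation is not None:
            a = np.asarray(self.oversample_allocation, dtype=float)
            if np.any(a < 0) or abs(a.sum() - 1.0) > 1e-9:
                raise ValueError("oversample_allocation must be a probability vector")


def inverse_frequency_allocation(counts) -> tuple[float, ...]:
    """Dominant-quadrant allocation proportional to inverse class frequency.

    Minority classes receive the largest quadrant more often, realising the
    adjustable by-area oversampling of the mosaic builder.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError("all class counts must be positive")
    inv = 1.0 / counts
    return tuple(inv / inv.sum())


def sample_split_point(
    rng: np.random.Generator, max_tries: int = 1000
) -> SplitPoint:
    """Uniform split point conditioned on the majority constraint.

    Rejection sampling from the uniform distribution on (0,1)^2; the
    acceptance region (one quadrant larger than half the square) has measure
    2 - 2 ln 2 ~ 0.614, so the retry cap is never reached in practice.
    """
    for _ in range(max_tries):
        p = SplitPoint(fx=float(rng.uniform()), fy=float(rng.uniform()))
        if p.satisfies_majority:
            return p
    raise RuntimeError("split-point rejection sampling exceeded max_tries")


def assign_quadrants(
    rng: np.random.Generator,
    split: SplitPoint,
    pools: list[list[str]],
    allocation: tuple[float, ...] | None = None,
) -> dict[str, tuple[int, str]]:
    """Assign (class, source image id) to each quadrant of ``split``.

    One source image is drawn per class (with replacement) and a fourth from
    a uniformly random class, so all classes are represented.  The dominant
    quadrant receives an image of a class drawn from ``allocation`` (uniform
    by default); the remaining three slots are shuffled over the remaining
    quadrants.
    """
    n_classes = len(pools)
    if any(len(p) == 0 for p in pools):
        raise ValueError("every class pool must be non-empty")
    alloc = (
        np.full(n_classes, 1.0 / n_classes)
        if allocation is None
        else np.asarray(allocation, dtype=float)
    )
    extra = int(rng.integers(n_classes))
    slot_classes = list(range(n_classes)) + [extra]
    slot_images = [pools[c][int(rng.integers(len(pools[c])))] for c in slot_classes]

    dominant_class = int(rng.choice(n_classes, p=alloc))
    candidates = [i for i, c in enumerate(slot_classes) if c == dominant_class]
    dominant_slot = candidates[int(rng.integers(len(candidates)))]

    rest = [i for i in range(4) if i != dominant_slot]
    rng.shuffle(rest)
    order = [None] * 4
    largest = split.largest_quadrant
    other_quadrants = [q for q in QUADRANTS if q != largest]
    assignment = {largest: dominant_slot}
    for q, slot in zip(other_quadrants, rest):
        assignment[q] = slot
    return {
        q: (slot_classes[s], slot_images[s]) for q, s in assignment.items()
    }


def _pixel_boundaries(split: SplitPoint, size: int) -> tuple[int, int]:
    px = int(round(split.fx * size))
    py = int(round(split.fy * size))
    if px <= 0 or px >= size or py <= 0 or py >= size:
        raise DegenerateQuadrantError(
            f"split {split} rounds to an empty quadrant on a {size}px canvas"
        )
    return px, py


def _resize_patch(patch: np.ndarray, height: int, width: int) -> np.ndarray:
    out = resize(
        patch.astype(np.float64),
        (height, width),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def synthesize_mosaic(
    spec: MosaicSpec, sources: dict[str, LabeledImage]
) -> np.ndarray:
    """Render the mosaic image described by ``spec``.

    Each quadrant is the source image cropped to its representative box and
    bilinearly rescaled to the quadrant's pixel extent; quadrant boundaries
    sit at ``round(fx * size)`` / ``round(fy * size)``.
    """
    size = spec.output_size
    px, py = _pixel_boundaries(spec.split, size)
    regions = {
        "TL": (slice(0, py), slice(0, px)),
        "TR": (slice(0, py), slice(px, size)),
        "BL": (slice(py, size), slice(0, px)),
        "BR": (slice(py, size), slice(px, size)),
    }
    canvas = np.empty((size, size, 3), dtype=np.uint8)
    for q in QUADRANTS:
        patch_spec = spec.quadrants[q]
        rows, cols = regions[q]
        crop = patch_spec.crop.crop(sources[patch_spec.image_id].pixels)
        canvas[rows, cols] = _resize_patch(
            crop, rows.stop - rows.start, cols.stop - cols.start
        )
    return canvas


def compute_soft_label(
    split: SplitPoint,
    quadrant_classes: tuple[int, int, int, int],
    n_classes: int = 3,
) -> SoftLabel:
    """Soft label from exact fractional quadrant areas.

    ``probs[c]`` is the sum of the unit-square areas of the quadrants
    assigned class ``c`` (quadrant order TL, TR, BL, BR); areas are the
    exact products of split fractions, not rounded pixel counts, so the
    entries always sum to 1.
    """
    areas = split.quadrant_areas()
    probs = np.zeros(n_classes, dtype=float)
    for q, c in zip(QUADRANTS, quadrant_classes):
        probs[c] += areas[q]
    return SoftLabel(probs=probs)


@dataclass(frozen=True)
class MosaicImage:
    """A synthesized mosaic with its soft label and full provenance."""

    pixels: np.ndarray
    soft_label: SoftLabel
    spec: MosaicSpec
    id: str


def build_mosaic_dataset(
    train_images: list[LabeledImage],
    model,
    config: MosaicConfig,
    n_classes: int | None = None,
) -> list[MosaicImage]:
    """Build ``config.n_images`` mosaic/soft-label pairs from ``train_images``.

    The representative box of every source image is computed once with the
    stage-1 ``model`` (Grad-CAM at the ground-truth class, Otsu, largest
    region) and cached; an image whose binary map is empty falls back to its
    full-image box.  Deterministic given ``config.seed``.  ``train_images``
    must exclude the test partition.
    """
    if n_classes is None:
        n_classes = max(im.label for im in train_images) + 1
    pools: list[list[str]] = [[] for _ in range(n_classes)]
    by_id: dict[str, LabeledImage] = {}
    for im in train_images:
        pools[im.label].append(im.id)
        by_id[im.id] = im
    if config.n_images > 0 and any(len(p) == 0 for p in pools):
        raise ValueError("every class needs at least one training image")

    roi_cache: dict[str, BoundingBox] = {
        im.id: extract_roi(model, im) for im in train_images
    } if config.n_images > 0 else {}

    rng = np.random.default_rng(config.seed)
    mosaics: list[MosaicImage] = []
    for i in range(config.n_images):
        while True:
            split = sample_split_point(rng)
            try:
                _pixel_boundaries(split, config.output_size)
                break
            except DegenerateQuadrantError:
                continue
        assignment = assign_quadrants(
            rng, split, pools, config.oversample_allocation
        )
        quadrants = {
            q: QuadrantPatch(
                class_index=cls, image_id=img_id, crop=roi_cache[img_id]
            )
            for q, (cls, img_id) in assignment.items()
        }
        spec = MosaicSpec(
            split=split, quadrants=quadrants, output_size=config.output_size
        )
        label = compute_soft_label(split, spec.quadrant_classes(), n_classes)
        mosaics.append(
            MosaicImage(
                pixels=synthesize_mosaic(spec, by_id),
                soft_label=label,
                spec=spec,
                id=f"mosaic_{i:05d}",
            )
        )
    return mosaics
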