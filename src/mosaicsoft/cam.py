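"""Representative-region extraction: Grad-CAM, Otsu binarization, largest box.

The mosaic builder needs to know, for every source image, where the
class-relevant evidence sits.  That region is located in three steps:

1. a Grad-CAM importance map of the image for its ground-truth class —
   channel activations of the designated conv layer weighted by the
   spatially averaged gradient of the class logit, rectified, upsampled
   bilinearly to image resolution and min-max normalized to [0, 1];
2. Otsu's threshold (256-bin histogram, maximal between-class variance)
   turning the map into representative / non-representative pixels;
3. the tight axis-aligned bounding box of the largest 8-connected
   representative region.

Coordinates are 0-based and half-open throughout, so a box composes
directly with numpy slicing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.transform import resize

from mosaicsoft.synthetic import LabeledImage

__all__ = [
    "ImportanceMap",
    "BinaryMask",
    "BoundingBox",
    "UnsupportedModelError",
    "EmptyRegionError",
    "compute_grad_cam",
    "binarize_otsu",
    "largest_region_bbox",
    "extract_roi",
]


class UnsupportedModelError(TypeError):
    """The model does not expose conv-layer activations and gradients."""


class EmptyRegionError(ValueError):
    """The binary map contains no representative pixel."""


@dataclass(frozen=True)
class ImportanceMap:
    """Min-max-normalized Grad-CAM map in [0, 1] for one target class."""

    values: np.ndarray
    source_class: int

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2:
            raise ValueError("importance map must be 2-D")
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError("importance map values must lie in [0, 1]")


@dataclass(frozen=True)
class BinaryMask:
    """Boolean map of representative pixels, same shape as its source map."""

    mask: np.ndarray


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box, 0-based half-open: [x_min, x_max) x [y_min, y_max)."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate bounding box {self}")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    @classmethod
    def full(cls, height: int, width: int) -> "BoundingBox":
        return cls(0, 0, width, height)

    def crop(self, pixels: np.ndarray) -> np.ndarray:
        return pixels[self.y_min : self.y_max, self.x_min : self.x_max]


def _normalize01(values: np.ndarray) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi - lo <= 1e-12:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def compute_grad_cam(
    model, image: LabeledImage | np.ndarray, target_class: int
) -> ImportanceMap:
    """Grad-CAM importance map of ``image`` for ``target_class``.

    ``model`` must expose ``cam_data(image01, target_class)`` returning the
    (H', W', C) activations of its designated conv layer and the gradient of
    the target-class logit with respect to them (see
    :class:`mosaicsoft.nn.SmallCNN`); otherwise an
    :class:`UnsupportedModelError` is raised.  The channel weights are the
    spatial means of the gradient; the weighted activation sum is rectified,
    bilinearly upsampled to the image size, and min-max normalized (a
    constant raw map normalizes to all zeros).
    """
    if not hasattr(model, "cam_data"):
        raise UnsupportedModelError(
            f"{type(model).__name__} does not expose cam_data(); Grad-CAM needs "
            "access to a convolutional layer's activations and gradients"
        )
    pixels = image.pixels if isinstance(image, LabeledImage) else np.asarray(image)
    if pixels.dtype == np.uint8:
        pixels = pixels.astype(np.float32) / 255.0
    activations, gradients = model.cam_data(pixels, target_class)
    weights = gradients.mean(axis=(0, 1))
    raw = np.maximum(activations @ weights, 0.0)
    upsampled = resize(
        raw, pixels.shape[:2], order=1, mode="edge", anti_aliasing=False
    )
    return ImportanceMap(values=_normalize01(upsampled), source_class=int(target_class))


def binarize_otsu(imap: ImportanceMap | np.ndarray) -> BinaryMask:
    """Binarize an importance map at Otsu's threshold (256 histogram bins).

    Pixels strictly above the threshold are representative.  A constant map
    has no between-class structure; the whole image is then treated as
    representative so the pipeline stays total.
    """
    values = imap.values if isinstance(imap, ImportanceMap) else np.asarray(imap)
    if np.ptp(values) <= 1e-12:
        return BinaryMask(mask=np.ones(values.shape, dtype=bool))
    t = threshold_otsu(values, nbins=256)
    return BinaryMask(mask=values > t)


def largest_region_bbox(mask: BinaryMask | np.ndarray) -> BoundingBox:
    """Bounding box of the largest 8-connected region of true pixels.

    Ties on region size go to the component whose first pixel comes first in
    row-major order.  An all-false mask raises :class:`EmptyRegionError`;
    callers that need totality fall back to the full-image box.
    """
    m = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise EmptyRegionError("binary map has no representative pixel")
    labels = cc_label(m, connectivity=2)
    regions = regionprops(labels)
    # labels are assigned in raster-scan order, so among equal areas the
    # lowest label is the component encountered first
    best = max(regions, key=lambda r: (r.area, -r.label))
    y0, x0, y1, x1 = best.bbox
    return BoundingBox(x_min=int(x0), y_min=int(y0), x_max=int(x1), y_max=int(y1))


def extract_roi(
    model, image: LabeledImage, target_class: int | None = None
) -> BoundingBox:
    """Full pipeline: Grad-CAM -> Otsu -> largest-region box, with fallback.

    ``target_class`` defaults to the image's ground-truth label (known at
    augmentation time).  If the binary map is empty the full-image box is
    returned and a warning is emitted.
    """
    cls = image.label if target_class is None else target_class
    imap = compute_grad_cam(model, image, cls)
    mask = binarize_otsu(imap)
    try:
        return largest_region_bbox(mask)
    except EmptyRegionError:
        warnings.warn(
            f"image {image.id}: empty representative region, using full image",
            stacklevel=2,
        )
        h, w = image.shape
        return BoundingBox.full(h, w)
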