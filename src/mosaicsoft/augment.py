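"""Conventional image augmentation: zoom, flips, rotation, shift.

Two policies are used during curriculum training.  Original photographs get
the full policy (random zoom 0.8-1.0, horizontal/vertical flips, rotation
within +/-30 degrees, shifts within +/-10% of the side, nearest-pixel fill
outside the input).  Mosaic images get a gentler policy — flips plus
rotation within +/-5 degrees only — whose purpose is to keep the network
from latching onto the cross-shaped seam between the four patches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["AugmentationPolicy", "augment_image"]


@dataclass(frozen=True)
class AugmentationPolicy:
    """Ranges of the random affine augmentation applied during training.

    ``zoom_range`` is an interval of scale factors (values below 1 enlarge
    the content, i.e. zoom in); ``rotation_range`` is in degrees;
    ``shift_range`` is a fraction of the image side; ``fill_mode`` names the
    boundary rule for pixels sampled outside the input.
    """

    zoom_range: tuple[float, float] = (0.8, 1.0)
    horizontal_flip: bool = True
    vertical_flip: bool = True
    rotation_range: tuple[float, float] = (-30.0, 30.0)
    shift_range: tuple[float, float] = (-0.1, 0.1)
    fill_mode: str = "nearest"

    @classmethod
    def stage1(cls) -> "AugmentationPolicy":
        """Policy for original (real) images."""
        return cls()

    @classmethod
    def mosaic(cls) -> "AugmentationPolicy":
        """Policy for mosaic images: flips and small rotations only."""
        return cls(
            zoom_range=(1.0, 1.0),
            rotation_range=(-5.0, 5.0),
            shift_range=(0.0, 0.0),
        )

    @classmethod
    def identity(cls) -> "AugmentationPolicy":
        return cls(
            zoom_range=(1.0, 1.0),
            horizontal_flip=False,
            vertical_flip=False,
            rotation_range=(0.0, 0.0),
            shift_range=(0.0, 0.0),
        )


def augment_image(
    image: np.ndarray, policy: AugmentationPolicy, rng: np.random.Generator
) -> np.ndarray:
    """Apply one random draw of ``policy`` to an (H, W, C) float image.

    The zoom, rotation and shift are composed into a single affine map
    about the image center and resampled bilinearly in one pass.
    """
    out = image
    if policy.horizontal_flip and rng.random() < 0.5:
        out = out[:, ::-1]
    if policy.vertical_flip and rng.random() < 0.5:
        out = out[::-1]

    scale = rng.uniform(*policy.zoom_range)
    angle = np.deg2rad(rng.uniform(*policy.rotation_range))
    h, w = out.shape[:2]
    dy = rng.uniform(*policy.shift_range) * h
    dx = rng.uniform(*policy.shift_range) * w
    if scale == 1.0 and angle == 0.0 and dx == 0.0 and dy == 0.0:
        return np.ascontiguousarray(out)

    # output -> input mapping: rotate by -angle and scale about the center,
    # then translate; row/col convention
    cos, sin = np.cos(angle), np.sin(angle)
    mat = scale * np.array([[cos, -sin], [sin, cos]])
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - mat @ center + np.array([dy, dx])
    channels = [
        ndimage.affine_transform(
            out[..., c], mat, offset=offset, order=1, mode=policy.fill_mode
        )
        for c in range(out.shape[2])
    ]
    return np.stack(channels, axis=-1)
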