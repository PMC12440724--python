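"""Calibrated image containers.

Every image in this package carries its physical pixel spacing (mm/pixel per
axis) so that mask dilation and peritumoral-ring widths can be expressed in
millimetres rather than pixels, the way they are prescribed clinically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ShapeMismatchError

#: Rec.601 luma weights used everywhere a 3-channel image is reduced to
#: a single luminance channel.
REC601_WEIGHTS = np.array([0.299, 0.587, 0.114])


def _as_spacing(spacing_mm) -> tuple[float, float]:
    """Normalize a scalar or (row, col) pair to a (row, col) spacing tuple."""
    arr = np.atleast_1d(np.asarray(spacing_mm, dtype=float))
    if arr.size == 1:
        arr = np.array([arr[0], arr[0]])
    if arr.size != 2:
        raise ParameterError(f"spacing_mm must be a scalar or pair, got {spacing_mm!r}")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ParameterError(f"spacing_mm must be strictly positive, got {spacing_mm!r}")
    return float(arr[0]), float(arr[1])


def rec601_luminance(pixels: np.ndarray) -> np.ndarray:
    """Luminance of a (H, W) or (H, W, 3) array via fixed Rec.601 weights."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim == 2:
        return pixels
    if pixels.ndim == 3 and pixels.shape[2] == 3:
        return pixels @ REC601_WEIGHTS
    raise ParameterError(f"expected 1 or 3 channels, got array of shape {pixels.shape}")


@dataclass(frozen=True)
class CalibratedImage:
    """A 2-D pixel array (1 or 3 channels) with physical pixel spacing.

    Parameters
    ----------
    pixels:
        ``(H, W)`` or ``(H, W, 3)`` array of finite values. Grayscale images
        are stored as 2-D arrays.
    spacing_mm:
        mm per pixel, scalar (isotropic) or ``(row, col)`` pair.
    """

    pixels: np.ndarray
    spacing_mm: tuple[float, float]

    def __post_init__(self):
        pixels = np.asarray(self.pixels)
        if pixels.ndim not in (2, 3) or (pixels.ndim == 3 and pixels.shape[2] not in (1, 3)):
            raise ParameterError(f"image must have 1 or 3 channels, got shape {pixels.shape}")
        if pixels.ndim == 3 and pixels.shape[2] == 1:
            pixels = pixels[:, :, 0]
        if not np.all(np.isfinite(pixels)):
            raise ParameterError("image contains non-finite values")
        object.__setattr__(self, "pixels", pixels)
        object.__setattr__(self, "spacing_mm", _as_spacing(self.spacing_mm))

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    def luminance(self) -> np.ndarray:
        return rec601_luminance(self.pixels)


@dataclass(frozen=True)
class BinaryMask:
    """A boolean segmentation in pixel register with its image.

    Any nonzero input pixel is treated as true; masks are strictly binary.
    """

    pixels: np.ndarray
    spacing_mm: tuple[float, float]

    def __post_init__(self):
        pixels = np.asarray(self.pixels)
        if pixels.ndim != 2:
            raise ParameterError(f"mask must be 2-D, got shape {pixels.shape}")
        object.__setattr__(self, "pixels", pixels.astype(bool))
        object.__setattr__(self, "spacing_mm", _as_spacing(self.spacing_mm))

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    def check_register(self, image: CalibratedImage) -> None:
        if self.spatial_shape != image.spatial_shape:
            raise ShapeMismatchError(
                f"mask shape {self.spatial_shape} does not match image {image.spatial_shape}"
            )


@dataclass(frozen=True)
class BoundingBox:
    """Inclusive row/col bounds of a mask (row-major, 0-based)."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self):
        if self.row_min > self.row_max or self.col_min > self.col_max:
            raise ParameterError(f"degenerate bounding box {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.row_max - self.row_min + 1, self.col_max - self.col_min + 1

    @property
    def area_px(self) -> int:
        h, w = self.shape
        return h * w

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_min, self.row_max + 1), slice(self.col_min, self.col_max + 1)

    def contains(self, other: "BoundingBox") -> bool:
        return (
            self.row_min <= other.row_min
            and self.row_max >= other.row_max
            and self.col_min <= other.col_min
            and self.col_max >= other.col_max
        )
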