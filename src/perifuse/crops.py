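"""Compose color mode, ROI shape and fusion strategy into region crops.

The model grid crosses three factors:

* color: ``PC`` (pseudo-color retained) vs ``GRAY`` (Rec.601 grayscale);
* ROI shape: ``OP`` (original precise: background outside the mask zeroed)
  vs ``BB`` (bounding box: tight rectangle, interior retained);
* fusion: ``INTRA`` (lesion only), ``DE`` (direct extension: one crop over
  lesion + ring), ``FLF`` (feature-level fusion: separate intra and peri
  crops whose features are concatenated downstream).

``BB`` with ``FLF`` is excluded: the intratumoral bounding box overlaps the
peritumoral ring, so the two "separate" regions would share pixels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .errors import EmptyROIError, ParameterError, StrategyError
from .geometry import bounding_box, dilate_mask, peritumoral_ring
from .images import BinaryMask, BoundingBox, CalibratedImage, rec601_luminance

COLORS = ("PC", "GRAY")
ROI_SHAPES = ("OP", "BB")
FUSIONS = ("INTRA", "DE", "FLF")
DEFAULT_MARGINS_MM = (2.0, 4.0, 6.0, 8.0, 10.0)

_NAME_RE = re.compile(
    r"^(?P<color>PC|GRAY)-(?P<shape>OP|BB)-"
    r"(?:(?P<intra>Intra)|(?P<fusion>DE|FLF)-Peri \((?P<margin>[0-9.]+)mm\))$"
)


def to_grayscale(image: CalibratedImage) -> CalibratedImage:
    """Single-channel luminance via fixed Rec.601 weights; idempotent."""
    if image.n_channels == 1:
        return image
    return CalibratedImage(rec601_luminance(image.pixels), image.spacing_mm)


@dataclass(frozen=True)
class StrategyConfig:
    """One model of the grid: (color, ROI shape, fusion, margin in mm)."""

    color: str
    roi_shape: str
    fusion: str
    margin_mm: float = 0.0

    def __post_init__(self):
        if self.color not in COLORS:
            raise StrategyError(f"color must be one of {COLORS}, got {self.color!r}")
        if self.roi_shape not in ROI_SHAPES:
            raise StrategyError(f"roi_shape must be one of {ROI_SHAPES}, got {self.roi_shape!r}")
        if self.fusion not in FUSIONS:
            raise StrategyError(f"fusion must be one of {FUSIONS}, got {self.fusion!r}")
        if self.roi_shape == "BB" and self.fusion == "FLF":
            raise StrategyError(
                "BB+FLF is excluded: the intratumoral bounding box partially "
                "overlaps the peritumoral ring"
            )
        if self.fusion == "INTRA" and self.margin_mm != 0:
            raise StrategyError("margin_mm must be 0 for an intratumoral-only model")
        if self.fusion != "INTRA" and self.margin_mm <= 0:
            raise StrategyError("fusion models require a positive margin_mm")

    @property
    def name(self) -> str:
        """Deterministic model name, e.g. ``PC-OP-DE-Peri (4mm)``."""
        if self.fusion == "INTRA":
            return f"{self.color}-{self.roi_shape}-Intra"
        return f"{self.color}-{self.roi_shape}-{self.fusion}-Peri ({self.margin_mm:g}mm)"

    @classmethod
    def from_name(cls, name: str) -> "StrategyConfig":
        m = _NAME_RE.match(name)
        if m is None:
            raise ParameterError(f"unparseable strategy name {name!r}")
        if m.group("intra"):
            return cls(m.group("color"), m.group("shape"), "INTRA", 0.0)
        return cls(m.group("color"), m.group("shape"), m.group("fusion"), float(m.group("margin")))


@dataclass(frozen=True)
class RegionCrop:
    """A rectangular crop fed to feature extraction.

    ``mask`` is the defining region mask in crop coordinates; for OP crops
    every pixel outside it is exactly 0. ``bbox`` records the crop's frame in
    the source image, for containment checks and provenance.
    """

    pixels: np.ndarray
    region_tag: str
    source_case_id: str
    mask: np.ndarray
    bbox: BoundingBox

    def __post_init__(self):
        if self.pixels.size == 0:
            raise ParameterError("empty crop")
        if self.region_tag not in ("intra", "peri", "union"):
            raise ParameterError(f"unknown region_tag {self.region_tag!r}")


def _region_masks(case, strategy: StrategyConfig) -> list[tuple[str, BinaryMask]]:
    lesion = case.mask
    if strategy.fusion == "INTRA":
        return [("intra", lesion)]
    if strategy.fusion == "DE":
        return [("union", dilate_mask(lesion, strategy.margin_mm))]
    ring = peritumoral_ring(lesion, strategy.margin_mm)
    if not ring.pixels.any():
        raise EmptyROIError("empty peritumoral ROI")
    return [("intra", lesion), ("peri", ring)]


def build_crops(case, strategy: StrategyConfig) -> list[RegionCrop]:
    """Build the crop(s) a strategy feeds to feature extraction.

    INTRA yields one crop from the lesion mask, DE one crop from the
    lesion + ring union, FLF two crops tagged ``intra`` and ``peri``. Each
    crop is framed by its defining mask's bounding box; OP zeroes pixels
    outside the mask, BB retains the full rectangle interior. Grayscale
    conversion (if requested) is applied before cropping.
    """
    image = to_grayscale(case.image) if strategy.color == "GRAY" else case.image
    crops = []
    for tag, region in _region_masks(case, strategy):
        if not region.pixels.any():
            raise EmptyROIError("empty peritumoral ROI")
        box = bounding_box(region)
        rs, cs = box.slices()
        pixels = np.array(image.pixels[rs, cs])
        region_crop = region.pixels[rs, cs]
        if strategy.roi_shape == "OP":
            pixels[~region_crop] = 0
        crops.append(
            RegionCrop(
                pixels=pixels,
                region_tag=tag,
                source_case_id=case.case_id,
                mask=region_crop,
                bbox=box,
            )
        )
    return crops


def enumerate_strategies(margins_mm=DEFAULT_MARGINS_MM) -> list[StrategyConfig]:
    """The model grid: 4 intratumoral configs plus 6 fusion configs per margin.

    The fusion block per margin is {PC,GRAY} x {BB-DE, OP-DE, OP-FLF}; BB-FLF
    is excluded by construction. An empty margin list yields only the four
    intratumoral configs.
    """
    margins = [float(m) for m in margins_mm]
    if len(set(margins)) != len(margins):
        raise ParameterError(f"duplicate margins in {list(margins_mm)!r}")
    configs = [
        StrategyConfig("PC", "BB", "INTRA"),
        StrategyConfig("PC", "OP", "INTRA"),
        StrategyConfig("GRAY", "BB", "INTRA"),
        StrategyConfig("GRAY", "OP", "INTRA"),
    ]
    for margin in margins:
        for color in COLORS:
            configs.append(StrategyConfig(color, "BB", "DE", margin))
            configs.append(StrategyConfig(color, "OP", "DE", margin))
            configs.append(StrategyConfig(color, "OP", "FLF", margin))
    return configs
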