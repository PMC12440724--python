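"""Synthetic CEUS-like cohort generator.

Clinical contrast-enhanced ultrasound cohorts are private; this module
generates labeled stand-in cases with a *known* spatial distribution of class
signal so that every downstream stage (ring geometry, crop strategies, deep
features, the selection chain, the strategy grid) can be tested end to end.

Each case is a pseudo-color rendering of an underlying intensity field on a
[0, 1] scale:

``field = base + jitter + lesion_base * lesion
        + label * (intra_contrast * lesion + peri_contrast * rim)
        + texture (malignant, in-lesion) + smoothed speckle-like noise``

so that, before noise, the malignant-vs-benign difference is *exactly* zero
outside the lesion and the true peritumoral rim. ``jitter`` is a slowly
varying gain field (4 mm correlation length, sd ``0.5 * noise_sd``) that
emulates exam-to-exam and across-the-field gain/attenuation variation: it is
what keeps a plain in-lesion mean from being a perfect classifier at
realistic noise levels, and because it decorrelates over a few millimetres,
tissue far from the lesion is a poor gain reference — over-expanded
peritumoral crops gain no free normalization signal. All noise terms vanish
when ``noise_sd`` is 0, so the exact-confinement invariants hold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .geometry import dilate_mask
from .images import BinaryMask, CalibratedImage, rec601_luminance

#: Tissue background level and lesion enhancement, on the [0, 1] field scale.
BASE_LEVEL = 0.35
LESION_BASE_CONTRAST = 0.25
#: Low-frequency radial boundary perturbation amplitude (fraction of radius);
#: the clearance check budgets for a 1.35x worst-case radius.
BOUNDARY_PERTURB_AMP = 0.10
RADIUS_SAFETY_FACTOR = 1.35
#: Slowly varying gain field: sd as a fraction of noise_sd, correlation in mm.
GAIN_FIELD_FRAC = 0.5
GAIN_FIELD_SIGMA_MM = 4.0
#: Gaussian smoothing sigmas (pixels) for speckle-like noise and texture.
NOISE_SMOOTH_SIGMA = 1.2
TEXTURE_SMOOTH_SIGMA = 2.0


def _colormap_sepia(v: np.ndarray) -> np.ndarray:
    return _luminance_exact_map(v, chroma=np.array([1.0, 0.0, 0.0]))


def _colormap_ocean(v: np.ndarray) -> np.ndarray:
    return _luminance_exact_map(v, chroma=np.array([0.0, 0.0, 1.0]))


def _colormap_verdant(v: np.ndarray) -> np.ndarray:
    return _luminance_exact_map(v, chroma=np.array([0.0, 1.0, 0.0]))


def _luminance_exact_map(v: np.ndarray, chroma: np.ndarray) -> np.ndarray:
    """Map gray levels in [0,1] to RGB whose Rec.601 luminance equals v.

    The chroma direction is projected orthogonal to the luma axis, so adding
    it leaves luminance untouched; its amplitude 0.8*v*(1-v) keeps every
    channel inside [0, 1].
    """
    weights = np.array([0.299, 0.587, 0.114])
    direction = chroma - float(chroma @ weights)
    amp = 0.8 * v * (1.0 - v)
    return np.clip(v[..., None] + amp[..., None] * direction, 0.0, 1.0)


COLORMAPS = {
    "sepia": _colormap_sepia,
    "ocean": _colormap_ocean,
    "verdant": _colormap_verdant,
}


def render_pseudo_color(gray_image: CalibratedImage, colormap_id: str) -> CalibratedImage:
    """Render a single-channel image as a 3-channel pseudo-color image.

    The mapping is pointwise and monotone in luminance: converting the output
    back to grayscale with Rec.601 weights recovers the input clipped to
    [0, 1], so intensity rank order is preserved.
    """
    if gray_image.n_channels != 1:
        raise ParameterError("render_pseudo_color expects a single-channel image")
    if colormap_id not in COLORMAPS:
        raise ParameterError(
            f"unknown colormap_id {colormap_id!r}; available: {sorted(COLORMAPS)}"
        )
    v = np.clip(np.asarray(gray_image.pixels, dtype=float), 0.0, 1.0)
    rgb = COLORMAPS[colormap_id](v)
    return CalibratedImage(rgb, gray_image.spacing_mm)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic cohort.

    All widths are millimetres, converted through ``pixel_spacing_mm``.
    ``true_rim_width_mm`` is the band beyond which the peritumoral class
    signal is exactly zero; contrasts are additive class mean-intensity
    offsets on the [0, 1] field scale.
    """

    n_cases: int = 400
    malignant_fraction: float = 0.5
    image_size: int = 128
    pixel_spacing_mm: float = 0.25
    lesion_radius_range_mm: tuple[float, float] = (3.0, 6.0)
    intratumoral_contrast: float = 0.15
    peritumoral_contrast: float = 0.15
    true_rim_width_mm: float = 4.0
    noise_sd: float = 0.25
    texture_heterogeneity: float = 0.05
    colormap_id: str = "sepia"

    def __post_init__(self):
        if self.n_cases < 1:
            raise ParameterError("n_cases must be positive")
        if not 0.0 < self.malignant_fraction < 1.0:
            raise ParameterError("malignant_fraction must lie in (0, 1)")
        if self.pixel_spacing_mm <= 0:
            raise ParameterError("pixel_spacing_mm must be positive")
        lo, hi = self.lesion_radius_range_mm
        if not 0 < lo <= hi:
            raise ParameterError("lesion_radius_range_mm must satisfy 0 < min <= max")
        if self.true_rim_width_mm < 0 or self.noise_sd < 0 or self.texture_heterogeneity < 0:
            raise ParameterError("widths, noise_sd and texture_heterogeneity are nonnegative")
        if self.colormap_id not in COLORMAPS:
            raise ParameterError(
                f"unknown colormap_id {self.colormap_id!r}; available: {sorted(COLORMAPS)}"
            )
        self._check_clearance()

    def _check_clearance(self) -> None:
        # The lesion (with worst-case boundary perturbation) plus the true rim
        # must fit with >= 2 mm clearance from the image border.
        half_extent_mm = self.image_size * self.pixel_spacing_mm / 2.0
        need = (
            self.lesion_radius_range_mm[1] * RADIUS_SAFETY_FACTOR
            + self.true_rim_width_mm
            + 2.0
        )
        if need > half_extent_mm:
            raise ParameterError(
                "lesion cannot fit in image: requires "
                f"{need:.2f} mm (max radius x {RADIUS_SAFETY_FACTOR} + rim "
                f"{self.true_rim_width_mm} mm + 2 mm clearance) but the image "
                f"half-extent is {half_extent_mm:.2f} mm"
            )


@dataclass(frozen=True)
class SyntheticCase:
    """One synthetic lesion: pseudo-color image, mask, label, optional loop."""

    case_id: str
    image: CalibratedImage
    mask: BinaryMask
    label: int
    frames: tuple[CalibratedImage, ...] | None = None
    true_peak_index: int | None = None

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ParameterError(f"label must be 0 (benign) or 1 (malignant), got {self.label}")
        if not self.mask.pixels.any():
            raise ParameterError("mask must be nonempty")
        self.mask.check_register(self.image)
        if (self.frames is None) != (self.true_peak_index is None):
            raise ParameterError("frames and true_peak_index must be set together")
        if self.frames is not None and not 0 <= self.true_peak_index < len(self.frames):
            raise ParameterError("true_peak_index out of range")


def _lesion_mask(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """An irregular ellipse: random axes/orientation plus low-frequency
    radial perturbation, so that bounding-box and precise-ROI crops differ."""
    n = spec.image_size
    s = spec.pixel_spacing_mm
    half_mm = n * s / 2.0
    lo, hi = spec.lesion_radius_range_mm
    a_mm = rng.uniform(lo, hi)
    b_mm = rng.uniform(lo, hi)
    orientation = rng.uniform(0.0, np.pi)
    # Harmonics 2..4 of the boundary angle, bounded so the worst-case radius
    # stays under RADIUS_SAFETY_FACTOR * max(a, b).
    coefs = rng.normal(0.0, 1.0, size=(3, 2))
    margin = half_mm - (max(a_mm, b_mm) * RADIUS_SAFETY_FACTOR + spec.true_rim_width_mm + 2.0)
    center_mm = rng.uniform(-margin, margin, size=2) if margin > 0 else np.zeros(2)

    rows = (np.arange(n) - (n - 1) / 2.0) * s
    dy = rows[:, None] - center_mm[0]
    dx = rows[None, :] - center_mm[1]
    cos_t, sin_t = np.cos(orientation), np.sin(orientation)
    u = dy * cos_t + dx * sin_t
    v = -dy * sin_t + dx * cos_t
    phi = np.arctan2(v, u)
    perturb = np.ones_like(phi)
    for k, (c, sn) in zip((2, 3, 4), coefs):
        perturb += BOUNDARY_PERTURB_AMP / 3.0 * (c * np.cos(k * phi) + sn * np.sin(k * phi))
    perturb = np.clip(perturb, 0.6, RADIUS_SAFETY_FACTOR)
    return (u / a_mm) ** 2 + (v / b_mm) ** 2 <= perturb**2


def _smoothed_noise(rng: np.random.Generator, shape, sigma: float, sd: float) -> np.ndarray:
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    std = raw.std()
    if std == 0:
        return np.zeros(shape)
    return raw * (sd / std)


def generate_cohort(spec: CohortSpec, seed: int) -> list[SyntheticCase]:
    """Generate a labeled cohort; a pure function of ``(spec, seed)``.

    Exactly ``round(n_cases * malignant_fraction)`` cases are malignant, in a
    seeded shuffled order. The malignant-class signal is additive inside the
    lesion (``intratumoral_contrast``) and inside the ring of width
    ``true_rim_width_mm`` (``peritumoral_contrast``) and exactly zero
    elsewhere before noise.
    """
    root = np.random.SeedSequence(seed)
    children = root.spawn(spec.n_cases + 1)
    label_rng = np.random.default_rng(children[0])
    n_mal = int(np.floor(spec.n_cases * spec.malignant_fraction + 0.5))
    labels = np.zeros(spec.n_cases, dtype=int)
    labels[:n_mal] = 1
    labels = labels[label_rng.permutation(spec.n_cases)]

    spacing = (spec.pixel_spacing_mm, spec.pixel_spacing_mm)
    cases = []
    for i in range(spec.n_cases):
        rng = np.random.default_rng(children[i + 1])
        lesion = _lesion_mask(spec, rng)
        mask = BinaryMask(lesion, spacing)
        if spec.true_rim_width_mm > 0:
            rim = dilate_mask(mask, spec.true_rim_width_mm).pixels & ~lesion
        else:
            rim = np.zeros_like(lesion)

        label = int(labels[i])
        field = np.full(lesion.shape, BASE_LEVEL)
        if spec.noise_sd > 0:
            field += _smoothed_noise(
                rng,
                lesion.shape,
                GAIN_FIELD_SIGMA_MM / spec.pixel_spacing_mm,
                GAIN_FIELD_FRAC * spec.noise_sd,
            )
        field[lesion] += LESION_BASE_CONTRAST
        if label == 1:
            field[lesion] += spec.intratumoral_contrast
            field[rim] += spec.peritumoral_contrast
            if spec.texture_heterogeneity > 0:
                tex = _smoothed_noise(
                    rng, lesion.shape, TEXTURE_SMOOTH_SIGMA, spec.texture_heterogeneity
                )
                field[lesion] += tex[lesion]
        if spec.noise_sd > 0:
            field += _smoothed_noise(rng, lesion.shape, NOISE_SMOOTH_SIGMA, spec.noise_sd)

        gray = CalibratedImage(field, spacing)
        image = render_pseudo_color(gray, spec.colormap_id)
        cases.append(SyntheticCase(case_id=f"case_{i:04d}", image=image, mask=mask, label=label))
    return cases


def make_dynamic_loop(
    case: SyntheticCase, n_frames: int, peak_index: int, seed: int
) -> SyntheticCase:
    """Attach a dynamic frame sequence with a known peak-enhancement frame.

    The in-lesion enhancement is scaled over time by a gamma-variate-like
    unimodal curve with its strict maximum at ``peak_index``; out-of-mask
    pixels receive small per-frame noise so frames differ realistically while
    the in-mask time-intensity curve stays exactly unimodal.
    """
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    if not 0 <= peak_index < n_frames:
        raise ParameterError(
            f"peak_index must lie in [0, {n_frames - 1}], got {peak_index}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, n_frames, peak_index]))
    gray = rec601_luminance(case.image.pixels)
    m = case.mask.pixels
    bg_level = float(gray[~m].mean()) if (~m).any() else 0.0

    # Gamma-variate-like wash-in/wash-out, normalized to 1 at the peak.
    t = np.arange(n_frames, dtype=float)
    tau = (t + 1.0) / (peak_index + 1.0)
    curve = tau**2.0 * np.exp(2.0 * (1.0 - tau))

    frames = []
    for ct in curve:
        f = gray.copy()
        f[m] = bg_level + ct * (gray[m] - bg_level)
        out_noise = rng.normal(0.0, 0.01, size=f.shape)
        f[~m] += out_noise[~m]
        frames.append(
            render_pseudo_color(CalibratedImage(f, case.image.spacing_mm), "sepia")
        )
    return dataclasses.replace(case, frames=tuple(frames), true_peak_index=peak_index)
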