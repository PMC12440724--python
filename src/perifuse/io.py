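"""Cohort directory layout: PNG images + masks with a CSV manifest.

Layout written by :func:`write_cohort`::

    <root>/manifest.csv        case_id, image_path, mask_path, label, spacing_mm
    <root>/images/<id>.png     8-bit RGB pseudo-color image
    <root>/masks/<id>.png      8-bit mask, 0/255

Single cases can also be loaded from PNG/JPEG (spacing supplied by the
caller) or DICOM (spacing read from the PixelSpacing tag).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .errors import ParameterError
from .images import BinaryMask, CalibratedImage
from .synthetic import CohortSpec, SyntheticCase


def write_cohort(cases: list[SyntheticCase], root: str | Path) -> Path:
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        image_path = root / "images" / f"{case.case_id}.png"
        mask_path = root / "masks" / f"{case.case_id}.png"
        rgb = np.clip(case.image.pixels, 0.0, 1.0)
        Image.fromarray((rgb * 255).round().astype(np.uint8)).save(image_path)
        Image.fromarray(np.where(case.mask.pixels, 255, 0).astype(np.uint8)).save(mask_path)
        rows.append(
            {
                "case_id": case.case_id,
                "image_path": str(image_path.relative_to(root)),
                "mask_path": str(mask_path.relative_to(root)),
                "label": case.label,
                "spacing_mm": case.image.spacing_mm[0],
            }
        )
    manifest = root / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(root: str | Path) -> list[SyntheticCase]:
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv")
    cases = []
    for row in manifest.itertuples():
        image, mask = load_case(
            root / row.image_path, root / row.mask_path, spacing_mm=row.spacing_mm
        )
        cases.append(
            SyntheticCase(case_id=str(row.case_id), image=image, mask=mask, label=int(row.label))
        )
    return cases


def _read_image_array(path: Path, spacing_mm) -> tuple[np.ndarray, float | None]:
    if path.suffix.lower() == ".dcm":
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(np.float32)
        arr = arr / max(float(arr.max()), 1.0)
        spacing = float(ds.PixelSpacing[0]) if "PixelSpacing" in ds else None
        return arr, spacing
    arr = np.asarray(Image.open(path)).astype(np.float32) / 255.0
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr, None


def load_case(
    image_path: str | Path, mask_path: str | Path, spacing_mm: float | None = None
) -> tuple[CalibratedImage, BinaryMask]:
    """Load one image/mask pair from PNG/JPEG/DICOM in pixel register."""
    image_arr, file_spacing = _read_image_array(Path(image_path), spacing_mm)
    spacing = spacing_mm if spacing_mm is not None else file_spacing
    if spacing is None:
        raise ParameterError(
            f"no pixel spacing available for {image_path}: pass spacing_mm or use "
            "DICOM with a PixelSpacing tag"
        )
    mask_arr = np.asarray(Image.open(mask_path).convert("L"))
    image = CalibratedImage(image_arr, spacing)
    mask = BinaryMask(mask_arr > 127, spacing)
    mask.check_register(image)
    return image, mask


def load_cohort_spec(path: str | Path) -> CohortSpec:
    """Read a cohort spec from a YAML or JSON config file."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParameterError(f"cohort spec file {path} must hold a mapping")
    if "lesion_radius_range_mm" in raw:
        raw["lesion_radius_range_mm"] = tuple(raw["lesion_radius_range_mm"])
    return CohortSpec(**raw)
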