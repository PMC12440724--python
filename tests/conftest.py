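import numpy as np
import pytest

import perifuse as pf


@pytest.fixture(scope="session")
def small_spec():
    """A compact cohort spec used across tests (96 px at 0.3 mm/px)."""
    return pf.CohortSpec(
        n_cases=16,
        image_size=96,
        pixel_spacing_mm=0.3,
        lesion_radius_range_mm=(3.0, 5.0),
        true_rim_width_mm=4.0,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return pf.generate_cohort(small_spec, seed=7)


@pytest.fixture(scope="session")
def noise_free_spec(small_spec):
    import dataclasses

    return dataclasses.replace(small_spec, n_cases=12, noise_sd=0.0, texture_heterogeneity=0.0)


@pytest.fixture(scope="session")
def noise_free_cohort(noise_free_spec):
    return pf.generate_cohort(noise_free_spec, seed=11)


def make_crop(pixels, region_tag="intra", mask=None):
    """A RegionCrop around a bare pixel array, for backbone-level tests."""
    pixels = np.asarray(pixels)
    if mask is None:
        mask = np.ones(pixels.shape[:2], dtype=bool)
    h, w = pixels.shape[:2]
    return pf.RegionCrop(
        pixels=pixels,
        region_tag=region_tag,
        source_case_id="synthetic",
        mask=mask,
        bbox=pf.BoundingBox(0, h - 1, 0, w - 1),
    )
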