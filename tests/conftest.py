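"""Shared fixtures: small, fast phantoms and the full-size study phantom.

All fixtures are deterministic (fixed seeds) and generated at run time;
no data files are stored.
"""

import numpy as np
import pytest

from speleoclean import cleaning, surface
from speleoclean.phantom import PhantomSpec, generate_phantom, simulate_reader


SMALL_SPEC = PhantomSpec(
    shaft_radius=6.0,
    shaft_length=30.0,
    head_radius=7.0,
    neck_radius=4.0,
    neck_length=5.0,
    head_offset=6.0,
    trochanter_bump_radius=5.0,
    trochanter_offset=8.0,
    crust_thickness_mean=2.5,
    crust_thickness_sd=0.6,
    spacing=(0.5, 0.5, 1.0),
    seed=1,
)


@pytest.fixture(scope="session")
def small_truth():
    """A coarse, fast phantom for unit-level pipeline tests."""
    return generate_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def default_truth():
    """The full-size phantom at the default (study) conditions."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def small_cleaned_mesh(small_truth):
    """Largest-component isosurface of the virtually cleaned small phantom
    segmented from its own truth mask (zero reader noise)."""
    truth = small_truth
    template = cleaning.erase_masked(truth.volume, truth.bone_mask)
    cleaned = cleaning.subtract_template(truth.volume, template)
    iso = surface.default_iso_hu(cleaned, cleaning.DEFAULT_BACKGROUND_HU)
    return surface.largest_component(surface.extract_isosurface(cleaned, iso))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
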