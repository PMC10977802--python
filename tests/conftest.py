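"""Shared fixtures; the expensive acoustic templates are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from hifusim.acoustic import AcousticMedium, discretize_bowl
from hifusim.phantom import generate_phantom
from hifusim.sonication import DEFAULT_BOWL, focal_intensity_template


@pytest.fixture(scope="session")
def water_lossless():
    return AcousticMedium(c_m_s=1482.0, rho_kg_m3=994.0, alpha_db_cm_mhz=0.0)


@pytest.fixture(scope="session")
def small_bowl():
    """Desk-scale bowl (F = 40 mm, a = 15 mm, 1 MHz) for fast field tests."""
    return discretize_bowl(40.0, 15.0, 1.0)


@pytest.fixture(scope="session")
def default_bowl():
    """The default abdominal-HIFU geometry (F = 130 mm, a = 64 mm)."""
    return discretize_bowl(frequency_mhz=1.0, **DEFAULT_BOWL)


@pytest.fixture(scope="session")
def adeno_phantom():
    """Default-grid adenomyosis phantom (0.5 mm voxels)."""
    return generate_phantom(
        (28.0, 28.0, 40.0), 0.5, (8.0, 8.0, 12.0), "adenomyosis-myometrium"
    )


@pytest.fixture(scope="session")
def fibroid_phantom():
    return generate_phantom(
        (28.0, 28.0, 40.0), 0.5, (8.0, 8.0, 12.0), "fibroid-muscle"
    )


@pytest.fixture(scope="session")
def default_template(default_bowl, adeno_phantom):
    """Normalized focal-intensity template of the default bowl on the
    default phantom grid (shared: this is the expensive acoustic solve)."""
    return focal_intensity_template(default_bowl, adeno_phantom, 1.0)


@pytest.fixture(scope="session")
def small_phantom():
    """Small phantom for fast bioheat-coupled tests."""
    return generate_phantom(
        (20.0, 20.0, 28.0), 0.5, (4.0, 4.0, 6.0), "adenomyosis-myometrium"
    )


@pytest.fixture(scope="session")
def small_template(small_phantom, default_bowl):
    return focal_intensity_template(default_bowl, small_phantom, 1.0)
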