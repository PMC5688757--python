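"""Shared fixtures: small lattices and rendered images reused across tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from retinamech import mosaic_model as mm
from retinamech import synthetic_data as sd

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lattice():
    """3 columns x 4 repeat units, cones only, default geometry."""
    return mm.generate_mosaic_lattice(n_columns=3, n_repeat_units=4, spacing=5.0)


@pytest.fixture(scope="session")
def lattice_rods():
    return mm.generate_mosaic_lattice(
        n_columns=3, n_repeat_units=4, spacing=5.0, include_rods=True
    )


@pytest.fixture(scope="session")
def membrane_stack(lattice):
    """Noise-free ZO1 membrane z-stack with a flat OLM at 9 um."""
    return sd.render_zstack(
        lattice,
        {"mode": "flat", "params": {"z0": 9.0}},
        {"ZO1": sd.ChannelSpec("membrane")},
        pixel_size=0.5,
    )


@pytest.fixture(scope="session")
def band_image_lattice():
    """4 columns -> 3 inter-column glial bands, columns along +y."""
    return mm.generate_mosaic_lattice(n_columns=4, n_repeat_units=5, spacing=5.0)


@pytest.fixture(scope="session")
def band_image(band_image_lattice):
    return sd.render_glial_band_image(
        band_image_lattice, band_width_px=8, lamella_width_px=2, pixel_size=0.5
    )


def line_image(angle_deg: float, shape=(96, 96), width: float = 8.0) -> np.ndarray:
    """A single straight bright ridge through the image centre."""
    gy, gx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = (shape[0] - 1) / 2, (shape[1] - 1) / 2
    th = np.radians(angle_deg)
    # signed distance to the line through the centre at angle_deg
    d = -(gx - cx) * np.sin(th) + (gy - cy) * np.cos(th)
    return np.exp(-(d**2) / (2 * (width / 2.355) ** 2))
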