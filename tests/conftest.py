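"""Shared fixtures: small geometries and volumes for fast unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from nanoct.geometry import ScanGeometry

# detector pitch chosen so the effective pixel at the rotation axis is
# exactly 1 um for the whole-body distances (desk-scale convention)
UNIT_PITCH = 450.0 / 0.71


def small_geometry(
    detector=(48, 48), n_angles=20, source_fwhm=0.0, pitch=UNIT_PITCH
) -> ScanGeometry:
    return ScanGeometry(
        sod=0.71, sdd=450.0, detector_shape=detector,
        detector_pitch=pitch, n_angles=n_angles, source_fwhm=source_fwhm,
    )


@pytest.fixture
def geom_small() -> ScanGeometry:
    return small_geometry()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def sphere_volume(n: int, radius: float, mu0: float = 0.01) -> np.ndarray:
    zz, yy, xx = np.indices((n, n, n))
    c = (n - 1) / 2.0
    r = np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2)
    return np.where(r <= radius, mu0, 0.0)


def gaussian_blob(n: int, widths=(6.0, 4.5, 3.5), amp: float = 0.02) -> np.ndarray:
    """Smooth test volume (no sharp edges, so interpolation-scheme
    differences stay second order)."""
    zz, yy, xx = np.indices((n, n, n), dtype=float)
    c = (n - 1) / 2.0
    return amp * np.exp(
        -(((zz - c) / widths[0]) ** 2 + ((yy - c) / widths[1]) ** 2
          + ((xx - c) / widths[2]) ** 2)
    )
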