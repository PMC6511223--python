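"""Cone-beam scan geometry and projection-data containers.

A laboratory nanoCT system magnifies the sample purely geometrically: an
X-ray point source illuminates the specimen and the shadow image is
recorded on a flat detector.  The magnification is the ratio of the
source-to-detector distance (SDD) to the source-to-rotation-axis distance
(SOD), and the effective voxel size of a reconstruction on a matched grid
is the detector pitch divided by that magnification.

Coordinate conventions
----------------------
Volumes are indexed ``(z, y, x)`` with axis 0 the rotation axis (for the
micro-animal phantom this is the anterior-posterior axis).  World
coordinates are in micrometres, centred on the rotation axis with the
volume centre at the origin; voxel ``i`` along an axis of length ``n``
sits at ``(i - (n - 1) / 2) * voxel_size``.  At rotation angle ``theta``
the source lies at ``-sod * u(theta)`` in the horizontal ``(y, x)`` plane
with ``u = (cos t, sin t)``, and the detector plane is perpendicular to
``u`` at distance ``sdd`` from the source, spanned by
``t = (-sin t, cos t)`` (columns) and ``z`` (rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "ScanGeometry",
    "ProjectionSet",
    "FlatField",
    "magnification",
    "effective_voxel_size",
    "implied_voxel_size",
    "WHOLE_BODY_GEOMETRY",
    "HEAD_GEOMETRY",
    "desk_geometry",
]

Domain = Literal["line_integral", "counts", "transmission", "log"]


@dataclass(frozen=True)
class ScanGeometry:
    """Cone-beam acquisition geometry.

    Parameters
    ----------
    sod : float
        Source-to-rotation-axis distance in mm.
    sdd : float
        Source-to-detector distance in mm.
    detector_shape : tuple of int
        Detector size as ``(rows, cols)``; rows run along the rotation
        axis, columns along the fan direction.
    detector_pitch : float
        Detector pixel pitch in micrometres.
    n_angles : int
        Number of projection angles.
    angle_range_deg : float
        Angular range covered by the scan (default full 360 degrees).
    source_fwhm : float
        FWHM of the Gaussian X-ray source spot in nanometres.
    """

    sod: float
    sdd: float
    detector_shape: tuple[int, int] = (256, 256)
    detector_pitch: float = 172.0
    n_angles: int = 1599
    angle_range_deg: float = 360.0
    source_fwhm: float = 500.0

    def __post_init__(self) -> None:
        if not 0 < self.sod < self.sdd:
            raise ValueError(f"require 0 < sod < sdd, got sod={self.sod}, sdd={self.sdd}")
        if self.n_angles < 1:
            raise ValueError(f"n_angles must be >= 1, got {self.n_angles}")
        if self.detector_pitch <= 0:
            raise ValueError(f"detector_pitch must be > 0, got {self.detector_pitch}")

    @property
    def magnification(self) -> float:
        return self.sdd / self.sod

    @property
    def pixel_size_iso(self) -> float:
        """Detector pitch demagnified to the rotation-axis plane, in um."""
        return self.detector_pitch / self.magnification

    @property
    def angles_deg(self) -> np.ndarray:
        """Evenly spaced view angles over [0, angle_range_deg), first at 0."""
        return np.arange(self.n_angles) * (self.angle_range_deg / self.n_angles)

    @property
    def source_fwhm_detector_px(self) -> float:
        """Detector-plane FWHM of the source blur, in detector pixels.

        A source spot of FWHM ``s`` produces a penumbra of width
        ``s * (M - 1)`` on the detector for an object at the rotation
        axis, i.e. approximately ``s`` in object units when M >> 1.
        """
        fwhm_um = self.source_fwhm * 1e-3 * (self.magnification - 1.0)
        return fwhm_um / self.detector_pitch


def magnification(geom: ScanGeometry) -> float:
    """Geometrical magnification M = SDD / SOD."""
    return geom.magnification


def effective_voxel_size(geom: ScanGeometry) -> float:
    """Effective (demagnified) voxel size in nanometres: pitch / M."""
    return geom.detector_pitch * 1e3 / geom.magnification


def implied_voxel_size(voxel_nm: float, geom_from: ScanGeometry, geom_to: ScanGeometry) -> float:
    """Voxel size (nm) of a second scan geometry implied by a first.

    With the same detector, voxel sizes scale inversely with the
    magnification: ``voxel_to = voxel_from * M_from / M_to``.
    """
    return voxel_nm * geom_from.magnification / geom_to.magnification


@dataclass
class ProjectionSet:
    """A stack of 2D projections with their view angles.

    ``data`` has shape ``(n_angles, rows, cols)``.  ``domain`` tracks the
    physical meaning of the pixel values: ideal line integrals of the
    attenuation coefficient, raw photon counts, flat-field-normalised
    transmission, or negative-log (Beer-Lambert inverted) data.
    """

    data: np.ndarray
    angles_deg: np.ndarray
    domain: Domain
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"projection data must be 3D, got shape {self.data.shape}")
        if self.data.shape[0] != self.angles_deg.shape[0]:
            raise ValueError(
                f"{self.data.shape[0]} projections but {self.angles_deg.shape[0]} angles"
            )
        if self.domain == "counts" and np.any(self.data < 0):
            raise ValueError("counts domain requires nonnegative data")
        if self.domain == "transmission" and np.any(self.data <= 0):
            raise ValueError("transmission domain requires strictly positive data")

    @property
    def n_angles(self) -> int:
        return self.data.shape[0]

    def with_data(self, data: np.ndarray, domain: Domain | None = None) -> "ProjectionSet":
        return ProjectionSet(
            data=data,
            angles_deg=self.angles_deg,
            domain=domain if domain is not None else self.domain,
            geometry=self.geometry,
        )


@dataclass
class FlatField:
    """Detector illumination image acquired without the sample."""

    image: np.ndarray
    mean_flux: float = field(init=False)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if np.any(self.image <= 0):
            raise ValueError("flat field must be strictly positive everywhere")
        self.mean_flux = float(self.image.mean())

    @classmethod
    def uniform(cls, shape: tuple[int, int], flux: float) -> "FlatField":
        return cls(image=np.full(shape, float(flux)))


# Instrument geometries the defaults emulate: a whole-body scan at
# SOD 0.71 mm / SDD 450 mm and a head re-scan at 0.61 mm / 520 mm, both
# with 1599 projections over 360 degrees on a 172-um-pitch photon
# counting detector (yielding ~270 nm and ~200 nm effective voxels).
WHOLE_BODY_GEOMETRY = ScanGeometry(sod=0.71, sdd=450.0, detector_pitch=172.0, n_angles=1599)
HEAD_GEOMETRY = ScanGeometry(sod=0.61, sdd=520.0, detector_pitch=172.0, n_angles=1599)


def desk_geometry(
    head: bool = False,
    detector_shape: tuple[int, int] = (256, 256),
    n_angles: int = 240,
    source_fwhm: float = 500.0,
) -> ScanGeometry:
    """Down-scaled geometry for desk-size experiments.

    Keeps the instrument's source/detector distances but opens the
    detector pitch so the whole-body scan has an effective pixel of
    exactly 1.0 um at the rotation axis (the head geometry then lands at
    ~0.74 um, preserving the instrument's resolution ratio).
    """
    base = HEAD_GEOMETRY if head else WHOLE_BODY_GEOMETRY
    pitch = WHOLE_BODY_GEOMETRY.magnification * 1.0
    return replace(
        base,
        detector_shape=detector_shape,
        detector_pitch=pitch,
        n_angles=n_angles,
        source_fwhm=source_fwhm,
    )
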