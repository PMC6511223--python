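"""Cone-beam forward/back projection and photon-count simulation.

``forward_project`` and ``back_project`` form an exact adjoint pair
(same Joseph interpolation weights), which the statistical iterative
reconstruction relies on for its gradients.  ``apply_source_blur``
models the finite X-ray spot as a Gaussian in the detector plane, and
``simulate_counts`` applies the Beer-Lambert law with Poisson counting
statistics against a flat-field illumination.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from . import _kernels
from .geometry import FlatField, ProjectionSet, ScanGeometry
from .volumes import ReconVolume

__all__ = [
    "forward_project",
    "back_project",
    "apply_source_blur",
    "simulate_counts",
    "simulate_scan",
    "stitch_vertical",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _check_field_of_view(shape: tuple[int, int, int], voxel: float, geom: ScanGeometry) -> None:
    nz, ny, nx = shape
    half_diag = 0.5 * voxel * float(np.hypot(ny, nx))
    sod_um = geom.sod * 1e3
    if half_diag >= sod_um:
        raise ValueError(
            f"volume horizontal half-diagonal {half_diag:.1f} um reaches the source "
            f"(sod {sod_um:.1f} um)"
        )
    nr, nc = geom.detector_shape
    # exact fan condition: tangent ray to the bounding cylinder of radius
    # half_diag; vertical: top rim of the cylinder seen at the near edge
    u_iso_max = sod_um * half_diag / np.sqrt(sod_um**2 - half_diag**2)
    v_iso_max = 0.5 * nz * voxel * sod_um / (sod_um - half_diag)
    pitch_iso = geom.detector_pitch * geom.sod / geom.sdd
    if u_iso_max > 0.5 * nc * pitch_iso or v_iso_max > 0.5 * nr * pitch_iso:
        raise ValueError(
            "volume exceeds the detector field of view at this magnification; "
            "reduce the grid or scan in vertical tiles (stitch_vertical)"
        )


def forward_project(
    mu: np.ndarray | ReconVolume,
    geom: ScanGeometry,
    voxel_size: float | None = None,
) -> ProjectionSet:
    """Cone-beam line integrals of an attenuation volume.

    Every detector pixel receives the integral of ``mu`` (1/um) along
    the ray from the point source through the pixel centre, for each
    view angle.  Linear in ``mu``.
    """
    if isinstance(mu, ReconVolume):
        voxel_size = mu.voxel_size
        mu = mu.data
    if voxel_size is None:
        raise ValueError("voxel_size must be given when mu is a bare array")
    mu = np.ascontiguousarray(mu, dtype=np.float64)
    _check_field_of_view(mu.shape, voxel_size, geom)
    nr, nc = geom.detector_shape
    angles = np.deg2rad(geom.angles_deg)
    out = np.empty((geom.n_angles, nr, nc), dtype=np.float64)
    _kernels.joseph_forward(
        mu, float(voxel_size), geom.sod * 1e3, geom.sdd * 1e3,
        float(geom.detector_pitch), nr, nc, angles, out,
    )
    return ProjectionSet(data=out, angles_deg=geom.angles_deg, domain="line_integral", geometry=geom)


def back_project(
    p: ProjectionSet,
    grid_shape: tuple[int, int, int],
    voxel_size: float,
) -> np.ndarray:
    """Exact adjoint of :func:`forward_project` (unfiltered backprojection)."""
    if p.domain not in ("line_integral", "log"):
        raise ValueError(f"back_project expects line_integral or log domain, got {p.domain}")
    geom = p.geometry
    if p.data.shape[1:] != tuple(geom.detector_shape):
        raise ValueError("projection shape does not match geometry detector_shape")
    nz, ny, nx = grid_shape
    data = np.ascontiguousarray(p.data, dtype=np.float64)
    angles = np.deg2rad(p.angles_deg)
    out = np.empty((nz, ny, nx), dtype=np.float64)
    _kernels.joseph_adjoint(
        data, float(voxel_size), geom.sod * 1e3, geom.sdd * 1e3,
        float(geom.detector_pitch), nz, ny, nx, angles, out,
    )
    return out


def apply_source_blur(p: ProjectionSet, geom: ScanGeometry | None = None) -> ProjectionSet:
    """Blur each projection with the detector-plane source Gaussian.

    The finite source spot (FWHM ``geom.source_fwhm`` nm in the object
    plane) casts a penumbra of FWHM ``source_fwhm * (M - 1)`` on the
    detector.  Flux-preserving (reflective boundaries, normalised
    kernel); identity when the FWHM is zero.
    """
    if p.domain not in ("line_integral", "transmission"):
        raise ValueError(f"source blur applies to line_integral or transmission, got {p.domain}")
    geom = geom or p.geometry
    sigma_px = geom.source_fwhm_detector_px * _FWHM_TO_SIGMA
    if sigma_px == 0.0:
        return p
    blurred = np.empty_like(p.data, dtype=float)
    for i in range(p.n_angles):
        ndimage.gaussian_filter(p.data[i], sigma=sigma_px, mode="reflect", output=blurred[i])
    return p.with_data(blurred)


def simulate_counts(
    p: ProjectionSet,
    flat: FlatField,
    seed: int | np.random.Generator | None = None,
    stochastic: bool = True,
) -> ProjectionSet:
    """Photon counts for projections under Beer-Lambert + Poisson.

    Expected counts are ``flat * exp(-p)`` for line-integral input, or
    ``flat * t`` for transmission input (e.g. after source blur).  With
    ``stochastic=False`` the expectation itself is returned (the
    infinite-flux limit), which makes noiseless round-trip tests exact.
    """
    if p.domain == "line_integral":
        if not np.all(np.isfinite(p.data)):
            raise ValueError("line integrals must be finite")
        lam = flat.image[None] * np.exp(-p.data)
    elif p.domain == "transmission":
        lam = flat.image[None] * p.data
    else:
        raise ValueError(f"simulate_counts expects line_integral or transmission, got {p.domain}")
    if flat.image.shape != p.data.shape[1:]:
        raise ValueError("flat-field shape does not match projections")
    if not stochastic:
        return p.with_data(lam, domain="counts")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.poisson(lam).astype(np.float64)
    return p.with_data(counts, domain="counts")


def simulate_scan(
    mu: np.ndarray | ReconVolume,
    geom: ScanGeometry,
    flux: float,
    seed: int | np.random.Generator | None = None,
    voxel_size: float | None = None,
    stochastic: bool = True,
) -> tuple[ProjectionSet, FlatField]:
    """Full acquisition: project, blur by the source spot, count photons.

    The source blur acts on the transmitted intensity (its physical
    place) before Poisson sampling.  Returns the counts and the flat
    field used.
    """
    p = forward_project(mu, geom, voxel_size=voxel_size)
    t = p.with_data(np.exp(-p.data), domain="transmission")
    t = apply_source_blur(t, geom)
    flat = FlatField.uniform(tuple(geom.detector_shape), flux)
    counts = simulate_counts(t, flat, seed=seed, stochastic=stochastic)
    return counts, flat


def stitch_vertical(
    volumes: list[np.ndarray] | list[ReconVolume],
    overlaps: int | list[int],
) -> np.ndarray | ReconVolume:
    """Blend vertically tiled scans into a single volume.

    ``volumes`` are ordered along axis 0 (anterior to posterior);
    adjacent tiles share ``overlaps`` slices, blended with a linear
    ramp.  Output height is the sum of tile heights minus the overlaps.
    """
    if len(volumes) == 0:
        raise ValueError("no volumes to stitch")
    is_recon = isinstance(volumes[0], ReconVolume)
    if is_recon:
        voxels = {v.voxel_size for v in volumes}
        if len(voxels) > 1:
            raise ValueError(f"inconsistent voxel sizes: {sorted(voxels)}")
        arrays = [v.data for v in volumes]
    else:
        arrays = [np.asarray(v) for v in volumes]
    if len(arrays) == 1:
        return volumes[0]
    n_joints = len(arrays) - 1
    if isinstance(overlaps, int):
        overlaps = [overlaps] * n_joints
    if len(overlaps) != n_joints:
        raise ValueError(f"need {n_joints} overlaps, got {len(overlaps)}")
    for v in arrays[1:]:
        if v.shape[1:] != arrays[0].shape[1:]:
            raise ValueError("tile cross-sections differ")
    out = arrays[0].astype(float)
    for v, ov in zip(arrays[1:], overlaps):
        if ov < 1 or ov > min(out.shape[0], v.shape[0]):
            raise ValueError(f"overlap {ov} invalid for tile heights {out.shape[0]}, {v.shape[0]}")
        ramp = ((np.arange(ov) + 1) / (ov + 1))[:, None, None]
        blended = out[-ov:] * (1 - ramp) + v[:ov] * ramp
        out = np.concatenate([out[:-ov], blended, v[ov:]], axis=0)
    if is_recon:
        return ReconVolume(out, volumes[0].voxel_size, provenance="stitched",
                           meta={"tiles": len(arrays), "overlaps": list(overlaps)})
    return out
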