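"""Filtered backprojection (FDK) and background-noise measurement.

The FDK algorithm reconstructs a cone-beam scan by cosine pre-weighting
each projection, ramp-filtering along detector rows, and weighted
backprojection.  It is exact in the rotation midplane and a good
approximation at the small cone angles of a nanoCT geometry.  The
background noise of the FBP volume doubles as the data-driven estimate
of the Huber transition parameter used by the statistical
reconstruction.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .geometry import ProjectionSet
from .volumes import ReconVolume

__all__ = ["ramp_filter", "fbp_reconstruct", "background_noise", "ramp_kernel"]

_WINDOWS = ("ramp", "shepp-logan", "hann")


def ramp_kernel(n: int) -> np.ndarray:
    """Dimensionless discrete ramp (Ram-Lak) kernel of length ``n``.

    ``h[0] = 1/4``, ``h[k] = -1/(pi*k)**2`` for odd lag ``k``, zero for
    even lags; lags wrap circularly so the kernel can be applied by FFT
    over a zero-padded row.
    """
    lag = np.minimum(np.arange(n), n - np.arange(n))
    h = np.zeros(n)
    h[0] = 0.25
    odd = lag % 2 == 1
    h[odd] = -1.0 / (np.pi * lag[odd]) ** 2
    return h


def _filter_response(n_pad: int, window: str) -> np.ndarray:
    H = np.fft.rfft(ramp_kernel(n_pad)).real
    H[0] = 0.0  # remove residual DC of the truncated kernel
    f = np.fft.rfftfreq(n_pad)  # cycles/sample, Nyquist = 0.5
    if window == "ramp":
        w = np.ones_like(f)
    elif window == "shepp-logan":
        w = np.sinc(f)  # sin(pi f)/(pi f); 2/pi at Nyquist
    elif window == "hann":
        w = 0.5 * (1.0 + np.cos(np.pi * f / 0.5))  # zero at Nyquist
    else:
        raise ValueError(f"unknown window {window!r}; choose from {_WINDOWS}")
    return H * w


def ramp_filter(p: ProjectionSet, window: str = "ramp") -> ProjectionSet:
    """Row-wise ramp filtering of log-domain projections.

    Filters along the detector column (fan) direction in the frequency
    domain with the chosen apodisation window.  The zero-frequency
    component is exactly zero, so constant rows map to zero.  The
    kernel is dimensionless; FDK rescales by the detector sampling.
    """
    if p.domain not in ("log", "line_integral"):
        raise ValueError(f"ramp_filter expects log/line_integral domain, got {p.domain}")
    n = p.data.shape[-1]
    n_pad = 1 << int(np.ceil(np.log2(max(2 * n, 16))))
    left = (n_pad - n) // 2
    right = n_pad - n - left
    H = _filter_response(n_pad, window)
    # edge-replicated padding: constant rows stay constant under the
    # circular filter and therefore map exactly to zero (DC bin is zero)
    padded = np.pad(p.data, [(0, 0)] * (p.data.ndim - 1) + [(left, right)], mode="edge")
    spec = np.fft.rfft(padded, axis=-1)
    filtered = np.fft.irfft(spec * H, n=n_pad, axis=-1)[..., left:left + n]
    return p.with_data(filtered)


def fbp_reconstruct(
    p: ProjectionSet,
    grid_shape: tuple[int, int, int],
    voxel_size: float,
    window: str = "shepp-logan",
) -> ReconVolume:
    """FDK cone-beam filtered backprojection.

    Cosine pre-weighting, row-wise ramp filtering with the chosen
    window, and distance-weighted backprojection onto a grid centred on
    the rotation axis.  Assumes full 360-degree coverage; fewer than a
    handful of views reconstruct poorly but are not an error.
    """
    if p.domain not in ("log", "line_integral"):
        raise ValueError(f"fbp_reconstruct expects log/line_integral domain, got {p.domain}")
    geom = p.geometry
    import warnings

    if p.n_angles >= 2 and float(np.ptp(p.angles_deg)) < 180.0 * (1 - 1.0 / p.n_angles):
        warnings.warn("angular coverage below 180 degrees; FDK result will be distorted")
    nr, nc = p.data.shape[1], p.data.shape[2]
    pitch_iso = geom.pixel_size_iso
    sod_um = geom.sod * 1e3
    # cosine weighting in isocentre-plane coordinates
    v = (np.arange(nr) - (nr - 1) / 2.0) * pitch_iso
    u = (np.arange(nc) - (nc - 1) / 2.0) * pitch_iso
    cosw = sod_um / np.sqrt(sod_um**2 + v[:, None] ** 2 + u[None, :] ** 2)
    weighted = p.with_data(p.data * cosw[None])
    filtered = ramp_filter(weighted, window=window).data / pitch_iso
    nz, ny, nx = grid_shape
    out = np.empty((nz, ny, nx), dtype=np.float64)
    angles = np.deg2rad(p.angles_deg)
    _kernels.fdk_backproject(
        np.ascontiguousarray(filtered), float(voxel_size), sod_um, geom.sdd * 1e3,
        float(geom.detector_pitch), nz, ny, nx, angles, out,
    )
    d_beta = np.deg2rad(geom.angle_range_deg) / p.n_angles
    coverage = min(geom.angle_range_deg / 360.0, 1.0)
    out *= d_beta / (2.0 * coverage) if coverage > 0 else d_beta / 2.0
    return ReconVolume(
        out, voxel_size, provenance="FBP",
        meta={"window": window, "n_angles": p.n_angles},
    )


def background_noise(
    v: ReconVolume,
    roi: tuple[slice, slice, slice],
    support: np.ndarray | None = None,
) -> float:
    """Standard deviation of gray values in a background ROI.

    ``roi`` is a (z, y, x) slice triple that must lie entirely outside
    the object; when a support mask (e.g. the phantom's body) is given,
    overlap raises an error.
    """
    if len(roi) != 3:
        raise ValueError("roi must be a (z, y, x) slice triple")
    if support is not None:
        if support.shape != v.data.shape:
            raise ValueError("support mask shape does not match volume")
        if np.any(support[roi]):
            raise ValueError("background ROI overlaps the object support")
    values = v.data[roi]
    if values.size == 0:
        raise ValueError("empty background ROI")
    return float(values.std())
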