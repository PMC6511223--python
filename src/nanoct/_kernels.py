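"""Numba kernels for cone-beam projection and backprojection.

The forward projector uses Joseph's method: each source-to-pixel ray is
parametrised by the voxel planes of its dominant horizontal axis and the
volume is sampled by bilinear interpolation in the two remaining axes.
The backprojector implemented here is the exact matrix transpose of the
forward kernel (same interpolation weights and traversal bounds, scatter
instead of gather), which is what the gradient of the statistical
reconstruction objective requires.  A separate voxel-driven kernel
performs the weighted cone-beam (FDK) backprojection used by filtered
backprojection.

Rays that miss the volume's bounding cylinder are skipped, and the
marching range along the dominant axis is clipped to the ray's
intersection with the grid; both shortcuts are shared verbatim by the
forward and adjoint kernels so the pair stays an exact transpose.

All arithmetic is float64; distances are in micrometres.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["joseph_forward", "joseph_adjoint", "fdk_backproject"]


@njit(cache=True, inline="always")
def _ray_setup(r, c, nr, nc, pitch, sod, sdd, cos_t, sin_t):
    """Source position and ray direction for detector pixel (r, c)."""
    # source in world (z, y, x); rotation axis is z through the origin
    sz = 0.0
    sy = -sod * cos_t
    sx = -sod * sin_t
    # detector pixel centre
    u = (c - (nc - 1) / 2.0) * pitch
    v = (r - (nr - 1) / 2.0) * pitch
    pz = v
    py = (sdd - sod) * cos_t + u * (-sin_t)
    px = (sdd - sod) * sin_t + u * cos_t
    return sz, sy, sx, pz - sz, py - sy, px - sx


@njit(cache=True, inline="always")
def _interval(lo, hi, s, d, t0, t1):
    """Intersect [t0, t1] with {t : lo <= s + t*d <= hi}."""
    if d > 1e-300 or d < -1e-300:
        ta = (lo - s) / d
        tb = (hi - s) / d
        if ta > tb:
            ta, tb = tb, ta
        if ta > t0:
            t0 = ta
        if tb < t1:
            t1 = tb
    elif s < lo or s > hi:
        t1 = t0 - 1.0
    return t0, t1


@njit(cache=True, inline="always")
def _march_range(sz, sy, sx, dz, dy, dx, voxel, nz, ny, nx, main_is_y, r_cyl2):
    """k-range of voxel planes along the dominant axis where the ray can
    touch the grid; (1, 0) when the ray misses entirely."""
    # bounding-cylinder test in the horizontal plane
    dd = dy * dy + dx * dx
    cross = sy * dx - sx * dy
    if cross * cross > r_cyl2 * dd:
        return 1, 0
    # half-extents with one voxel of bilinear margin
    hz = (nz - 1) / 2.0 * voxel + voxel
    hy = (ny - 1) / 2.0 * voxel + voxel
    hx = (nx - 1) / 2.0 * voxel + voxel
    t0, t1 = 0.0, 1.0e300
    t0, t1 = _interval(-hz, hz, sz, dz, t0, t1)
    t0, t1 = _interval(-hy, hy, sy, dy, t0, t1)
    t0, t1 = _interval(-hx, hx, sx, dx, t0, t1)
    if t1 < t0:
        return 1, 0
    if main_is_y:
        n_m, s_m, d_m = ny, sy, dy
    else:
        n_m, s_m, d_m = nx, sx, dx
    c_m = (n_m - 1) / 2.0
    wa = s_m + t0 * d_m
    wb = s_m + t1 * d_m
    if wa > wb:
        wa, wb = wb, wa
    kmin = int(np.ceil(wa / voxel + c_m))
    kmax = int(np.floor(wb / voxel + c_m))
    if kmin < 0:
        kmin = 0
    if kmax > n_m - 1:
        kmax = n_m - 1
    return kmin, kmax


@njit(cache=True)
def joseph_forward(vol, voxel, sod, sdd, pitch, nr, nc, angles_rad, out):
    """Line integrals of ``vol`` for every (angle, row, col) ray.

    ``out`` has shape (n_angles, nr, nc) and is overwritten.
    """
    nz, ny, nx = vol.shape
    cz = (nz - 1) / 2.0
    cy = (ny - 1) / 2.0
    cx = (nx - 1) / 2.0
    rc = 0.5 * voxel * np.sqrt(float(ny * ny + nx * nx)) + voxel
    r_cyl2 = rc * rc
    for a in range(angles_rad.shape[0]):
        cos_t = np.cos(angles_rad[a])
        sin_t = np.sin(angles_rad[a])
        for r in range(nr):
            for c in range(nc):
                sz, sy, sx, dz, dy, dx = _ray_setup(
                    r, c, nr, nc, pitch, sod, sdd, cos_t, sin_t
                )
                main_is_y = abs(dy) >= abs(dx)
                kmin, kmax = _march_range(
                    sz, sy, sx, dz, dy, dx, voxel, nz, ny, nx, main_is_y, r_cyl2
                )
                acc = 0.0
                norm = np.sqrt(dz * dz + dy * dy + dx * dx)
                if main_is_y:
                    step = voxel * norm / abs(dy)
                    for k in range(kmin, kmax + 1):
                        t = ((k - cy) * voxel - sy) / dy
                        fz = (sz + t * dz) / voxel + cz
                        fx = (sx + t * dx) / voxel + cx
                        if fz < 0.0 or fz > nz - 1 or fx < 0.0 or fx > nx - 1:
                            continue
                        iz = int(fz)
                        ix = int(fx)
                        if iz > nz - 2:
                            iz = nz - 2
                        if ix > nx - 2:
                            ix = nx - 2
                        wz = fz - iz
                        wx = fx - ix
                        acc += step * (
                            (vol[iz, k, ix] * (1 - wx) + vol[iz, k, ix + 1] * wx) * (1 - wz)
                            + (vol[iz + 1, k, ix] * (1 - wx) + vol[iz + 1, k, ix + 1] * wx) * wz
                        )
                else:
                    step = voxel * norm / abs(dx)
                    for k in range(kmin, kmax + 1):
                        t = ((k - cx) * voxel - sx) / dx
                        fz = (sz + t * dz) / voxel + cz
                        fy = (sy + t * dy) / voxel + cy
                        if fz < 0.0 or fz > nz - 1 or fy < 0.0 or fy > ny - 1:
                            continue
                        iz = int(fz)
                        iy = int(fy)
                        if iz > nz - 2:
                            iz = nz - 2
                        if iy > ny - 2:
                            iy = ny - 2
                        wz = fz - iz
                        wy = fy - iy
                        acc += step * (
                            (vol[iz, iy, k] * (1 - wy) + vol[iz, iy + 1, k] * wy) * (1 - wz)
                            + (vol[iz + 1, iy, k] * (1 - wy) + vol[iz + 1, iy + 1, k] * wy) * wz
                        )
                out[a, r, c] = acc


@njit(cache=True)
def joseph_adjoint(proj, voxel, sod, sdd, pitch, nz, ny, nx, angles_rad, out):
    """Exact transpose of :func:`joseph_forward`.

    Scatters each projection value back along its ray with the same
    bilinear weights and step length.  ``out`` has shape (nz, ny, nx)
    and is overwritten.
    """
    n_angles, nr, nc = proj.shape
    cz = (nz - 1) / 2.0
    cy = (ny - 1) / 2.0
    cx = (nx - 1) / 2.0
    rc = 0.5 * voxel * np.sqrt(float(ny * ny + nx * nx)) + voxel
    r_cyl2 = rc * rc
    out[:, :, :] = 0.0
    for a in range(n_angles):
        cos_t = np.cos(angles_rad[a])
        sin_t = np.sin(angles_rad[a])
        for r in range(nr):
            for c in range(nc):
                val = proj[a, r, c]
                if val == 0.0:
                    continue
                sz, sy, sx, dz, dy, dx = _ray_setup(
                    r, c, nr, nc, pitch, sod, sdd, cos_t, sin_t
                )
                main_is_y = abs(dy) >= abs(dx)
                kmin, kmax = _march_range(
                    sz, sy, sx, dz, dy, dx, voxel, nz, ny, nx, main_is_y, r_cyl2
                )
                norm = np.sqrt(dz * dz + dy * dy + dx * dx)
                if main_is_y:
                    g = val * voxel * norm / abs(dy)
                    for k in range(kmin, kmax + 1):
                        t = ((k - cy) * voxel - sy) / dy
                        fz = (sz + t * dz) / voxel + cz
                        fx = (sx + t * dx) / voxel + cx
                        if fz < 0.0 or fz > nz - 1 or fx < 0.0 or fx > nx - 1:
                            continue
                        iz = int(fz)
                        ix = int(fx)
                        if iz > nz - 2:
                            iz = nz - 2
                        if ix > nx - 2:
                            ix = nx - 2
                        wz = fz - iz
                        wx = fx - ix
                        out[iz, k, ix] += g * (1 - wz) * (1 - wx)
                        out[iz, k, ix + 1] += g * (1 - wz) * wx
                        out[iz + 1, k, ix] += g * wz * (1 - wx)
                        out[iz + 1, k, ix + 1] += g * wz * wx
                else:
                    g = val * voxel * norm / abs(dx)
                    for k in range(kmin, kmax + 1):
                        t = ((k - cx) * voxel - sx) / dx
                        fz = (sz + t * dz) / voxel + cz
                        fy = (sy + t * dy) / voxel + cy
                        if fz < 0.0 or fz > nz - 1 or fy < 0.0 or fy > ny - 1:
                            continue
                        iz = int(fz)
                        iy = int(fy)
                        if iz > nz - 2:
                            iz = nz - 2
                        if iy > ny - 2:
                            iy = ny - 2
                        wz = fz - iz
                        wy = fy - iy
                        out[iz, iy, k] += g * (1 - wz) * (1 - wy)
                        out[iz, iy + 1, k] += g * (1 - wz) * wy
                        out[iz + 1, iy, k] += g * wz * (1 - wy)
                        out[iz + 1, iy + 1, k] += g * wz * wy


@njit(cache=True)
def fdk_backproject(filtered, voxel, sod, sdd, pitch, nz, ny, nx, angles_rad, out):
    """Voxel-driven weighted cone-beam backprojection (FDK).

    ``filtered`` holds cosine-weighted, ramp-filtered projections.  Each
    voxel is projected through the point source onto the detector,
    sampled bilinearly, and accumulated with the FDK distance weight
    ``(sod / L_u)**2`` where ``L_u`` is the voxel's distance from the
    source along the central-ray direction.  The caller applies the
    ``d_beta / 2`` angular quadrature scale.
    """
    n_angles, nr, nc = filtered.shape
    cz = (nz - 1) / 2.0
    cy = (ny - 1) / 2.0
    cx = (nx - 1) / 2.0
    cr = (nr - 1) / 2.0
    cc = (nc - 1) / 2.0
    out[:, :, :] = 0.0
    for a in range(n_angles):
        cos_t = np.cos(angles_rad[a])
        sin_t = np.sin(angles_rad[a])
        for iy in range(ny):
            y = (iy - cy) * voxel
            for ix in range(nx):
                x = (ix - cx) * voxel
                lu = sod + y * cos_t + x * sin_t
                if lu <= 0.0:
                    continue
                lt = -y * sin_t + x * cos_t
                mag = sdd / lu
                fc = lt * mag / pitch + cc
                if fc < 0.0 or fc > nc - 1:
                    continue
                ic = int(fc)
                if ic > nc - 2:
                    ic = nc - 2
                wc = fc - ic
                w2 = (sod / lu) * (sod / lu)
                zscale = mag / pitch
                for iz in range(nz):
                    z = (iz - cz) * voxel
                    fr = z * zscale + cr
                    if fr < 0.0 or fr > nr - 1:
                        continue
                    ir = int(fr)
                    if ir > nr - 2:
                        ir = nr - 2
                    wr = fr - ir
                    val = (
                        filtered[a, ir, ic] * (1 - wr) * (1 - wc)
                        + filtered[a, ir, ic + 1] * (1 - wr) * wc
                        + filtered[a, ir + 1, ic] * wr * (1 - wc)
                        + filtered[a, ir + 1, ic + 1] * wr * wc
                    )
                    out[iz, iy, ix] += w2 * val
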