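"""Forward/back projection, source blur, photon counts, stitching."""

import numpy as np
import pytest
from scipy import ndimage

from nanoct.geometry import FlatField, ProjectionSet
from nanoct.projector import (
    apply_source_blur,
    back_project,
    forward_project,
    simulate_counts,
    simulate_scan,
    stitch_vertical,
)
from nanoct.volumes import ReconVolume

from conftest import gaussian_blob, small_geometry, sphere_volume


class TestForwardProject:
    def test_zero_volume_zero_projections(self, geom_small):
        p = forward_project(np.zeros((16, 16, 16)), geom_small, voxel_size=1.0)
        assert np.all(p.data == 0)
        assert p.domain == "line_integral"

    def test_central_ray_through_sphere_is_chord(self):
        vol = sphere_volume(64, radius=20.0, mu0=0.01)
        geom = small_geometry(detector=(128, 128), n_angles=1)
        p = forward_project(vol, geom, voxel_size=1.0)
        # detector centre falls between the four central pixels
        central = p.data[0, 63:65, 63:65].mean()
        assert central == pytest.approx(2 * 20 * 0.01, rel=0.01)

    def test_matches_dense_ray_integration_oracle(self):
        """Joseph sampling vs brute-force fine-step integration along
        the same off-centre rays, on a smooth volume."""
        vol = gaussian_blob(32)
        geom = small_geometry(detector=(48, 48), n_angles=3)
        p = forward_project(vol, geom, voxel_size=1.0)
        sod, sdd = geom.sod * 1e3, geom.sdd * 1e3
        nr, nc = geom.detector_shape
        rng = np.random.default_rng(0)
        for _ in range(12):
            a = rng.integers(0, 3)
            r = rng.integers(4, nr - 4)
            c = rng.integers(4, nc - 4)
            theta = np.deg2rad(geom.angles_deg[a])
            ct, st = np.cos(theta), np.sin(theta)
            src = np.array([0.0, -sod * ct, -sod * st])
            u = (c - (nc - 1) / 2) * geom.detector_pitch
            v = (r - (nr - 1) / 2) * geom.detector_pitch
            pix = np.array([
                v,
                (sdd - sod) * ct - u * st,
                (sdd - sod) * st + u * ct,
            ])
            d = pix - src
            # dense sampling at 0.05 voxel steps through the volume region
            ts = np.linspace(0.7 * sod / np.linalg.norm(d), 1.3 * sod / np.linalg.norm(d), 4000)
            pts = src[None] + ts[:, None] * d[None]
            idx = pts.T / 1.0 + (np.array(vol.shape)[:, None] - 1) / 2.0
            samples = ndimage.map_coordinates(vol, idx, order=1, mode="constant")
            ds = np.diff(ts)[0] * np.linalg.norm(d)
            oracle = samples.sum() * ds
            if oracle < 1e-4:
                continue
            assert p.data[a, r, c] == pytest.approx(oracle, rel=0.005)

    def test_linearity(self, geom_small, rng):
        x = rng.random((16, 16, 16))
        y = rng.random((16, 16, 16))
        px = forward_project(x, geom_small, voxel_size=1.0).data
        py = forward_project(y, geom_small, voxel_size=1.0).data
        pxy = forward_project(2.0 * x - 3.0 * y, geom_small, voxel_size=1.0).data
        assert np.allclose(pxy, 2.0 * px - 3.0 * py, atol=1e-10)

    def test_field_of_view_guard(self):
        geom = small_geometry(detector=(8, 8))
        with pytest.raises(ValueError, match="field of view"):
            forward_project(np.zeros((64, 64, 64)), geom, voxel_size=1.0)


class TestAdjointness:
    def test_inner_product_identity_32cubed(self, geom_small, rng):
        """<Ax, y> == <x, A^T y>: the load-bearing property for the
        statistical reconstruction gradients."""
        x = rng.random((32, 32, 32))
        ax = forward_project(x, geom_small, voxel_size=1.0)
        y = rng.random(ax.data.shape)
        aty = back_project(ax.with_data(y), (32, 32, 32), 1.0)
        lhs = np.vdot(ax.data, y)
        rhs = np.vdot(x, aty)
        assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_zero_projections_zero_volume(self, geom_small):
        p = ProjectionSet(
            np.zeros((geom_small.n_angles, 48, 48)), geom_small.angles_deg,
            "line_integral", geom_small,
        )
        assert np.all(back_project(p, (16, 16, 16), 1.0) == 0)

    def test_single_pixel_backprojects_along_one_ray(self):
        geom = small_geometry(detector=(32, 32), n_angles=4)
        data = np.zeros((4, 32, 32))
        data[0, 16, 16] = 1.0
        p = ProjectionSet(data, geom.angles_deg, "line_integral", geom)
        vol = back_project(p, (24, 24, 24), 1.0)
        hit = np.argwhere(vol != 0)
        assert hit.size > 0
        # angle 0: source on -y axis, central pixel ray runs along y;
        # support stays within the bilinear footprint of that line
        assert np.ptp(hit[:, 0]) <= 2
        assert np.ptp(hit[:, 2]) <= 2

    def test_wrong_domain_rejected(self, geom_small):
        p = ProjectionSet(
            np.ones((geom_small.n_angles, 48, 48)), geom_small.angles_deg,
            "counts", geom_small,
        )
        with pytest.raises(ValueError, match="domain"):
            back_project(p, (16, 16, 16), 1.0)


class TestSourceBlur:
    def test_zero_fwhm_is_identity(self, rng):
        geom = small_geometry(source_fwhm=0.0)
        p = ProjectionSet(rng.random((geom.n_angles, 48, 48)), geom.angles_deg,
                          "line_integral", geom)
        assert apply_source_blur(p, geom) is p

    def test_flux_preserved(self, rng):
        geom = small_geometry(source_fwhm=3000.0)
        p = ProjectionSet(rng.random((geom.n_angles, 48, 48)), geom.angles_deg,
                          "transmission", geom)
        b = apply_source_blur(p, geom)
        for i in range(p.n_angles):
            assert b.data[i].sum() == pytest.approx(p.data[i].sum(), rel=1e-6)

    def test_impulse_response_fwhm(self):
        # large source spot so the detector-plane FWHM spans ~4 pixels
        geom = small_geometry(detector=(64, 64), n_angles=1, source_fwhm=4000.0)
        data = np.zeros((1, 64, 64))
        data[0, 32, 32] = 1.0
        p = ProjectionSet(data, geom.angles_deg, "line_integral", geom)
        out = apply_source_blur(p, geom).data[0]
        profile = out[32]
        half = profile.max() / 2
        above = np.flatnonzero(profile >= half)
        # linear interpolation at the half-maximum crossings
        lo = above[0] - (profile[above[0]] - half) / (profile[above[0]] - profile[above[0] - 1])
        hi = above[-1] + (profile[above[-1]] - half) / (profile[above[-1]] - profile[above[-1] + 1])
        measured = hi - lo
        assert measured == pytest.approx(geom.source_fwhm_detector_px, abs=0.5)


class TestSimulateCounts:
    def test_unattenuated_beam_mean_flux(self, geom_small):
        p = ProjectionSet(np.zeros((1, 200, 200)), np.zeros(1), "line_integral",
                          geom_small)
        flat = FlatField.uniform((200, 200), 1e4)
        counts = simulate_counts(p, flat, seed=0)
        n = counts.data.size
        assert counts.data.mean() == pytest.approx(1e4, abs=3 * 100 / np.sqrt(n))

    def test_deterministic_mode_is_beer_lambert(self, geom_small, rng):
        p = ProjectionSet(rng.random((2, 16, 16)), np.zeros(2), "line_integral",
                          geom_small)
        flat = FlatField.uniform((16, 16), 1e4)
        counts = simulate_counts(p, flat, stochastic=False)
        assert np.allclose(counts.data / flat.image, np.exp(-p.data))

    def test_poisson_mean_and_variance(self, geom_small):
        # p = ln 2 at flux 1e4: counts ~ Poisson(5000)
        p = ProjectionSet(np.full((1, 320, 320), np.log(2.0)), np.zeros(1),
                          "line_integral", geom_small)
        flat = FlatField.uniform((320, 320), 1e4)
        counts = simulate_counts(p, flat, seed=5).data
        n = counts.size
        assert counts.mean() == pytest.approx(5000, abs=3 * np.sqrt(5000 / n))
        assert counts.var() == pytest.approx(5000, rel=0.05)

    def test_seeded_reproducible(self, geom_small, rng):
        p = ProjectionSet(rng.random((2, 8, 8)), np.zeros(2), "line_integral", geom_small)
        flat = FlatField.uniform((8, 8), 100.0)
        a = simulate_counts(p, flat, seed=9).data
        b = simulate_counts(p, flat, seed=9).data
        assert np.array_equal(a, b)


class TestStitchVertical:
    def test_single_scan_identity(self, rng):
        v = rng.random((10, 4, 4))
        assert stitch_vertical([v], 4) is v

    def test_two_half_volumes_rebuild_phantom(self):
        vol = gaussian_blob(32)
        top, bottom = vol[:20], vol[12:]
        stitched = stitch_vertical([top, bottom], overlaps=8)
        assert stitched.shape == vol.shape
        assert np.allclose(stitched, vol, atol=1e-12)

    def test_four_tiles_cover_full_axial_extent(self):
        vol = np.arange(152 * 2 * 2, dtype=float).reshape(152, 2, 2)
        tiles = [vol[0:44], vol[36:80], vol[72:116], vol[108:152]]
        stitched = stitch_vertical(tiles, overlaps=8)
        assert stitched.shape[0] == 152
        assert np.allclose(stitched, vol)

    def test_voxel_size_mismatch_rejected(self):
        a = ReconVolume(np.zeros((4, 4, 4)), 1.0)
        b = ReconVolume(np.zeros((4, 4, 4)), 2.0)
        with pytest.raises(ValueError, match="voxel"):
            stitch_vertical([a, b], 2)

    def test_invalid_overlap_rejected(self, rng):
        a, b = rng.random((6, 4, 4)), rng.random((6, 4, 4))
        with pytest.raises(ValueError, match="overlap"):
            stitch_vertical([a, b], overlaps=10)


class TestSimulateScan:
    def test_noiseless_roundtrip_recovers_line_integrals(self):
        vol = sphere_volume(24, 8.0, 0.01)
        geom = small_geometry(detector=(40, 40), n_angles=4, source_fwhm=0.0)
        counts, flat = simulate_scan(vol, geom, flux=1e4, voxel_size=1.0,
                                     stochastic=False)
        p = forward_project(vol, geom, voxel_size=1.0)
        assert np.allclose(-np.log(counts.data / flat.image), p.data, atol=1e-12)
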