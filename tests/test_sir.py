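"""Statistical iterative reconstruction: penalty, objective, fitting."""

import numpy as np
import pytest

from nanoct.fbp import fbp_reconstruct
from nanoct.geometry import FlatField, ProjectionSet
from nanoct.projector import forward_project, simulate_scan
from nanoct.sir import (
    SIRConfig,
    SIRModel,
    estimate_delta,
    huber,
    roughness_penalty,
    sir_objective,
    sir_reconstruct,
)
from nanoct.volumes import ReconVolume

from conftest import small_geometry, sphere_volume


class TestHuber:
    def test_zero_at_origin(self):
        v, d = huber(0.0, 0.5)
        assert v == 0.0 and d == 0.0

    def test_continuity_at_knee(self):
        delta = 0.3
        v, d = huber(delta, delta)
        assert v == pytest.approx(delta**2 / 2)
        assert d == pytest.approx(delta)
        v_eps, _ = huber(delta * (1 + 1e-9), delta)
        assert v_eps == pytest.approx(v, rel=1e-6)

    def test_linear_branch_value(self):
        delta = 0.2
        v, d = huber(2 * delta, delta)
        assert v == pytest.approx(1.5 * delta**2)
        assert d == pytest.approx(delta)

    def test_symmetric_and_vectorized(self):
        t = np.array([-0.4, -0.1, 0.0, 0.1, 0.4])
        v, d = huber(t, 0.2)
        assert np.allclose(v, v[::-1])
        assert np.allclose(d, -d[::-1])

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            huber(1.0, 0.0)


class TestRoughnessPenalty:
    def test_constant_volume_zero_penalty(self):
        v, g = roughness_penalty(np.full((5, 5, 5), 0.7), 0.1)
        assert v == 0.0
        assert np.all(g == 0.0)

    def test_two_voxel_face_pair_quadratic(self):
        mu = np.zeros((2, 1, 1))
        mu[1, 0, 0] = 0.05
        v, _ = roughness_penalty(mu, delta=0.1)
        assert v == pytest.approx(0.05**2 / 2)

    def test_gradient_matches_finite_differences(self, rng):
        mu = rng.random((8, 8, 8))
        delta = 0.3
        _, g = roughness_penalty(mu, delta)
        h = 1e-6
        for idx in [(0, 0, 0), (3, 4, 5), (7, 7, 7), (2, 0, 6)]:
            up, dn = mu.copy(), mu.copy()
            up[idx] += h
            dn[idx] -= h
            vu, _ = roughness_penalty(up, delta)
            vd, _ = roughness_penalty(dn, delta)
            fd = (vu - vd) / (2 * h)
            assert g[idx] == pytest.approx(fd, rel=1e-5)

    def test_neighbor_weights_inverse_distance(self):
        # edge-diagonal pair contributes 1/sqrt(2) of a face pair
        mu_face = np.zeros((1, 2, 1))
        mu_face[0, 1, 0] = 0.01
        mu_edge = np.zeros((1, 2, 2))
        mu_edge[0, 1, 1] = 0.01
        v_face, _ = roughness_penalty(mu_face, 1.0)
        v_edge, _ = roughness_penalty(mu_edge, 1.0)
        # edge volume has: one face pair per axis (two) and one diagonal
        expected = v_face * (2 + 1 / np.sqrt(2))
        assert v_edge == pytest.approx(expected)


class TestEstimateDelta:
    def test_known_noise_fixture(self, rng):
        sigma = 0.01
        v = ReconVolume(rng.normal(0, sigma, (32, 32, 32)), 1.0)
        roi = (slice(0, 25), slice(0, 25), slice(0, 25))
        assert estimate_delta(v, roi, c=1.0) == pytest.approx(sigma, rel=0.05)

    def test_c_scales_linearly(self, rng):
        v = ReconVolume(rng.normal(0, 0.01, (16, 16, 16)), 1.0)
        roi = (slice(0, 10), slice(0, 10), slice(0, 10))
        assert estimate_delta(v, roi, c=2.0) == pytest.approx(
            2.0 * estimate_delta(v, roi, c=1.0)
        )

    def test_noiseless_volume_hits_floor(self):
        v = ReconVolume(np.zeros((8, 8, 8)), 1.0)
        roi = (slice(0, 4), slice(0, 4), slice(0, 4))
        assert estimate_delta(v, roi, delta_min=1e-6) == 1e-6


def _counts_fixture(truth, geom, flux=1e4, seed=None, stochastic=True):
    return simulate_scan(truth, geom, flux, seed=seed, voxel_size=1.0,
                         stochastic=stochastic)


class TestObjective:
    def test_zero_at_truth_for_noiseless_data(self):
        # noiseless data generated by the reconstruction's own forward
        # model (blur acting on the line integrals): the truth is then
        # the exact global minimum of the data term
        truth = sphere_volume(12, 4.0, 0.02)
        geom = small_geometry(detector=(20, 20), n_angles=16, source_fwhm=450.0)
        from nanoct.geometry import FlatField
        from nanoct.projector import apply_source_blur, simulate_counts

        p = apply_source_blur(forward_project(truth, geom, voxel_size=1.0), geom)
        flat = FlatField.uniform(geom.detector_shape, 1e4)
        counts = simulate_counts(p, flat, stochastic=False)
        cfg = SIRConfig(beta=0.0, delta=0.01, source_fwhm_model_nm=450.0)
        model = SIRModel(counts, geom, cfg, truth.shape, 1.0, flat=flat)
        f, g = model.objective(truth, 0.01)
        # counts-weighted squared residuals: scale out the weights
        assert f / model.weights.sum() < 1e-16
        assert np.abs(g).max() < 1e-8

    def test_gradient_matches_finite_differences(self, rng):
        truth = rng.random((8, 8, 8)) * 0.02
        geom = small_geometry(detector=(12, 12), n_angles=12, source_fwhm=450.0)
        counts, flat = _counts_fixture(truth, geom, seed=1)
        cfg = SIRConfig(beta=10.0, delta=0.01, source_fwhm_model_nm=450.0)
        model = SIRModel(counts, geom, cfg, truth.shape, 1.0, flat=flat)
        mu = rng.random((8, 8, 8)) * 0.02
        _, g = model.objective(mu, 0.01)
        h = 1e-6
        for idx in [(0, 0, 0), (4, 3, 2), (7, 7, 7)]:
            up, dn = mu.copy(), mu.copy()
            up[idx] += h
            dn[idx] -= h
            fu, _ = model.objective(up, 0.01)
            fd_, _ = model.objective(dn, 0.01)
            fd = (fu - fd_) / (2 * h)
            assert g[idx] == pytest.approx(fd, rel=1e-5)

    def test_unweighted_unblurred_reduces_to_least_squares(self, rng):
        """With w = 1 and B = identity the objective must equal the
        ordinary least-squares objective evaluated with a dense matrix."""
        geom = small_geometry(detector=(12, 12), n_angles=12, source_fwhm=0.0)
        shape = (8, 8, 8)
        n_vox = np.prod(shape)
        basis = np.zeros(shape)
        cols = []
        for j in range(n_vox):
            basis.flat[j] = 1.0
            cols.append(forward_project(basis, geom, voxel_size=1.0).data.ravel())
            basis.flat[j] = 0.0
        A = np.stack(cols, axis=1)
        mu = rng.random(shape) * 0.02
        truth = rng.random(shape) * 0.02
        p = forward_project(truth, geom, voxel_size=1.0)
        data = p.with_data(p.data, domain="log")
        cfg = SIRConfig(beta=0.0, delta=0.01, source_fwhm_model_nm=0.0)
        model = SIRModel(data, geom, cfg, shape, 1.0)
        f, g = model.objective(mu, 0.01)
        r = A @ mu.ravel() - p.data.ravel()
        f_dense = 0.5 * r @ r
        g_dense = A.T @ r
        assert f == pytest.approx(f_dense, rel=1e-10)
        assert np.allclose(g.ravel(), g_dense, atol=1e-10 * np.abs(g_dense).max())

    def test_functional_wrapper(self, rng):
        truth = rng.random((6, 6, 6)) * 0.01
        geom = small_geometry(detector=(10, 10), n_angles=8, source_fwhm=0.0)
        counts, flat = _counts_fixture(truth, geom, seed=2)
        cfg = SIRConfig(beta=0.0, delta=0.01)
        f, g = sir_objective(truth, counts, geom, cfg, voxel_size=1.0, flat=flat)
        assert np.isfinite(f) and g.shape == truth.shape


class TestFit:
    def test_noiseless_beta0_recovers_phantom(self):
        truth = sphere_volume(16, 5.0, 0.02)
        geom = small_geometry(detector=(24, 24), n_angles=36, source_fwhm=0.0)
        counts, flat = _counts_fixture(truth, geom, stochastic=False)
        cfg = SIRConfig(beta=0.0, delta=0.01, source_fwhm_model_nm=0.0,
                        max_iters=150, grad_tol=1e-10)
        model = SIRModel(counts, geom, cfg, truth.shape, 1.0, flat=flat)
        res = model.fit(init=np.zeros_like(truth))
        rmse = np.sqrt(np.mean((res.volume.data - truth) ** 2))
        assert rmse <= 0.01 * 0.02
        assert res.volume.provenance == "SIR"

    def test_objective_monotone_over_accepted_iterates(self, rng):
        truth = sphere_volume(12, 4.0, 0.02)
        geom = small_geometry(detector=(20, 20), n_angles=24, source_fwhm=450.0)
        counts, flat = _counts_fixture(truth, geom, seed=3)
        cfg = SIRConfig(beta=100.0, delta=1e-3, max_iters=15,
                        source_fwhm_model_nm=450.0)
        model = SIRModel(counts, geom, cfg, truth.shape, 1.0, flat=flat)
        res = model.fit(init=np.zeros_like(truth))
        h = res.objective_history
        assert len(h) >= 3
        assert all(b <= a * (1 + 1e-10) + 1e-12 for a, b in zip(h, h[1:]))

    def test_stationary_start_terminates_quickly(self):
        truth = sphere_volume(12, 4.0, 0.02)
        geom = small_geometry(detector=(20, 20), n_angles=24, source_fwhm=0.0)
        counts, flat = _counts_fixture(truth, geom, stochastic=False)
        cfg = SIRConfig(beta=0.0, delta=0.01, source_fwhm_model_nm=0.0,
                        max_iters=50, grad_tol=1e-10)
        model = SIRModel(counts, geom, cfg, truth.shape, 1.0, flat=flat)
        res = model.fit(init=truth)
        assert res.n_iter <= 2
        assert np.allclose(res.volume.data, truth, atol=1e-8)

    def test_large_delta_limit_matches_quadratic_penalty(self, rng):
        """delta -> inf: huber -> pure quadratic; solutions agree."""
        truth = sphere_volume(10, 3.0, 0.02)
        geom = small_geometry(detector=(16, 16), n_angles=16, source_fwhm=0.0)
        counts, flat = _counts_fixture(truth, geom, seed=4)
        beta = 50.0

        def solve(delta):
            cfg = SIRConfig(beta=beta, delta=delta, max_iters=100,
                            source_fwhm_model_nm=0.0, grad_tol=1e-12)
            m = SIRModel(counts, geom, cfg, truth.shape, 1.0, flat=flat)
            return m.fit(init=np.zeros_like(truth)).volume.data

        big = solve(1e6)  # effectively quadratic everywhere
        huge = solve(1e9)
        scale = np.abs(huge).max()
        assert np.abs(big - huge).max() <= 0.01 * scale

    def test_nonnegativity_enforced(self, rng):
        truth = sphere_volume(10, 3.0, 0.02)
        geom = small_geometry(detector=(16, 16), n_angles=16, source_fwhm=0.0)
        counts, flat = _counts_fixture(truth, geom, seed=5, flux=100.0)
        cfg = SIRConfig(beta=0.0, delta=0.01, max_iters=30, source_fwhm_model_nm=0.0)
        model = SIRModel(counts, geom, cfg, truth.shape, 1.0, flat=flat)
        res = model.fit(init=np.zeros_like(truth))
        assert res.volume.data.min() >= 0.0

    def test_more_iterations_do_not_worsen_recovery(self):
        truth = sphere_volume(12, 4.0, 0.02)
        geom = small_geometry(detector=(20, 20), n_angles=24, source_fwhm=0.0)
        counts, flat = _counts_fixture(truth, geom, seed=8)
        errs = []
        for iters in (1, 15):
            cfg = SIRConfig(beta=50.0, delta=1e-3, max_iters=iters,
                            source_fwhm_model_nm=0.0)
            model = SIRModel(counts, geom, cfg, truth.shape, 1.0, flat=flat)
            res = model.fit(init=np.zeros_like(truth))
            errs.append(np.sqrt(np.mean((res.volume.data - truth) ** 2)))
        assert errs[1] <= errs[0]

    def test_auto_delta_requires_roi(self):
        truth = sphere_volume(10, 3.0, 0.02)
        geom = small_geometry(detector=(16, 16), n_angles=16)
        counts, flat = _counts_fixture(truth, geom, seed=6)
        model = SIRModel(counts, geom, SIRConfig(), truth.shape, 1.0, flat=flat)
        with pytest.raises(ValueError, match="ROI"):
            model.fit(init="fbp")

    def test_summary_reports_resolved_hyperparameters(self):
        truth = sphere_volume(10, 3.0, 0.02)
        geom = small_geometry(detector=(16, 16), n_angles=16, source_fwhm=0.0)
        counts, flat = _counts_fixture(truth, geom, seed=7)
        cfg = SIRConfig(beta=10.0, delta="auto", max_iters=5, source_fwhm_model_nm=0.0)
        model = SIRModel(counts, geom, cfg, truth.shape, 1.0, flat=flat)
        res = model.fit(init="fbp", background_roi=(slice(0, 2), slice(0, 2), slice(0, 2)))
        text = res.summary()
        assert "delta" in text and "beta" in text
        assert res.volume.meta["delta"] == res.delta

    def test_one_call_reconstruction(self):
        truth = sphere_volume(10, 3.0, 0.02)
        geom = small_geometry(detector=(16, 16), n_angles=16, source_fwhm=0.0)
        counts, flat = _counts_fixture(truth, geom, stochastic=False)
        cfg = SIRConfig(beta=0.0, delta=0.01, max_iters=60, source_fwhm_model_nm=0.0)
        vol = sir_reconstruct(counts, geom, cfg, truth.shape, 1.0,
                              init=np.zeros_like(truth), flat=flat)
        assert np.sqrt(np.mean((vol.data - truth) ** 2)) < 0.02 * 0.02


class TestConfigValidation:
    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            SIRConfig(beta=-1.0)

    def test_bad_delta_rejected(self):
        with pytest.raises(ValueError):
            SIRConfig(delta=-0.5)
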