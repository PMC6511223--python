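"""Phantom generator: fractions, determinism, cells, attenuation."""

import numpy as np
import pytest
from scipy import ndimage

from nanoct.morphometry import label_volumes
from nanoct.phantom import (
    BODY_MATRIX,
    DEFAULT_MATERIALS,
    STORAGE_CELLS,
    TABLE_FRACTIONS,
    MaterialError,
    PackingError,
    Phantom,
    PhantomSpec,
    assign_attenuation,
    build_phantom,
    phantom_report,
    sample_cell_volumes,
)
from nanoct.volumes import LabelField

CONN26 = np.ones((3, 3, 3), dtype=bool)


def small_spec(**overrides) -> PhantomSpec:
    """Half-scale specimen for fast tests."""
    kwargs = dict(
        grid_shape=(96, 48, 48), body_length=76.0, body_width=16.0,
        n_storage_cells=20, cell_volume_range=(6.0, 25.0), cell_volume_mean=12.0,
        cell_min_gap=1.0, cell_organ_gap=0.5, rng_seed=7,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="module")
def default_phantom() -> Phantom:
    return build_phantom(PhantomSpec(rng_seed=1))


class TestSpecValidation:
    def test_fractions_must_sum_below_one(self):
        with pytest.raises(ValueError, match="sum"):
            PhantomSpec(organ_fractions={"a": 0.6, "b": 0.5})

    def test_body_must_fit_grid(self):
        with pytest.raises(ValueError, match="fit"):
            PhantomSpec(grid_shape=(64, 96, 96), body_length=152.0)

    def test_cell_mean_must_lie_in_range(self):
        with pytest.raises(ValueError, match="mean"):
            PhantomSpec(cell_volume_mean=100.0, cell_volume_range=(20.8, 83.4))


class TestBuildPhantom:
    def test_deterministic_for_fixed_seed(self):
        a = build_phantom(small_spec())
        b = build_phantom(small_spec())
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.mu, b.mu)

    def test_different_seed_changes_cells(self):
        a = build_phantom(small_spec(rng_seed=1))
        b = build_phantom(small_spec(rng_seed=2))
        assert not np.array_equal(a.labels, b.labels)

    def test_empty_spec_single_body_label(self):
        ph = build_phantom(small_spec(organ_fractions={}, n_storage_cells=0))
        labs = set(np.unique(ph.labels)) - {0}
        assert labs == {1}
        assert ph.legend == {1: BODY_MATRIX}

    def test_requested_extents_realized(self, default_phantom):
        t = default_phantom.truth
        assert t.body_length_um == pytest.approx(152.0, abs=1.0)
        assert t.body_width_um == pytest.approx(32.0, abs=1.0)

    def test_organ_fractions_within_two_percent(self, default_phantom):
        t = default_phantom.truth
        for name, frac in TABLE_FRACTIONS.items():
            realized = t.pct_of(name) / 100.0
            assert realized == pytest.approx(frac, rel=0.02), name

    def test_midgut_hindgut_fraction_matches_specimen(self, default_phantom):
        # the dominant digestive structure occupies ~9.97% of TBV
        assert default_phantom.truth.pct_of("midgut + hindgut") == pytest.approx(
            9.97, abs=0.05
        )

    def test_mu_zero_exactly_outside_labels(self, default_phantom):
        assert np.all(default_phantom.mu[default_phantom.labels == 0] == 0)
        assert np.all(default_phantom.mu[default_phantom.labels != 0] > 0)

    def test_legend_matches_label_content(self, default_phantom):
        present = set(np.unique(default_phantom.labels).tolist()) - {0}
        assert present == set(default_phantom.legend)

    def test_volume_bookkeeping(self, default_phantom):
        # every body voxel is labeled matrix, organ or cell
        body = default_phantom.body_mask
        labs, counts = np.unique(default_phantom.labels, return_counts=True)
        assert counts[labs != 0].sum() == body.sum()

    def test_organ_component_counts(self, default_phantom):
        lf = default_phantom.label_field()
        expected = {
            "midgut + hindgut": 1, "salivary glands": 2, "pharynx": 1,
            "brain": 1, "ovary": 1, "Malpighian tubules": 3,
            "claw glands": 8, "esophagus": 1,
        }
        for name, n_expected in expected.items():
            _, n = ndimage.label(lf.mask(name), structure=CONN26)
            assert n == n_expected, name

    def test_cells_are_separate_components_with_gap(self, default_phantom):
        cells = default_phantom.label_field().mask(STORAGE_CELLS)
        # every cell is its own 26-connected component: since each cell
        # is a connected ball, this holds iff no two cells touch (at
        # least one voxel of separation everywhere)
        _, n = ndimage.label(cells, structure=CONN26)
        assert n == 137
        # the attenuation band of the noiseless phantom also yields
        # exactly 137 cells, so count recovery is achievable in principle
        from nanoct.morphometry import segment_cells
        from nanoct.phantom import cell_band
        from nanoct.volumes import ReconVolume

        lf = segment_cells(
            ReconVolume(default_phantom.mu, 1.0), cell_band(), min_voxels=4
        )
        assert len(lf.legend) == 137

    def test_infeasible_packing_raises(self):
        spec = small_spec(
            grid_shape=(32, 24, 24), body_length=24.0, body_width=10.0,
            n_storage_cells=200,
        )
        with pytest.raises(PackingError, match="cell"):
            build_phantom(spec)


class TestSampleCellVolumes:
    def test_zero_cells_empty(self):
        assert sample_cell_volumes(0, 48.2, (20.8, 83.4), 0).size == 0

    def test_study_conditions_range_and_mean(self):
        vols = sample_cell_volumes(137, 48.2, (20.8, 83.4), seed=3)
        assert vols.size == 137
        assert vols.min() >= 20.8 and vols.max() <= 83.4
        assert vols.mean() == pytest.approx(48.2, rel=0.10)
        assert np.all(np.diff(vols) <= 0)  # sorted descending

    def test_degenerate_range_single_value(self):
        assert sample_cell_volumes(1, 5.0, (5.0, 5.0), 0)[0] == 5.0

    def test_mean_outside_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            sample_cell_volumes(10, 90.0, (20.8, 83.4), 0)

    def test_seed_reproducible(self):
        a = sample_cell_volumes(50, 48.2, (20.8, 83.4), 11)
        b = sample_cell_volumes(50, 48.2, (20.8, 83.4), 11)
        assert np.array_equal(a, b)


class TestAssignAttenuation:
    def test_all_zero_labels_all_zero_mu(self):
        mu = assign_attenuation(np.zeros((4, 4, 4), dtype=int), DEFAULT_MATERIALS, {})
        assert np.all(mu == 0)

    def test_single_label_cube(self):
        labels = np.zeros((6, 6, 6), dtype=int)
        labels[1:5, 1:5, 1:5] = 1
        mu = assign_attenuation(labels, {"stuff": 0.5}, {1: "stuff"})
        assert np.all(mu[labels == 1] == 0.5)
        assert np.all(mu[labels == 0] == 0.0)

    def test_one_attenuation_mode_per_material(self, default_phantom):
        values = set(np.unique(default_phantom.mu)) - {0.0}
        names = {default_phantom.legend[k] for k in default_phantom.legend}
        assert values == {DEFAULT_MATERIALS[n] for n in names}

    def test_missing_material_entry_names_structure(self):
        labels = np.ones((2, 2, 2), dtype=int)
        with pytest.raises(MaterialError, match="mystery"):
            assign_attenuation(labels, {"other": 0.1}, {1: "mystery"})


class TestPhantomReport:
    def test_single_cube_is_whole_body(self):
        labels = np.zeros((12, 12, 12), dtype=np.uint16)
        labels[1:11, 1:11, 1:11] = 1
        lf = LabelField(labels, 1.0, {1: BODY_MATRIX})
        t = label_volumes(lf)
        assert t.tbv_um3 == 1000.0
        assert t.pct_of(BODY_MATRIX) == 100.0

    def test_two_equal_structures_split_evenly(self):
        labels = np.zeros((4, 4, 4), dtype=np.uint16)
        labels[:2] = 1
        labels[2:] = 2
        lf = LabelField(labels, 1.0, {1: "left", 2: "right"})
        t = label_volumes(lf)
        assert t.pct_of("left") == 50.0
        assert t.pct_of("right") == 50.0

    def test_storage_cell_fraction_near_measured(self, default_phantom):
        # 137 cells averaging 48.2 um^3 occupy ~4.8% of the body
        pct = phantom_report(default_phantom).pct_of(STORAGE_CELLS)
        assert pct == pytest.approx(4.80, abs=0.10)

    def test_report_is_ground_truth_table(self, default_phantom):
        t = phantom_report(default_phantom)
        voxel_vol = default_phantom.voxel_size**3
        n_mid = np.isin(
            default_phantom.labels,
            [k for k, v in default_phantom.legend.items() if v == "midgut + hindgut"],
        ).sum()
        assert t.volume_of("midgut + hindgut") == pytest.approx(n_mid * voxel_vol)
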