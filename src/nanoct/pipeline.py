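"""End-to-end pipeline: phantom -> scan -> reconstruct -> merge -> measure.

Mirrors the instrument's two-resolution acquisition protocol at configurable
scale: the whole specimen is scanned in vertical tiles and
reconstructed (FBP with Richardson-Lucy preprocessing, then SIR), the
head region is re-scanned at a finer effective voxel and reconstructed
with the source-blur-modelling SIR, the head labels are registered and
merged into the whole-body label field, and the combined label field
yields the morphometry report.

A single global seed fans out to per-stage seeds (stage-name hashed)
so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .fbp import fbp_reconstruct
from .geometry import ScanGeometry, desk_geometry
from .io import write_labels, write_volume
from .morphometry import (
    CellStats,
    MorphometryTable,
    body_extents,
    cell_stats,
    label_volumes,
    report,
    segment_cells,
)
from .phantom import (
    BODY_MATRIX,
    DEFAULT_MATERIALS,
    STORAGE_CELLS,
    Phantom,
    PhantomSpec,
    build_phantom,
    cell_band,
)
from .preprocess import PreprocessConfig, flat_field_normalize, neg_log, richardson_lucy
from .projector import simulate_scan, stitch_vertical
from .register import merge_labels, register_affine, resample_labels
from .sir import SIRConfig, SIRModel
from .volumes import LabelField, ReconVolume

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "stage_seed",
    "classify_attenuation",
    "integral_organ_volume",
    "recovered_volumes",
    "recovered_label_field",
    "background_roi",
]

log = logging.getLogger("nanoct.pipeline")

_CELL_LABEL_START = 100


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed and the stage name."""
    return int((int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1))


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run.

    The default scale is the desk-scale study condition: the full-size
    phantom (192 x 96 x 96 voxels at 1 um) scanned with 240 views on a
    256^2 detector at 1e4 photons/pixel.
    """

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    geometry: ScanGeometry = field(default_factory=desk_geometry)
    head_geometry: ScanGeometry = field(default_factory=lambda: desk_geometry(head=True))
    flux: float = 1.0e4
    n_tiles: int = 4
    tile_overlap: int = 8
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    fbp_window: str = "shepp-logan"
    sir: SIRConfig = field(default_factory=SIRConfig)
    sir_coarse_iters: int = 30  # 0 disables the coarse-to-fine pass
    head_fraction: float = 0.25  # anterior fraction of the body treated as head
    head_margin: int = 6  # extra slices scanned around the head region
    run_head_pass: bool = True
    materials: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MATERIALS))
    min_voxels: int = 4
    bin_width: float = 5.0
    rng_seed: int = 0

    def scaled_down(self) -> "PipelineConfig":
        """Small-problem profile used by the test suite (fast smoke runs)."""
        spec = replace(
            self.phantom,
            grid_shape=(96, 48, 48),
            body_length=76.0,
            body_width=16.0,
            n_storage_cells=24,
            cell_volume_range=(6.0, 25.0),
            cell_volume_mean=12.0,
            cell_min_gap=1.0,
            cell_organ_gap=0.5,
        )
        geom = replace(self.geometry, detector_shape=(128, 128), n_angles=96)
        hgeom = replace(self.head_geometry, detector_shape=(128, 128), n_angles=96)
        return replace(
            self, phantom=spec, geometry=geom, head_geometry=hgeom,
            n_tiles=2, tile_overlap=6,
            sir=replace(self.sir, max_iters=6),
        )


@dataclass
class PipelineResult:
    phantom: Phantom
    fbp_volume: ReconVolume
    sir_volume: ReconVolume
    merged_labels: LabelField
    table: MorphometryTable
    stats: CellStats
    out_dir: Path | None = None
    artifacts: dict = field(default_factory=dict)


def classify_attenuation(
    v: ReconVolume,
    materials: dict[str, float] | None = None,
    pv_iterations: int = 0,
    min_component: int = 10,
    return_halo: bool = False,
):
    """Assign every voxel to the material with the nearest attenuation.

    Midpoint thresholds between consecutive material values (and
    between zero and the lowest material for the background boundary).
    Organ-class components below ``min_component`` voxels — noise
    islands and interface specks, not anatomy — are absorbed into the
    class that surrounds them (the brightest class, storage cells, is
    exempt because individual cells are legitimately small).

    ``pv_iterations`` enables an optional partial-volume correction for
    under-converged or heavily smoothed reconstructions (e.g. measuring
    directly on FBP): a voxel whose neighbourhood contains both strictly
    brighter and strictly darker classes sits on a two-material
    interface, and its intermediate gray value is a mixture artefact
    rather than evidence of a third tissue; it is reassigned to
    whichever flanking class its value is closer to (the sub-voxel 50%
    occupancy threshold).  On a well-converged statistical
    reconstruction the raw bands are already essentially correct and
    this correction is left off.

    Storage cells keep one label here; per-cell labelling is done by
    :func:`nanoct.morphometry.segment_cells`.
    """
    mats = dict(materials if materials is not None else DEFAULT_MATERIALS)
    names = sorted(mats, key=mats.get)
    values = np.array([0.0] + [mats[n] for n in names])
    edges = 0.5 * (values[:-1] + values[1:])
    cls = np.digitize(v.data, edges)  # 0 = background, i -> names[i-1]
    footprint = np.ones((3, 3, 3), dtype=bool)
    # storage cells are far brighter than every organ, so the mixture
    # halo around each cell sweeps through the organ bands; a voxel
    # whose neighbourhood contains the cell class on one side and a
    # strictly darker class on the other is such a mixture, and is
    # split to the nearer of the two at the 50% occupancy level.  One
    # sweep only (no feedback), so genuine organ voxels further from
    # the cell are never touched.
    top = len(names)
    halo = np.zeros(cls.shape, dtype=bool)
    if top >= 2:
        lo = ndimage.minimum_filter(cls, footprint=footprint, mode="nearest")
        hi = ndimage.maximum_filter(cls, footprint=footprint, mode="nearest")
        halo = (hi == top) & (cls < top) & (lo < cls)
        if halo.any():
            mu_lo = values[lo[halo]]
            frac = (v.data[halo] - mu_lo) / (values[top] - mu_lo)
            cls[halo] = np.where(frac >= 0.5, top, lo[halo])
    # voxels flanked by their own class on both sides along the steepest
    # gray-value axis sit inside a solid region, not on a mixture shell;
    # they are never reassigned (prevents erosion of genuinely thin
    # structures by cascading reassignment)
    grads = [np.abs(np.gradient(v.data, axis=k)) for k in range(3)]
    grad_axis = np.argmax(np.stack(grads), axis=0)
    for _ in range(pv_iterations):
        solid = np.zeros(cls.shape, dtype=bool)
        for k in range(3):
            fwd = np.roll(cls, -1, axis=k)
            bwd = np.roll(cls, 1, axis=k)
            solid |= (grad_axis == k) & (fwd == cls) & (bwd == cls)
        lo = ndimage.minimum_filter(cls, footprint=footprint, mode="nearest")
        hi = ndimage.maximum_filter(cls, footprint=footprint, mode="nearest")
        interface = (lo < cls) & (cls < hi) & ~solid
        if not interface.any():
            break
        mu_lo = values[lo[interface]]
        mu_hi = values[hi[interface]]
        frac = (v.data[interface] - mu_lo) / (mu_hi - mu_lo)
        cls[interface] = np.where(frac >= 0.5, hi[interface], lo[interface])
    if min_component > 1:
        footprint26 = np.ones((3, 3, 3), dtype=bool)
        for k in range(1, len(names)):  # skip background and the cell class
            mask = cls == k
            labeled, n_comp = ndimage.label(mask, structure=footprint26)
            if n_comp == 0:
                continue
            counts = np.bincount(labeled.ravel())
            small = np.flatnonzero((counts < min_component) & (counts > 0))
            boxes = ndimage.find_objects(labeled)
            for comp in small:
                if comp == 0:
                    continue
                box = boxes[comp - 1]
                grown = tuple(
                    slice(max(s.start - 1, 0), min(s.stop + 1, dim))
                    for s, dim in zip(box, cls.shape)
                )
                local = labeled[grown] == comp
                ring = ndimage.binary_dilation(local, structure=footprint26) & ~local
                neighbors = cls[grown][ring]
                if neighbors.size == 0:
                    continue
                cls[grown][local] = np.bincount(neighbors).argmax()
    legend = {i + 1: n for i, n in enumerate(names)}
    lf = LabelField(cls.astype(np.uint32), v.voxel_size, legend)
    return (lf, halo) if return_halo else lf


def integral_organ_volume(
    v: ReconVolume,
    classified: LabelField,
    structure: str,
    materials: dict[str, float] | None = None,
    dilation: int = 2,
    big_component: int = 50,
    cell_exclusion: int = 1,
    halo: np.ndarray | None = None,
) -> float:
    """Partial-volume-corrected volume of one organ, in um^3.

    Mass-preserving reconstructions spread an organ's attenuation over
    a blur/shrinkage shell, so voxel counting under-measures thin
    structures.  Integrating the fractional occupancy
    ``(v - mu_matrix) / (mu_organ - mu_matrix)`` over a region that
    contains the organ and its shell but only matrix otherwise recovers
    the volume regardless of how the mass is locally redistributed, and
    zero-mean noise cancels in the sum.  The region is the organ's
    classified core dilated ``dilation`` times, clipped to the body,
    excluding storage cells with a ``cell_exclusion``-voxel guard band
    (their bright halos would otherwise be billed to the organ) and
    excluding components of other organ classes of at least
    ``big_component`` voxels (genuine neighbouring anatomy, while small
    fragments are this organ's own shell).
    """
    mats = dict(materials if materials is not None else DEFAULT_MATERIALS)
    mu_m = mats[BODY_MATRIX]
    if structure not in mats or structure in (BODY_MATRIX, STORAGE_CELLS):
        raise ValueError(f"integral volume applies to organs, not {structure!r}")
    footprint = np.ones((3, 3, 3), dtype=bool)
    cls = classified.labels
    inv = {name: lab for lab, name in classified.legend.items()}
    # the organ's core is the big components of its class only: small
    # fragments in the same gray band are other structures' shells and
    # must not seed the region
    mask = cls == inv[structure]
    labeled, n_comp = ndimage.label(mask, footprint)
    counts = np.bincount(labeled.ravel())
    big = np.flatnonzero(counts >= big_component)
    big = big[big != 0]
    core = np.isin(labeled, big) if big.size else mask
    roi = ndimage.binary_dilation(core, footprint, iterations=dilation) & (cls > 0)
    cells = cls == inv.get(STORAGE_CELLS, -1)
    if cells.any():
        roi &= ~ndimage.binary_dilation(cells, footprint, iterations=cell_exclusion)
    if halo is not None:
        # voxels the cell-halo sweep touched are cell/matrix mixtures;
        # their mass does not belong to any organ
        roi &= ~halo
    for name, lab in inv.items():
        if name in (structure, BODY_MATRIX, STORAGE_CELLS):
            continue
        mask = cls == lab
        if not (roi & mask).any():
            continue
        labeled, n = ndimage.label(mask, footprint)
        counts = np.bincount(labeled.ravel())
        big = np.flatnonzero(counts >= big_component)
        big = big[big != 0]
        if big.size:
            roi &= ~np.isin(labeled, big)
    frac = (v.data[roi] - mu_m) / (mats[structure] - mu_m)
    return float(frac.sum()) * v.voxel_size**3


def recovered_volumes(
    v: ReconVolume, materials: dict[str, float] | None = None
) -> MorphometryTable:
    """Morphometry table measured from a reconstruction.

    Total body volume and storage-cell volume come from nearest-material
    classification (their gray bands are wide and their interfaces
    explicitly corrected); each organ volume from the
    partial-volume-corrected integral estimator; the body matrix closes
    the bookkeeping (matrix = TBV - organs - cells), so structure
    volumes sum to TBV exactly.
    """
    mats = dict(materials if materials is not None else DEFAULT_MATERIALS)
    classified, halo = classify_attenuation(v, mats, return_halo=True)
    cls = classified.labels
    inv = {name: lab for lab, name in classified.legend.items()}
    voxel_vol = v.voxel_size**3
    tbv = float((cls > 0).sum()) * voxel_vol
    organ_names = [n for n in mats if n not in (BODY_MATRIX, STORAGE_CELLS)]
    volumes = {
        name: integral_organ_volume(v, classified, name, mats, halo=halo)
        for name in organ_names
    }
    if STORAGE_CELLS in inv:
        volumes[STORAGE_CELLS] = float((cls == inv[STORAGE_CELLS]).sum()) * voxel_vol
    volumes[BODY_MATRIX] = tbv - sum(volumes.values())
    length, width = body_extents(cls > 0, v.voxel_size)
    names = list(volumes)
    return MorphometryTable(
        structures=names,
        labels=[[inv[n]] if n in inv else [] for n in names],
        volumes_um3=[volumes[n] for n in names],
        tbv_um3=tbv,
        body_length_um=length,
        body_width_um=width,
    )


def recovered_label_field(
    v: ReconVolume,
    materials: dict[str, float] | None = None,
    min_voxels: int = 4,
) -> LabelField:
    """Full label field recovered from a reconstruction.

    Organ/matrix voxels by nearest-material classification; storage
    cells re-labelled individually as 26-connected components of the
    cell attenuation band (small specks dropped back to body matrix).
    """
    mats = dict(materials if materials is not None else DEFAULT_MATERIALS)
    classified = classify_attenuation(v, mats)
    labels = classified.labels.copy()
    legend = dict(classified.legend)
    cell_ids = [lab for lab, n in legend.items() if n == STORAGE_CELLS]
    matrix_id = next((lab for lab, n in legend.items() if n == "body matrix"), None)
    if cell_ids:
        cid = cell_ids[0]
        cells = segment_cells(v, cell_band(mats), min_voxels=min_voxels)
        # speck voxels in the band but not in a surviving component fall
        # back to body matrix
        stray = (labels == cid) & (cells.labels == 0)
        labels[stray] = matrix_id if matrix_id is not None else 0
        labels[labels == cid] = 0
        del legend[cid]
        incell = cells.labels != 0
        labels[incell] = cells.labels[incell] + (_CELL_LABEL_START - 1)
        legend.update({int(k) + (_CELL_LABEL_START - 1): v_ for k, v_ in cells.legend.items()})
    return LabelField(labels, v.voxel_size, legend)


def background_roi(
    grid_shape: tuple[int, int, int], body_mask: np.ndarray | None = None
) -> tuple[slice, slice, slice]:
    """A corner box outside the object support, for noise estimation."""
    nz, ny, nx = grid_shape
    roi = (
        slice(2, max(3, nz // 5)),
        slice(2, max(3, ny // 7)),
        slice(2, max(3, nx // 7)),
    )
    if body_mask is not None and body_mask[roi].any():
        raise ValueError("default background ROI intersects the body; supply one")
    return roi


def _tile_slices(nz: int, n_tiles: int, overlap: int) -> list[slice]:
    """Vertical tile ranges with the given overlap between neighbours."""
    if n_tiles == 1:
        return [slice(0, nz)]
    core = int(np.ceil((nz + (n_tiles - 1) * overlap) / n_tiles))
    slices = []
    start = 0
    for i in range(n_tiles):
        stop = min(start + core, nz)
        slices.append(slice(start, stop))
        if stop == nz:
            break
        start = stop - overlap
    return slices


def _scan_and_reconstruct(
    mu: np.ndarray,
    voxel: float,
    geom: ScanGeometry,
    cfg: PipelineConfig,
    seed: int,
    use_rl: bool,
    grid_shape: tuple[int, int, int],
    body_mask_tile: np.ndarray | None,
    recon_voxel: float | None = None,
) -> tuple[ReconVolume, ReconVolume]:
    """One tile: simulate counts, preprocess, FBP, SIR.  Returns (fbp, sir).

    ``voxel`` is the phantom's voxel size (the physical object being
    scanned); ``recon_voxel`` the reconstruction grid's, which differs
    for the finer head re-scan.
    """
    recon_voxel = voxel if recon_voxel is None else recon_voxel
    counts, flat = simulate_scan(mu, geom, cfg.flux, seed=seed, voxel_size=voxel)
    trans = flat_field_normalize(counts, flat, epsilon=cfg.preprocess.epsilon)
    if use_rl and cfg.preprocess.rl_iterations > 0:
        psf = cfg.preprocess.rl_psf_fwhm_px
        if psf is None:
            psf = geom.source_fwhm_detector_px
        trans = richardson_lucy(trans, psf, cfg.preprocess.rl_iterations)
    logp = neg_log(trans)
    fbp = fbp_reconstruct(logp, grid_shape, recon_voxel, window=cfg.fbp_window)
    if body_mask_tile is not None and body_mask_tile.shape != tuple(grid_shape):
        body_mask_tile = None  # mask lives on the phantom grid, not this one
    roi = background_roi(grid_shape, body_mask_tile)
    model = SIRModel(counts, geom, cfg.sir, grid_shape=grid_shape,
                     voxel_size=recon_voxel, flat=flat)
    multiscale = cfg.sir_coarse_iters > 0 and not any(
        n % 2 for n in (*grid_shape, *geom.detector_shape)
    )
    if multiscale:
        res = model.fit_multiscale(coarse_iters=cfg.sir_coarse_iters, background_roi=roi)
    else:
        res = model.fit(init="fbp", background_roi=roi)
    return fbp, res.volume


def _reconnect_cells_at_seam(merged: LabelField, head_end: int) -> LabelField:
    """Reunite storage-cell fragments split by the head-merge boundary.

    A cell straddling the boundary arrives as two labels, one from each
    segmentation, sometimes separated by a one-voxel seam gap from
    resampling misalignment; the resampled head segmentation can also
    carry one-slice dropouts from sub-voxel banding between the two
    grids.  Cell fragments are relabeled as 26-connected components,
    and two components inside (or just past) the head region whose
    in-plane footprints overlap across a z-gap of at most one slice are
    reunited.  Genuinely distinct cells are protected by the packing
    gap except in the rare case of a closely stacked, axially aligned
    pair.
    """
    footprint = np.ones((3, 3, 3), dtype=bool)
    cell_mask = merged.labels >= _CELL_LABEL_START
    lab, n = ndimage.label(cell_mask, structure=footprint)
    parent = list(range(n + 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    boxes = ndimage.find_objects(lab)
    nz = merged.labels.shape[0]
    if 1 < head_end < nz - 1 and n > 1:
        in_head = [c for c in range(1, n + 1)
                   if boxes[c - 1][0].start <= head_end + 2]
        for a in in_head:
            foot_a = (lab == a).any(axis=0)
            for b in in_head:
                gap = boxes[b - 1][0].start - boxes[a - 1][0].stop
                if not 0 <= gap <= 1:
                    continue
                if (foot_a & (lab == b).any(axis=0)).any():
                    parent[find(b)] = find(a)
    roots = sorted({find(c) for c in range(1, n + 1)})
    remap = np.zeros(n + 1, dtype=np.int64)
    for i, r in enumerate(roots, start=1):
        for c in range(1, n + 1):
            if find(c) == r:
                remap[c] = i
    new_labels = np.where(
        cell_mask, remap[lab] + (_CELL_LABEL_START - 1), merged.labels
    ).astype(np.uint32)
    legend = {k: v for k, v in merged.legend.items() if k < _CELL_LABEL_START}
    legend.update({
        i + (_CELL_LABEL_START - 1): STORAGE_CELLS for i in range(1, len(roots) + 1)
    })
    return LabelField(new_labels, merged.voxel_size, legend)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full workflow; optionally persist stage artifacts.

    Stages: phantom -> tiled whole-body scans -> preprocess -> FBP ->
    SIR -> stitch -> head scan -> SIR -> register + merge -> morphometry
    -> report.  Deterministic for a fixed config (the global seed fans
    out to stage seeds).
    """
    out = Path(out_dir) if out_dir is not None else None
    artifacts: dict[str, Path] = {}

    def save(name, writer, *args):
        if out is not None:
            artifacts[name] = writer(out / name, *args)

    log.info("stage phantom: grid=%s seed=%d", cfg.phantom.grid_shape, cfg.phantom.rng_seed)
    phantom = build_phantom(
        replace(cfg.phantom, rng_seed=stage_seed(cfg.rng_seed, "phantom")),
        materials=cfg.materials,
    )
    save("phantom_labels.tif", write_labels, phantom.label_field())
    save("phantom_mu.tif", write_volume, phantom.mu, phantom.voxel_size, "phantom")

    nz = phantom.labels.shape[0]
    tiles = _tile_slices(nz, cfg.n_tiles, cfg.tile_overlap)
    fbp_tiles, sir_tiles = [], []
    for i, sl in enumerate(tiles):
        mu_tile = phantom.mu[sl]
        body_tile = phantom.body_mask[sl]
        shape = mu_tile.shape
        log.info("stage scan tile %d/%d: slices %s", i + 1, len(tiles), sl)
        fbp_t, sir_t = _scan_and_reconstruct(
            mu_tile, phantom.voxel_size, cfg.geometry, cfg,
            stage_seed(cfg.rng_seed, f"scan-tile-{i}"), use_rl=True,
            grid_shape=shape, body_mask_tile=body_tile,
        )
        fbp_tiles.append(fbp_t)
        sir_tiles.append(sir_t)
    overlaps = [tiles[i].stop - tiles[i + 1].start for i in range(len(tiles) - 1)]
    fbp_whole = stitch_vertical(fbp_tiles, overlaps) if len(tiles) > 1 else fbp_tiles[0]
    sir_whole = stitch_vertical(sir_tiles, overlaps) if len(tiles) > 1 else sir_tiles[0]
    save("fbp_whole.tif", write_volume, fbp_whole)
    save("sir_whole.tif", write_volume, sir_whole)

    whole_labels = recovered_label_field(sir_whole, cfg.materials, cfg.min_voxels)

    if cfg.run_head_pass:
        head_end = int(round(cfg.head_fraction * nz))
        scan_end = min(nz, head_end + cfg.head_margin)
        mu_head = phantom.mu[:scan_end]
        head_voxel = cfg.head_geometry.pixel_size_iso
        hshape = (
            int(np.ceil(scan_end * phantom.voxel_size / head_voxel)),
            int(np.ceil(phantom.labels.shape[1] * phantom.voxel_size / head_voxel)),
            int(np.ceil(phantom.labels.shape[2] * phantom.voxel_size / head_voxel)),
        )
        log.info("stage head scan: %d slices at %.3f um voxel", scan_end, head_voxel)
        # the data term is integrated over voxels while the penalty is
        # counted per voxel pair, so the calibrated regularization
        # strength carries to the finer head grid scaled by the voxel
        # volume ratio
        beta_head = cfg.sir.beta * (head_voxel / phantom.voxel_size) ** 3
        head_cfg = replace(cfg, sir=replace(cfg.sir, beta=beta_head))
        _, sir_head = _scan_and_reconstruct(
            mu_head, phantom.voxel_size, cfg.head_geometry, head_cfg,
            stage_seed(cfg.rng_seed, "scan-head"), use_rl=False,
            grid_shape=hshape, body_mask_tile=None, recon_voxel=head_voxel,
        )
        save("sir_head.tif", write_volume, sir_head)
        # the head scan centres its slab on the rotation plane; in the
        # whole-body frame that slab centre sits at this z offset
        z_shift = (scan_end - nz) / 2.0 * phantom.voxel_size
        transform = register_affine(
            sir_head, sir_whole, initial_offset=np.array([z_shift, 0.0, 0.0])
        )
        head_labels = recovered_label_field(sir_head, cfg.materials, cfg.min_voxels)
        # keep head cell labels disjoint from whole-body cell labels
        shift = int(whole_labels.labels.max()) + 1
        remap = {
            lab: lab + shift for lab in head_labels.legend if lab >= _CELL_LABEL_START
        }
        if remap:
            lut = np.arange(int(head_labels.labels.max()) + 1, dtype=np.int64)
            for old, new in remap.items():
                lut[old] = new
            head_labels = LabelField(
                lut[head_labels.labels].astype(np.uint32), head_labels.voxel_size,
                {remap.get(k, k): v for k, v in head_labels.legend.items()},
            )
        head_on_whole = resample_labels(
            head_labels, transform, phantom.labels.shape, phantom.voxel_size
        )
        region = (slice(0, head_end), slice(None), slice(None))
        merged = merge_labels(whole_labels, head_on_whole, region)
        merged = _reconnect_cells_at_seam(merged, head_end)
    else:
        merged = whole_labels

    save("merged_labels.tif", write_labels, merged)
    table = label_volumes(merged)
    cells_only = LabelField(
        np.where(merged.labels >= _CELL_LABEL_START, merged.labels, 0).astype(np.uint32),
        merged.voxel_size,
        {k: v for k, v in merged.legend.items() if k >= _CELL_LABEL_START},
    )
    stats = cell_stats(cells_only, bin_width=cfg.bin_width)
    if out is not None:
        paths = report(table, stats, out / "report")
        artifacts.update({f"report/{k}": v for k, v in paths.items()})
        (out / "run_config.yaml").write_text(config_to_yaml(cfg))
    return PipelineResult(
        phantom=phantom, fbp_volume=fbp_whole, sir_volume=sir_whole,
        merged_labels=merged, table=table, stats=stats,
        out_dir=out, artifacts=artifacts,
    )


# -- config (de)serialisation ---------------------------------------------


def config_to_yaml(cfg: PipelineConfig) -> str:
    from .io import geometry_to_dict

    d = dataclasses.asdict(cfg)
    d["geometry"] = geometry_to_dict(cfg.geometry)
    d["head_geometry"] = geometry_to_dict(cfg.head_geometry)
    d["phantom"]["grid_shape"] = list(cfg.phantom.grid_shape)
    d["phantom"]["cell_volume_range"] = list(cfg.phantom.cell_volume_range)
    return yaml.safe_dump(d, sort_keys=False)


def config_from_yaml(text: str) -> PipelineConfig:
    from .io import geometry_from_dict

    d = yaml.safe_load(text)
    kwargs: dict = {}
    if "phantom" in d:
        ph = dict(d["phantom"])
        if "grid_shape" in ph:
            ph["grid_shape"] = tuple(ph["grid_shape"])
        if "cell_volume_range" in ph:
            ph["cell_volume_range"] = tuple(ph["cell_volume_range"])
        kwargs["phantom"] = PhantomSpec(**ph)
    if "geometry" in d:
        kwargs["geometry"] = geometry_from_dict(d["geometry"])
    if "head_geometry" in d:
        kwargs["head_geometry"] = geometry_from_dict(d["head_geometry"])
    if "preprocess" in d:
        kwargs["preprocess"] = PreprocessConfig(**d["preprocess"])
    if "sir" in d:
        kwargs["sir"] = SIRConfig(**d["sir"])
    for key in (
        "flux", "n_tiles", "tile_overlap", "fbp_window", "head_fraction",
        "head_margin", "run_head_pass", "materials", "min_voxels",
        "bin_width", "rng_seed",
    ):
        if key in d:
            kwargs[key] = d[key]
    return PipelineConfig(**kwargs)
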