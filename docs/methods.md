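# Methods

This note documents the models implemented in `nanoct`, the parameter
choices that matter, and what the synthetic-data experiments do and do
not demonstrate.

## Digital specimen (phantom)

The specimen is a voxelized superellipsoid capsule. With body
half-length c, half-width a (left–right) and half-height b
(dorsoventral), a voxel centre (z, y, x) lies inside the body when

    (|y|/a)^p + (|x|/b)^p < 1 − (|z|/c)^q ,

with cross-section exponent p = 8 (a rounded-rectangular trunk
cross-section) and axial exponent q = 4 (smoothly rounded anterior and
posterior ends; flat end-caps perpendicular to the rotation axis are
both unrealistic and the worst case for cone-beam reconstruction).
Default extents are 152 µm length and 32 µm maximum width; the default
height 0.975 × width makes the realized total body volume ≈ 0.139 nl,
matching the ~0.14 nl specimen the defaults emulate.

Organs are generated by ranked fill: each organ has a continuous shape
field (radial distance for the gut and tubules, an anisotropic
ellipsoid norm for glands, ganglia and gonad, with several congruent
components for the paired salivary glands, the three Malpighian
tubules and the eight claw glands), and exactly
round(fraction × body voxels) available voxels with the smallest field
values are taken, largest organ first. Realized volume fractions are
therefore within one voxel of their targets. The default fractions are
the published per-structure percentages of total body volume (9.97%
midgut+hindgut down to 0.12% esophagus). Distinct organs are laid out
with at least about a voxel of body matrix between them; the esophagus
deliberately touches the pharynx and gut at its ends.

Storage cells (default n = 137) receive volumes drawn from a
log-normal distribution hard-truncated to 20.8–83.4 µm³, with the
log-scale location solved (Brent bisection on the closed-form
truncated-log-normal mean) so the truncated mean equals 48.2 µm³ and a
fixed log-sd of 0.35. The log-normal family is a modelling choice —
only the reference specimen's empirical histogram is known — selected
as the standard positive, right-skewed candidate. Cells are voxel balls
of exactly round(V) voxels, placed by seeded rejection sampling with a
Euclidean-distance-transform feasibility mask; placement guarantees
≥ 1.5 voxels surface-to-surface between cells (so every cell stays its
own 26-connected component after reconstruction) and ≥ 2.5 voxels of
clearance from organs and the body surface (so cell partial-volume
halos and organ boundary shells stay geometrically separable). Packing failure raises an
error naming the first unplaceable cell.

Attenuation values (1/µm) encode the strong soft-tissue contrast of
heavy-metal staining as one gray band per material: body matrix
0.006, organs 0.011–0.046 in steps of 0.005 ordered by descending
volume, and storage cells isolated at 0.058. The matrix has by far
the largest interface area in the volume (the whole body surface plus
every organ boundary), so the band next to it — where whatever
residual mixture or noise leaks out of the matrix band must land —
belongs to the largest organ, where the leakage is relatively
negligible; the top-band isolation of the cells (0.012/µm gap to the
nearest organ band) makes cell counting robust.

## Acquisition model

Cone-beam geometry with a point source, flat detector and full 360°
coverage (evenly spaced views starting at 0°). The instrument
geometries are SOD/SDD = 0.71/450 mm (whole body) and 0.61/520 mm
(head), magnifications 633.8 and 852.5; with the 172 µm detector pitch
these give 271 nm and 202 nm effective voxels. Desk-scale experiments
keep the distances and open the pitch so the whole-body scan has
exactly 1 µm effective pixels.

Forward projection uses Joseph's method: each source-to-pixel ray is
parametrised by the voxel planes of its dominant transaxial axis and
sampled by bilinear interpolation in the other two axes; the
backprojector is the exact matrix transpose (inner-product agreement
at machine precision), which the reconstruction gradients require.
Kernels are numba-compiled float64.

The finite source spot (FWHM 400–500 nm; 500 nm default) blurs the
projection with a detector-plane Gaussian of FWHM spot × (M − 1) — the
penumbra of a point magnifier — applied to the transmitted intensity,
i.e. before photon counting; at M ≫ 1 this equals ~one spot FWHM in
object units. Counts are Poisson with mean flat-field × transmission
(seeded; a deterministic mode returns the expectation for noiseless
round-trip tests). Specimens taller than the field of view are scanned
as vertical tiles of the attenuation volume and the reconstructions
blended with a linear ramp over the overlap; at these cone angles
(≈ 5°) the slab approximation to a true source shift is negligible
relative to the reconstruction error.

## Preprocessing

Counts are clamped below at ε = 0.5 photons, divided by the flat
field, and (for the FBP route) Richardson–Lucy deconvolved before the
negative-log transform. RL runs on transmission images — its Poisson
model applies to intensities, not log data — with a normalised
Gaussian PSF, reflective boundaries (flux-conserving) and 25
iterations by default; each iteration is the standard multiplicative
EM update and decreases the Kullback–Leibler divergence between the
data and the re-blurred estimate.

## Filtered backprojection (FDK)

Cosine pre-weighting in isocentre-plane coordinates, row-wise
filtering with the analytic discrete ramp kernel
(h₀ = 1/4, h_k = −1/(πk)² for odd lags) applied circularly over
edge-replicated, power-of-two padded rows with the DC bin forced to
zero, optional Shepp–Logan (default) or Hann apodisation, and
voxel-driven distance-weighted backprojection with the (SOD/L)² FDK
weight and Δβ/2 quadrature scale. On a noiseless 64³ sphere the
central-region RMSE is ≈ 1% of the sphere's attenuation.

## Statistical iterative reconstruction

The reconstruction minimises

    Φ(µ) = ½ Σᵢ wᵢ (pᵢ − [B A µ]ᵢ)² + β R(µ)

- **Data term.** p is the log-domain data; wᵢ = measured counts, the
  inverse variance of log-transformed Poisson data — the standard
  quadratic surrogate for the Poisson likelihood, smooth and suited to
  quasi-Newton optimisation. B models the source blur as the same
  detector-plane Gaussian the simulator uses (independently
  configurable, so model-mismatch experiments are possible). B is
  symmetric under reflective boundaries, so the gradient is
  Aᵀ B (W(B A µ − p)) + β ∇R.
- **Penalty.** R sums huber(µ_j − µ_k, δ) over unordered
  26-neighbourhood pairs with inverse-distance weights (1, 1/√2,
  1/√3). δ is quadratic/linear transition of the Huber function:
  differences below δ (noise) are smoothed quadratically, differences
  above δ (tissue boundaries) incur only linear cost and survive.
- **δ estimation.** δ = c × (standard deviation of a background region
  of the FBP reconstruction of the same data), floored at 10⁻⁶/µm.
  The scale factor defaults to c = 4: background noise underestimates
  in-object noise (attenuation reduces counts inside the specimen and
  FBP noise is object-dependent), and on the desk-scale fixture in-body
  noise is ≈ 3–4 × the air-region value. c is configurable; c = 1
  reproduces the raw background estimate.
- **β.** Default 3 × 10⁵, fixed once on the desk-scale default fixture
  as the noise/resolution trade-off that flattens within-organ noise
  without measurably degrading the 10–90% edge rise, and frozen.
  β is problem-scale dependent (it balances a data term summed over
  rays against a penalty summed over voxel pairs); small-problem tests
  scale it down roughly with the ray count.
- **Optimisation.** L-BFGS (scipy L-BFGS-B, memory 10); nonnegativity
  of attenuation enforced as bound constraints (projected L-BFGS).
  The objective over accepted iterates is checked to be non-increasing
  and a divergence raises an error carrying the iterate and history.
  Initialisation is the FBP volume computed with the **Hann** window:
  the smoother init carries no Gibbs overshoot at strong edges, which
  the edge-preserving penalty would otherwise lock in as spurious
  bright shells; the FBP *product* of the pipeline keeps the sharper
  Shepp–Logan default.
- **Coarse-to-fine.** `fit_multiscale` first solves the problem with
  2×2-binned detector pixels (counts pooled, log data averaged with
  count weights — what physically binning photons would give) on a 2×
  voxel grid, then refines at full resolution from the trilinearly
  interpolated coarse solution. The coarse pass converges low and mid
  frequencies (including the cone-beam shading FBP leaves near the
  axial ends of the specimen) at 1/8 the per-iteration cost; defaults
  are 30 coarse + 40 fine iterations.

## Two-resolution merge

The head region is re-scanned at the finer geometry and reconstructed
on its own grid. Registration of the head volume to the whole-body
volume uses SimpleITK's affine transform with a mean-squares metric
(same modality and stain), a 3-level multi-resolution pyramid and a
regular-step gradient-descent optimizer; no smoothing is applied at
the final pyramid level because blurring does not commute with scaling
and would bias the recovered linear part. Labels are resampled through
the recovered transform with nearest-neighbour interpolation
(categorical data must not be averaged) and replace the whole-body
labels inside an axis-aligned head box; label-id collisions between
the two legends require an explicit remap.

## Morphometry and recovery measurement

Total body volume is the voxel volume of all nonzero labels (every
body voxel is labeled matrix, organ or cell); per-structure
percentages are 100 × V/TBV, displayed at two decimals with full
precision retained. Storage cells are the 26-connected components of
the cell attenuation band (lower threshold midway between the cell
value and the highest organ value), components under 4 voxels
discarded as specks; per-cell statistics include a histogram with
5 µm³ bins from zero — the conventional bin width for these
distributions, read as a volume unit since the histogram axis is a
volume — and sphere-equivalent diameters (6V/π)^(1/3). Body
length is the axis-0 extent of the body mask (an optional exclusion
mask removes appendages from the measure, matching the convention of
measuring body length without the hind legs) and width the maximum axis-1
extent.

Reconstructed volumes are segmented by nearest-material
classification: midpoint thresholds between consecutive material
values, followed by one cell-halo sweep — storage cells are far
brighter than every organ, so the mixture halo around each cell sweeps
through the organ bands; voxels flanked by the cell class on one side
and a strictly darker class on the other are split to the nearer of
the two at the 50% occupancy level. Organ-class components under 10
voxels are then absorbed into their surrounding class (noise islands
and interface specks; the cell class is exempt since real cells are
small). An optional iterated partial-volume sweep generalises the halo
correction to every class pair for under-converged or heavily smoothed
reconstructions (e.g. measuring directly on FBP); it is off by default
because on a converged statistical reconstruction the raw bands are
already essentially correct.

Organ volumes are measured by partial-volume-corrected integration
rather than voxel counting (`recovered_volumes`): because the
reconstruction approximately conserves attenuation mass locally, the
fractional occupancy ``(v − µ_matrix)/(µ_organ − µ_matrix)`` summed
over a region that contains the organ and its blur/shrinkage shell but
otherwise only matrix equals the organ volume, however the mass is
locally redistributed, and zero-mean noise cancels in the sum. The
region is the organ's classified core — the large (≥ 50-voxel)
connected components of its gray band, so that other structures' thin
shells falling into the same band cannot seed it — dilated twice,
clipped to the body, excluding storage cells with a one-voxel guard
band and excluding the large components of other organ classes.  This
matters most for the esophagus, whose two-voxel-radius tube loses a
quarter of its band-classified voxels to boundary shrinkage at desk
scale while the integral recovers it to within a voxel.  Total body
volume and cell volumes come from the classification (their bands are
wide and explicitly corrected), and the body matrix closes the
bookkeeping so structure volumes sum to TBV exactly.

## Problem sizes

The package's standard experiment ("desk scale") is the full-size
phantom — 192 × 96 × 96 voxels at 1 µm, 137 cells, published organ
fractions — scanned with 240 views on a 256² detector at 10⁴
photons/pixel, reconstructed with 30 coarse + 24 fine SIR iterations
(about 11 minutes on one CPU). Under these conditions the recovered
morphometry reproduces the ground truth to within ≈ 1% for every
structure, the cell count exactly, and the body extents to the
voxel. The test suite exercises unit properties on 8³–
64³ instances and the end-to-end pipeline (tiling, head re-scan,
registration and merge) on a reduced 64 × 32 × 32 specimen. A
"paper-scale" configuration (172 µm pitch, 270/200 nm voxels, 1599
views) exists in the geometry defaults but is not exercised by the
tests.

## Limitations

- Simulation and reconstruction share the same grid and ray model
  (an "inverse crime"): recovery results demonstrate the correctness
  and internal consistency of the chain, not performance on real
  instrument data with scatter, drift, rings, polychromatic beam
  hardening or detector point spread — none of which are modelled.
- The simulator blurs the transmitted intensity (physical); the
  reconstruction models blur on the log data (linearised). The
  residual mismatch is second order in the blur width and negligible
  at sub-pixel penumbras.
- The smallest organ (esophagus, 0.12% TBV ≈ 165 voxels at desk scale)
  is at the resolution limit by construction; its recovery error is
  surface-dominated and the most seed-sensitive number the pipeline
  produces.
- Vertical tiling simulates slab sub-volumes rather than a shifted
  source; exact only in the limit of small cone angle.
- Registration is intensity-based affine; no deformable model.
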