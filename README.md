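# nanoct

Cone-beam nano-computed-tomography (nanoCT) simulation, statistical
iterative reconstruction and 3D morphometry of micro-animal specimens,
in Python.

Laboratory nanoCT reaches voxel sizes of 100–300 nm purely by
geometrical magnification: a nanofocus X-ray source illuminates the
sample and its shadow is magnified onto the detector by the factor
M = SDD/SOD (source-to-detector over source-to-rotation-axis
distance), so the effective voxel is the detector pitch divided by M.
At this scale a whole microscopic animal — the motivating application
is a ~150 µm tardigrade — can be imaged intact, every organ segmented,
and each nutrient storage cell counted and measured individually.

`nanoct` implements that entire quantitative workflow as reusable,
tested components:

- **phantom** — a seeded digital specimen: a superellipsoid body of
  prescribed length and maximum width, organs placed at
  anatomically inspired positions with volume fractions of total body
  volume (TBV) met to within one voxel, and discrete storage cells with
  volumes drawn from a truncated log-normal distribution.
- **geometry / projector** — cone-beam scan description, Joseph
  ray-traced forward projection with an exactly matched adjoint,
  Gaussian source blur (spot FWHM × (M−1) in the detector plane),
  Beer–Lambert attenuation and Poisson counting noise against a flat
  field, and vertical tile stitching for specimens taller than one
  field of view.
- **preprocess** — flat-field normalisation, negative-log transform,
  Richardson–Lucy deconvolution of the source penumbra.
- **fbp** — FDK filtered backprojection (cosine weighting, discrete
  ramp kernel with ramp/Shepp–Logan/Hann apodisation) and
  background-noise measurement.
- **sir** — the headline reconstruction, a statsmodels-style model:

  ```
  Φ(µ) = ½ Σᵢ wᵢ (pᵢ − [B A µ]ᵢ)² + β R(µ)
  ```

  with A the cone-beam projector, B the detector-plane source-blur
  Gaussian, p the log-domain data, wᵢ the measured photon counts
  (inverse variance of log data), and R an edge-preserving Huber
  penalty over the 26-neighbourhood whose transition parameter δ is
  estimated from the FBP background noise. Minimised by (projected)
  L-BFGS with an optional coarse-to-fine pass.
- **register / merge** — affine registration (SimpleITK, mean-squares,
  multi-resolution) of a high-resolution head re-scan into the
  whole-body frame and label-field replacement.
- **morphometry** — per-structure volumes and %TBV, storage-cell
  identification as 26-connected components of an attenuation band,
  volume histograms, sphere-equivalent diameters d = (6V/π)^(1/3), and
  body extents.

## Worked example

```python
import numpy as np
from nanoct import (PhantomSpec, build_phantom, desk_geometry, simulate_scan,
                    SIRModel, SIRConfig, segment_cells, cell_stats,
                    equivalent_diameter)
from nanoct.phantom import cell_band
from nanoct.pipeline import background_roi

phantom = build_phantom(PhantomSpec(rng_seed=1))   # 137 cells, 152 x 32 um
print(phantom.truth.to_frame().head(4))

geom = desk_geometry(n_angles=240)                 # 1 um effective pixels
counts, flat = simulate_scan(phantom.mu, geom, flux=1e4, seed=7, voxel_size=1.0)

model = SIRModel(counts, geom, SIRConfig(), grid_shape=phantom.labels.shape,
                 voxel_size=1.0, flat=flat)
result = model.fit_multiscale(
    background_roi=background_roi(phantom.labels.shape, phantom.body_mask))

cells = segment_cells(result.volume, cell_band(), min_voxels=4)
stats = cell_stats(cells, bin_width=5.0)
print(f"{stats.n_cells} cells, mean {stats.mean:.1f} um^3, "
      f"mean equivalent diameter {equivalent_diameter(stats.mean):.1f} um")
```

The phantom's ground-truth table starts

```
           structure  volume_um3  pct_tbv
0  total body volume    138608.0   100.00
1        body matrix    109302.0    78.86
2   midgut + hindgut     13819.0     9.97
3      storage cells      6657.0     4.80
```

and the recovery prints

```
137 cells, mean 46.5 um^3, mean equivalent diameter 4.5 um
```

i.e. the scan–reconstruct–segment loop finds every one of the 137
simulated storage cells; the band-thresholded mean cell volume
(46.5 µm³, vs the 48.2 µm³ prescribed — thresholding slightly
under-measures each cell's boundary) gives back the prescribed
sphere-equivalent diameter of 4.5 µm.  Partial-volume-corrected
per-organ volumes are available through
`nanoct.recovered_volumes(result.volume)`, which reproduces every
structure of the phantom's truth table to within about one percent
under these scan conditions.

A command-line interface mirrors the library
(`nanoct phantom / simulate / preprocess / reconstruct / register /
merge / measure / run`); `nanoct run --small --seed 0 --out out/`
executes the whole pipeline — tiled whole-body scan, FBP and SIR, head
re-scan at finer voxel, affine label merge, morphometry report — at a
reduced problem size.

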