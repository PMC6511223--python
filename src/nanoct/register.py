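"""Affine registration and label-field merging for the two-resolution
workflow.

The whole specimen is reconstructed at one voxel size and the head
region re-scanned at a finer one; the head reconstruction is
registered to the whole-body volume with an affine transform
(mean-squares metric, multi-resolution, via SimpleITK), its label
field is resampled into the whole-body frame with nearest-neighbour
interpolation (labels are categorical), and the head region of the
whole-body labels is replaced by the resampled labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volumes import LabelField, ReconVolume

__all__ = [
    "AffineTransform",
    "RegistrationError",
    "register_affine",
    "resample_labels",
    "merge_labels",
]


class RegistrationError(RuntimeError):
    """Optimizer failed to converge; carries the metric trace."""

    def __init__(self, message: str, metric_trace: list[float]):
        super().__init__(message)
        self.metric_trace = metric_trace


@dataclass
class AffineTransform:
    """Affine map from moving to fixed physical coordinates (um):
    ``x_fixed = matrix @ x_moving + offset`` in (z, y, x) order."""

    matrix: np.ndarray
    offset: np.ndarray
    metric_value: float = np.nan
    metric_trace: list[float] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.offset = np.asarray(self.offset, dtype=float).reshape(3)
        if np.linalg.cond(self.matrix) >= 1e6:
            raise ValueError("affine matrix is (near) singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.offset)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self after other: x -> self(other(x))."""
        return AffineTransform(
            self.matrix @ other.matrix, self.matrix @ other.offset + self.offset
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.matrix.T + self.offset

    def to_flat(self) -> np.ndarray:
        """Row-major 3x3 matrix followed by the offset (12 numbers)."""
        return np.concatenate([self.matrix.ravel(), self.offset])

    @classmethod
    def from_flat(cls, values: np.ndarray) -> "AffineTransform":
        values = np.asarray(values, dtype=float).ravel()
        if values.size != 12:
            raise ValueError("expected 12 numbers (matrix + offset)")
        return cls(values[:9].reshape(3, 3), values[9:])


def _to_sitk(vol: ReconVolume) -> sitk.Image:
    """SimpleITK image with physical spacing; world origin at the volume
    centre, matching the package's reconstruction convention."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data, dtype=np.float64))
    s = vol.voxel_size
    img.SetSpacing((s, s, s))  # sitk axis order (x, y, z)
    shape = vol.data.shape  # (z, y, x)
    img.SetOrigin(tuple(-(n - 1) / 2.0 * s for n in shape[::-1]))
    return img


def register_affine(
    moving: ReconVolume,
    fixed: ReconVolume,
    initial_offset: np.ndarray | None = None,
    levels: int = 3,
    iterations: int = 200,
    sampling_fraction: float = 1.0,
) -> AffineTransform:
    """Affine transform mapping moving to fixed physical coordinates.

    Minimises the mean-squared intensity difference over the overlap
    with a 3-level multi-resolution pyramid and a gradient-descent
    optimizer.  ``initial_offset`` (um, (z, y, x)) seeds the transform
    when the volumes start far apart.
    """
    f_img = _to_sitk(fixed)
    m_img = _to_sitk(moving)
    tx = sitk.AffineTransform(3)
    if initial_offset is not None:
        off = np.asarray(initial_offset, dtype=float)
        # sitk maps fixed -> moving: translation is the inverse offset
        tx.SetTranslation(tuple(off[::-1]))
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    if sampling_fraction < 1.0:
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(sampling_fraction, seed=12345)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-5,
        numberOfIterations=iterations,
        relaxationFactor=0.6,
        gradientMagnitudeTolerance=1e-8,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    shrink = [2 ** (levels - 1 - i) for i in range(levels)]
    # no smoothing at the final level: blurring does not commute with
    # scaling, so it would bias the recovered linear part
    smooth = [float(s) if s > 1 else 0.0 for s in shrink]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel(smooth)
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInitialTransform(tx, inPlace=True)
    trace: list[float] = []
    reg.AddCommand(sitk.sitkIterationEvent, lambda: trace.append(reg.GetMetricValue()))
    try:
        result = reg.Execute(f_img, m_img)
    except RuntimeError as exc:  # pragma: no cover - sitk internal failures
        raise RegistrationError(f"registration failed: {exc}", trace) from exc
    # sitk's resampling transform maps fixed physical points to moving
    # physical points; invert to get moving -> fixed, and flip (x, y, z)
    # -> (z, y, x)
    a = np.asarray(result.GetMatrix(), dtype=float).reshape(3, 3)
    t = np.asarray(result.GetTranslation(), dtype=float)
    c = np.asarray(result.GetCenter(), dtype=float)
    # fixed -> moving: y = A (x - c) + c + t
    offset_fm = c + t - a @ c
    flip = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)
    fixed_to_moving = AffineTransform(flip @ a @ flip, flip @ offset_fm)
    out = fixed_to_moving.inverse()
    out.metric_value = float(reg.GetMetricValue())
    out.metric_trace = trace
    return out


def resample_labels(
    labels: LabelField,
    t: AffineTransform,
    target_shape: tuple[int, int, int],
    target_voxel_size: float,
) -> LabelField:
    """Resample a label field through an affine into a target grid.

    Nearest-neighbour interpolation in physical coordinates (labels are
    categorical and must not be averaged); voxels that map outside the
    source domain become background.
    """
    nz, ny, nx = target_shape
    tv = target_voxel_size
    sv = labels.voxel_size
    inv = t.inverse()
    idx = np.indices((nz, ny, nx), dtype=float)
    centers = np.stack(
        [(idx[k] - (target_shape[k] - 1) / 2.0) * tv for k in range(3)], axis=-1
    )
    src_phys = centers @ inv.matrix.T + inv.offset
    src_idx = np.stack(
        [src_phys[..., k] / sv + (labels.shape[k] - 1) / 2.0 for k in range(3)], axis=0
    )
    out = ndimage.map_coordinates(
        labels.labels, src_idx, order=0, mode="constant", cval=0, prefilter=False
    )
    return LabelField(out.astype(labels.labels.dtype), tv, dict(labels.legend))


def merge_labels(
    whole: LabelField,
    head: LabelField,
    region: tuple[slice, slice, slice],
    remap: dict[int, int] | None = None,
) -> LabelField:
    """Replace whole-body labels inside ``region`` with head labels.

    ``head`` must already be resampled onto the whole-body grid.  Inside
    the axis-aligned region box the head labels (including zeros)
    overwrite the whole-body ones; everything outside is untouched.
    Label ids shared by the two legends must name the same structure,
    otherwise a remap table for the head labels is required.
    """
    if head.shape != whole.shape:
        raise ValueError("head labels must be resampled to the whole-body grid first")
    if head.voxel_size != whole.voxel_size:
        raise ValueError("voxel sizes differ; resample first")
    head_labels = head.labels
    head_legend = dict(head.legend)
    if remap:
        lut = np.arange(int(head_labels.max()) + 1, dtype=np.int64)
        for old, new in remap.items():
            lut[old] = new
        head_labels = lut[head_labels]
        head_legend = {remap.get(k, k): v for k, v in head_legend.items()}
    collisions = {
        lab: (whole.legend[lab], head_legend[lab])
        for lab in set(whole.legend) & set(head_legend)
        if whole.legend[lab] != head_legend[lab]
    }
    if collisions:
        raise ValueError(
            f"label id collisions map different structures: {collisions}; "
            "provide a remap table for the head labels"
        )
    out = whole.labels.copy()
    out[region] = head_labels[region].astype(out.dtype)
    legend = dict(whole.legend)
    legend.update(head_legend)
    present = set(np.unique(out).tolist()) - {0}
    legend = {k: v for k, v in legend.items() if k in present}
    return LabelField(out, whole.voxel_size, legend)
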