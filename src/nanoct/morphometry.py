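"""Volumetric morphometry of segmented label fields.

Per-structure absolute volumes and percentages of total body volume
(TBV), storage-cell identification by attenuation-band thresholding and
26-connected component labelling, cell-volume histograms,
sphere-equivalent diameters, and body extents.  Every labeled voxel is
part of the body, so TBV is the voxel volume of all nonzero labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import LabelField, ReconVolume

__all__ = [
    "MorphometryTable",
    "CellStats",
    "label_volumes",
    "percent_of_tbv",
    "segment_cells",
    "cell_stats",
    "equivalent_diameter",
    "body_extents",
    "report",
    "plot_cell_histogram",
]

_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


def percent_of_tbv(volume, tbv: float):
    """Volume as a percentage of total body volume: 100 * V / TBV."""
    if tbv <= 0:
        raise ValueError("TBV must be positive")
    return 100.0 * np.asarray(volume, dtype=float) / float(tbv)


def equivalent_diameter(volume):
    """Sphere-equivalent diameter d = (6 V / pi)^(1/3), same length unit
    as volume^(1/3); strictly monotone in V."""
    return np.cbrt(6.0 * np.asarray(volume, dtype=float) / np.pi)


@dataclass
class MorphometryTable:
    """Per-structure volumes and percentages of total body volume."""

    structures: list[str]
    labels: list[list[int]]
    volumes_um3: list[float]
    tbv_um3: float
    body_length_um: float = np.nan
    body_width_um: float = np.nan

    @property
    def pct_tbv(self) -> list[float]:
        return [float(percent_of_tbv(v, self.tbv_um3)) for v in self.volumes_um3]

    def volume_of(self, structure: str) -> float:
        return self.volumes_um3[self.structures.index(structure)]

    def pct_of(self, structure: str) -> float:
        return float(percent_of_tbv(self.volume_of(structure), self.tbv_um3))

    def to_frame(self, precision: int | None = 2) -> pd.DataFrame:
        """Table-style frame: total body volume first, then structures in
        descending volume order; values optionally rounded for display."""
        order = np.argsort(self.volumes_um3)[::-1]
        rows = [("total body volume", self.tbv_um3, 100.0)]
        rows += [
            (self.structures[i], self.volumes_um3[i], self.pct_tbv[i]) for i in order
        ]
        df = pd.DataFrame(rows, columns=["structure", "volume_um3", "pct_tbv"])
        if precision is not None:
            df["volume_um3"] = df["volume_um3"].round(precision)
            df["pct_tbv"] = df["pct_tbv"].round(precision)
        return df


def label_volumes(lf: LabelField) -> MorphometryTable:
    """Per-structure voxel-count volumes and %TBV from a label field.

    Labels sharing a legend name (e.g. the individually labeled storage
    cells) are pooled into one structure row.  TBV is the volume of all
    nonzero labels — every body voxel is labeled matrix, organ or cell.
    """
    voxel_vol = lf.voxel_size**3
    labs, counts = np.unique(lf.labels, return_counts=True)
    nz = labs != 0
    labs, counts = labs[nz], counts[nz]
    if labs.size == 0:
        raise ValueError("label field has no body label: no TBV reference")
    tbv = float(counts.sum() * voxel_vol)
    by_structure: dict[str, tuple[list[int], float]] = {}
    for lab, cnt in zip(labs, counts):
        name = lf.legend[int(lab)]
        ids, vol = by_structure.get(name, ([], 0.0))
        ids.append(int(lab))
        by_structure[name] = (ids, vol + float(cnt) * voxel_vol)
    length, width = body_extents(lf.labels != 0, lf.voxel_size)
    names = list(by_structure)
    return MorphometryTable(
        structures=names,
        labels=[by_structure[n][0] for n in names],
        volumes_um3=[by_structure[n][1] for n in names],
        tbv_um3=tbv,
        body_length_um=length,
        body_width_um=width,
    )


def segment_cells(
    v: ReconVolume,
    mu_range: tuple[float, float],
    connectivity: int = 26,
    min_voxels: int = 4,
    structure_name: str = "storage cells",
) -> LabelField:
    """Threshold an attenuation band and label 26-connected components.

    Voxels with value in ``[lo, hi]`` form the mask; components smaller
    than ``min_voxels`` are discarded as noise specks; each surviving
    component receives its own label (all mapping to ``structure_name``).
    """
    lo, hi = mu_range
    if connectivity == 26:
        structure = _CONNECTIVITY_26
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    mask = (v.data >= lo) & (v.data <= hi)
    labeled, n = ndimage.label(mask, structure=structure)
    if n == 0:
        warnings.warn("empty mask: no components in the attenuation band")
        return LabelField(np.zeros(v.shape, dtype=np.uint16), v.voxel_size, {})
    counts = np.bincount(labeled.ravel())
    keep = np.flatnonzero(counts >= min_voxels)
    keep = keep[keep != 0]
    remap = np.zeros(n + 1, dtype=np.uint32)
    remap[keep] = np.arange(1, keep.size + 1)
    out = remap[labeled]
    legend = {int(i): structure_name for i in range(1, keep.size + 1)}
    return LabelField(out.astype(np.uint32), v.voxel_size, legend)


@dataclass
class CellStats:
    """Summary statistics of a set of storage cells."""

    n_cells: int
    volumes: np.ndarray  # um^3, descending
    bin_edges: np.ndarray
    histogram: np.ndarray
    equiv_diameters: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.equiv_diameters = equivalent_diameter(self.volumes)

    @property
    def total(self) -> float:
        return float(self.volumes.sum())

    @property
    def mean(self) -> float:
        return self.total / self.n_cells if self.n_cells else np.nan

    @property
    def min(self) -> float:
        return float(self.volumes.min()) if self.n_cells else np.nan

    @property
    def max(self) -> float:
        return float(self.volumes.max()) if self.n_cells else np.nan


def cell_stats(lf: LabelField, bin_width: float = 5.0) -> CellStats:
    """Per-cell volumes, histogram and sphere-equivalent diameters.

    Histogram bins start at zero with the given width (5 um^3 is the
    conventional bin for tardigrade storage-cell volume distributions).
    """
    if bin_width < 0:
        raise ValueError("bin width must be nonnegative")
    voxel_vol = lf.voxel_size**3
    counts = np.bincount(lf.labels.ravel())
    vols = counts[1:][counts[1:] > 0] * voxel_vol
    vols = np.sort(vols.astype(float))[::-1]
    n = vols.size
    if n == 0 or bin_width == 0:
        edges = np.array([0.0])
        hist = np.zeros(0, dtype=int)
    else:
        n_bins = int(np.ceil(vols.max() / bin_width)) or 1
        edges = np.arange(n_bins + 1) * bin_width
        hist, _ = np.histogram(vols, bins=edges)
    return CellStats(n_cells=n, volumes=vols, bin_edges=edges, histogram=hist)


def body_extents(
    body: LabelField | np.ndarray,
    voxel_size: float | None = None,
    exclusion_mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """Body length and maximum width, in um.

    Length is the extent of the body mask along the anterior-posterior
    axis (axis 0); width the maximum extent along the left-right axis
    (axis 1).  An exclusion mask (e.g. the hind legs, conventionally
    omitted from tardigrade length measurements) is removed from the
    mask first.
    """
    if isinstance(body, LabelField):
        mask = body.labels != 0
        voxel_size = body.voxel_size
    else:
        mask = np.asarray(body, dtype=bool)
        if voxel_size is None:
            raise ValueError("voxel_size required with a bare mask")
    if exclusion_mask is not None:
        mask = mask & ~exclusion_mask
    if not mask.any():
        raise ValueError("empty body mask")
    z = np.flatnonzero(mask.any(axis=(1, 2)))
    y = np.flatnonzero(mask.any(axis=(0, 2)))
    length = (z[-1] - z[0] + 1) * voxel_size
    width = (y[-1] - y[0] + 1) * voxel_size
    return float(length), float(width)


def report(
    table: MorphometryTable,
    stats: CellStats,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the morphometry report files.

    structures.csv is the specimen volume table (um^3 and %TBV at
    2 d.p.), cells.csv lists per-cell volumes and equivalent diameters,
    histogram.csv the binned distribution, and summary.txt a plain-text
    digest (count, mean, range, mean equivalent diameter at 1 d.p.).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "structures": out_dir / "structures.csv",
        "cells": out_dir / "cells.csv",
        "histogram": out_dir / "histogram.csv",
        "summary": out_dir / "summary.txt",
    }
    table.to_frame(precision=2).to_csv(paths["structures"], index=False)
    pd.DataFrame(
        {
            "cell": np.arange(1, stats.n_cells + 1),
            "volume_um3": np.round(stats.volumes, 2),
            "equiv_diameter_um": np.round(stats.equiv_diameters, 2),
        }
    ).to_csv(paths["cells"], index=False)
    pd.DataFrame(
        {
            "bin_lo_um3": stats.bin_edges[:-1],
            "bin_hi_um3": stats.bin_edges[1:],
            "count": stats.histogram,
        }
    ).to_csv(paths["histogram"], index=False)
    with open(paths["summary"], "w") as fh:
        fh.write(f"body length: {table.body_length_um:.1f} um\n")
        fh.write(f"body maximum width: {table.body_width_um:.1f} um\n")
        fh.write(f"total body volume: {table.tbv_um3:.2f} um^3\n")
        if stats.n_cells:
            fh.write(
                f"storage cells: n={stats.n_cells}, mean {stats.mean:.1f} um^3, "
                f"range {stats.min:.1f}-{stats.max:.1f} um^3, "
                f"mean equivalent diameter {equivalent_diameter(stats.mean):.1f} um\n"
            )
        else:
            fh.write("storage cells: n=0\n")
    return paths


def plot_cell_histogram(stats: CellStats, path: str | Path) -> Path:
    """Bar plot of the cell-volume distribution with the mean marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    widths = np.diff(stats.bin_edges)
    ax.bar(stats.bin_edges[:-1], stats.histogram, width=widths, align="edge",
           color="#4878cf", edgecolor="white")
    if stats.n_cells:
        ax.axvline(stats.mean, color="#ee854a", ls="--",
                   label=f"mean {stats.mean:.1f} $\\mu m^3$")
        ax.legend(frameon=False)
    ax.set_xlabel("cell volume ($\\mu m^3$)")
    ax.set_ylabel("number of cells")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
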