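"""File interchange: 3D TIFF volumes, label legends, projections, configs.

Volumes travel as multi-page TIFF stacks (one page per axis-0 slice),
float32 for intensities and uint16/uint32 for labels, with the voxel
size in the TIFF resolution tags and a JSON sidecar carrying voxel
size, provenance and resolved parameters.  Projection sets add a CSV
of view angles and a YAML geometry sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import ProjectionSet, ScanGeometry
from .volumes import LabelField, ReconVolume

__all__ = [
    "write_volume",
    "read_volume",
    "write_labels",
    "read_labels",
    "write_projections",
    "read_projections",
    "save_geometry",
    "load_geometry",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(path: str | Path, volume: ReconVolume | np.ndarray,
                 voxel_size: float | None = None, provenance: str = "unknown",
                 meta: dict | None = None) -> Path:
    """Write a 3D volume as a multi-page TIFF plus JSON sidecar.

    Float volumes are stored as float32, integer volumes with their
    integer dtype (uint16 when the range allows); round-trips are
    lossless for float32/uint16/uint32 data.
    """
    path = Path(path)
    if isinstance(volume, ReconVolume):
        data, voxel_size = volume.data, volume.voxel_size
        provenance, meta = volume.provenance, dict(volume.meta)
    else:
        data = np.asarray(volume)
        if voxel_size is None:
            raise ValueError("voxel_size required for a bare array")
    if data.ndim != 3:
        raise ValueError(f"expected a 3D stack, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    elif np.issubdtype(data.dtype, np.integer):
        if data.min() < 0:
            raise ValueError("integer volumes must be nonnegative")
        data = data.astype(np.uint16 if data.max() < 2**16 else np.uint32)
    else:
        raise ValueError(f"unsupported dtype {data.dtype}")
    path.parent.mkdir(parents=True, exist_ok=True)
    res = 1.0 / voxel_size
    tifffile.imwrite(
        path, data, photometric="minisblack",
        resolution=(res, res), metadata={"spacing": voxel_size, "unit": "um"},
    )
    sidecar = {
        "voxel_size_um": voxel_size,
        "provenance": provenance,
        "shape": list(data.shape),
        "dtype": str(data.dtype),
        "meta": _jsonable(meta or {}),
    }
    _sidecar(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_volume(path: str | Path, voxel_size: float | None = None) -> ReconVolume:
    """Read a multi-page TIFF volume written by :func:`write_volume`."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D TIFF stack, got {data.ndim}D data in {path}")
    provenance, meta = "unknown", {}
    sc = _sidecar(path)
    if sc.exists():
        info = json.loads(sc.read_text())
        voxel_size = info.get("voxel_size_um", voxel_size)
        provenance = info.get("provenance", provenance)
        meta = info.get("meta", {})
    if voxel_size is None:
        raise ValueError(f"no voxel size in sidecar of {path}; pass voxel_size")
    return ReconVolume(data, float(voxel_size), provenance=provenance, meta=meta)


def write_labels(path: str | Path, lf: LabelField) -> Path:
    """Label volume as TIFF plus a legend CSV (columns label,structure)."""
    path = Path(path)
    write_volume(path, lf.labels, voxel_size=lf.voxel_size, provenance="labels")
    legend = pd.DataFrame(
        sorted(lf.legend.items()), columns=["label", "structure"]
    )
    legend.to_csv(path.with_suffix(".legend.csv"), index=False)
    return path


def read_labels(path: str | Path) -> LabelField:
    path = Path(path)
    vol = read_volume(path)
    legend_path = path.with_suffix(".legend.csv")
    if not legend_path.exists():
        raise FileNotFoundError(f"missing legend CSV {legend_path}")
    df = pd.read_csv(legend_path)
    legend = {int(r.label): str(r.structure) for r in df.itertuples()}
    return LabelField(vol.data.astype(np.uint32), vol.voxel_size, legend)


def write_projections(path: str | Path, p: ProjectionSet) -> Path:
    """Projection stack as TIFF + angle CSV + geometry YAML sidecars."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, p.data.astype(np.float32), photometric="minisblack")
    pd.DataFrame({"angle_deg": p.angles_deg}).to_csv(
        path.with_suffix(".angles.csv"), index=False
    )
    save_geometry(path.with_suffix(".geometry.yaml"), p.geometry, extra={"domain": p.domain})
    return path


def read_projections(path: str | Path) -> ProjectionSet:
    path = Path(path)
    data = tifffile.imread(path)
    angles = pd.read_csv(path.with_suffix(".angles.csv"))["angle_deg"].to_numpy()
    info = yaml.safe_load(path.with_suffix(".geometry.yaml").read_text())
    domain = info.pop("domain", "line_integral")
    geom = geometry_from_dict(info)
    return ProjectionSet(data.astype(np.float64), angles, domain, geom)


_GEOM_KEYS = {
    "sod_mm": "sod",
    "sdd_mm": "sdd",
    "detector_shape": "detector_shape",
    "detector_pitch_um": "detector_pitch",
    "n_angles": "n_angles",
    "angle_range_deg": "angle_range_deg",
    "source_fwhm_nm": "source_fwhm",
}


def geometry_to_dict(geom: ScanGeometry) -> dict:
    d = dataclasses.asdict(geom)
    return {k: _jsonable(d[v]) for k, v in _GEOM_KEYS.items()}


def geometry_from_dict(info: dict) -> ScanGeometry:
    kwargs = {}
    for k, attr in _GEOM_KEYS.items():
        if k in info:
            kwargs[attr] = info[k]
        elif attr in info:
            kwargs[attr] = info[attr]
    if "detector_shape" in kwargs:
        kwargs["detector_shape"] = tuple(kwargs["detector_shape"])
    return ScanGeometry(**kwargs)


def save_geometry(path: str | Path, geom: ScanGeometry, extra: dict | None = None) -> Path:
    path = Path(path)
    d = geometry_to_dict(geom)
    if extra:
        d.update(_jsonable(extra))
    path.write_text(yaml.safe_dump(d, sort_keys=False))
    return path


def load_geometry(path: str | Path) -> ScanGeometry:
    return geometry_from_dict(yaml.safe_load(Path(path).read_text()))
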