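"""Reconstructed-volume and label-field containers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["ReconVolume", "LabelField"]


@dataclass
class ReconVolume:
    """A reconstructed 3D attenuation volume.

    ``data`` is attenuation in 1/um on the (z, y, x) grid; ``voxel_size``
    is in um.  ``provenance`` records how the volume was produced
    ("FBP", "SIR", "phantom", ...) and ``meta`` carries resolved
    reconstruction parameters.
    """

    data: np.ndarray
    voxel_size: float
    provenance: str = "unknown"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelField:
    """Integer label volume with a legend mapping labels to structures.

    0 is background; every nonzero label must appear in the legend.
    A structure may own several labels (each storage cell carries its
    own label but all map to the shared "storage cells" entry).
    """

    labels: np.ndarray
    voxel_size: float
    legend: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"label field must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels missing from legend: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def structure_labels(self, name: str) -> list[int]:
        return [lab for lab, s in self.legend.items() if s == name]

    def mask(self, name: str) -> np.ndarray:
        labs = self.structure_labels(name)
        return np.isin(self.labels, labs)
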