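"""Core containers shared by every pipeline stage.

Conventions used throughout the package:

* volumes are 3-D arrays indexed ``(z, y, x)`` with 0-based voxel indices;
* point coordinates are stored in the same ``(z, y, x)`` axis order, either
  in voxel units or in micrometres (the ``space`` tag records which);
* the default acquisition grid is isotropic at 3.6 um per voxel, the
  resolution of the light-sheet setup the package targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_VOXEL_SIZE_UM = 3.6


def _as_voxel_size(voxel_size_um) -> np.ndarray:
    v = np.broadcast_to(np.asarray(voxel_size_um, dtype=float), (3,)).copy()
    if not np.all(v > 0):
        raise ValueError(f"voxel_size_um must be positive, got {voxel_size_um!r}")
    return v


@dataclass
class Volume:
    """A 3-D intensity grid with voxel-size metadata.

    ``data`` is ``(z, y, x)``; ``voxel_size_um`` is the per-axis physical
    scale in micrometres (scalar input is broadcast to all three axes).
    """

    data: np.ndarray
    voxel_size_um: np.ndarray = field(default_factory=lambda: np.full(3, DEFAULT_VOXEL_SIZE_UM))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.voxel_size_um = _as_voxel_size(self.voxel_size_um)

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class CellCenters:
    """An ordered set of 3-D points (soma centers).

    ``points`` is an ``(n, 3)`` float array in ``(z, y, x)`` order; ``space``
    tags the coordinate units ("voxel" or "um").  ``labels`` optionally
    carries a per-point tag (annotator id, layer id, ...).
    """

    points: np.ndarray
    space: str = "voxel"
    labels: np.ndarray | None = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got shape {pts.shape}")
        self.points = pts
        if self.space not in ("voxel", "um"):
            raise ValueError(f"space must be 'voxel' or 'um', got {self.space!r}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(pts):
                raise ValueError("labels length must match number of points")

    def __len__(self) -> int:
        return len(self.points)

    def to_um(self, voxel_size_um) -> "CellCenters":
        """Return a copy in micrometre space (identity if already in um)."""
        if self.space == "um":
            return CellCenters(self.points.copy(), "um", self.labels)
        v = _as_voxel_size(voxel_size_um)
        return CellCenters(self.points * v, "um", self.labels)

    def to_voxel(self, voxel_size_um) -> "CellCenters":
        """Return a copy in voxel space (identity if already in voxels)."""
        if self.space == "voxel":
            return CellCenters(self.points.copy(), "voxel", self.labels)
        v = _as_voxel_size(voxel_size_um)
        return CellCenters(self.points / v, "voxel", self.labels)
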