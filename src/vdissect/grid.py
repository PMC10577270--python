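"""Voxel-grid domain types shared by every stage of the pipeline.

Conventions
-----------
* Arrays are indexed ``(i, j, k)`` in axis order ``(x, y, z)``.
* Indices are 0-based; world coordinates use the voxel-*center* convention:
  ``world = origin + index * spacing`` componentwise, in millimetres.
* The anatomical frame is fixed: ``+x`` = patient left, ``+y`` = anterior,
  ``+z`` = superior.  NIfTI volumes with other orientations are reduced to
  this frame on load (see :mod:`vdissect.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage


class Label:
    """Integer label codes for dissected atrial structures."""

    BACKGROUND = 0
    LA = 1
    LSPV = 2
    LIPV = 3
    RSPV = 4
    RIPV = 5
    LAA = 6
    COMMON_LEFT_TRUNK = 7
    SUPPLEMENTAL = 8  # first supplemental code; further ones are 9, 10, ...

    #: labels expected in the standard four-PV anatomy
    EXPECTED = (LSPV, LIPV, RSPV, RIPV, LAA)

    NAMES = {
        0: "background",
        1: "LA",
        2: "LSPV",
        3: "LIPV",
        4: "RSPV",
        5: "RIPV",
        6: "LAA",
        7: "common_left_trunk",
        8: "supplemental",
    }

    @staticmethod
    def name(code: int) -> str:
        if code >= Label.SUPPLEMENTAL:
            return f"supplemental_{code - Label.SUPPLEMENTAL + 1}"
        return Label.NAMES.get(code, f"label_{code}")


#: provisional labels assigned by raw dissection start here
PROVISIONAL_BASE = 100


class StructuringElement(Enum):
    """Unit ball of one morphological step, by 3D digital connectivity."""

    FACE6 = 1
    EDGE18 = 2
    VERTEX26 = 3

    def footprint(self) -> np.ndarray:
        """3x3x3 boolean footprint (symmetric about its centre)."""
        return ndimage.generate_binary_structure(3, self.value)


def _as_triple(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a length-3 sequence, got shape {arr.shape}")
    return arr


@dataclass
class VoxelGrid:
    """3D boolean occupancy with anisotropic spacing (mm) and world origin.

    Parameters
    ----------
    occupancy : ndarray of bool, shape (nx, ny, nz)
    spacing : per-axis voxel size in mm, strictly positive
    origin : world-mm position of the centre of voxel (0, 0, 0)
    """

    occupancy: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 3 or min(self.occupancy.shape) < 1:
            raise ValueError("occupancy must be a 3D array with all dimensions >= 1")
        self.spacing = _as_triple(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple:
        return self.occupancy.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def volume_mm3(self) -> float:
        """Total occupied volume = count(true) * voxel volume."""
        return float(np.count_nonzero(self.occupancy)) * self.voxel_volume

    @property
    def volume_ml(self) -> float:
        return self.volume_mm3 / 1000.0

    def world_coordinates(self, index) -> np.ndarray:
        """World-mm centre of the voxel at ``index`` (0-based, in bounds)."""
        idx = np.asarray(index)
        if idx.shape[-1] != 3:
            raise ValueError("index must have 3 components")
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            raise IndexError(f"index {index} out of bounds for shape {self.shape}")
        return self.origin + idx * self.spacing

    def indices_world(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World-mm centres of all foreground voxels (of ``mask`` if given)."""
        m = self.occupancy if mask is None else mask
        idx = np.argwhere(m)
        return self.origin + idx * self.spacing

    def centroid_mm(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Mass centroid of foreground voxel centres in mm."""
        m = self.occupancy if mask is None else mask
        if not m.any():
            raise ValueError("cannot take centroid of empty mask")
        idx_mean = np.mean(np.argwhere(m), axis=0)
        return self.origin + idx_mean * self.spacing

    def with_occupancy(self, occupancy: np.ndarray) -> "VoxelGrid":
        """New grid with the same geometry and a different occupancy."""
        return VoxelGrid(occupancy, self.spacing.copy(), self.origin.copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, VoxelGrid):
            return NotImplemented
        return (
            self.occupancy.shape == other.occupancy.shape
            and np.array_equal(self.occupancy, other.occupancy)
            and np.allclose(self.spacing, other.spacing, atol=1e-6)
            and np.allclose(self.origin, other.origin, atol=1e-6)
        )


@dataclass
class AtriumLabelMap:
    """Integer-labelled volume on a voxel grid.

    Label codes: 0 background, 1 LA body, 2 LSPV, 3 LIPV, 4 RSPV, 5 RIPV,
    6 LAA, 7 common left trunk, >=8 supplemental PVs.  Raw dissection uses
    provisional codes >= 100 until structures are classified.
    """

    labels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = np.round(self.labels).astype(np.int16)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        self.spacing = _as_triple(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def grid(self) -> VoxelGrid:
        """Binary shell (all positive labels) as a VoxelGrid."""
        return VoxelGrid(self.labels > 0, self.spacing.copy(), self.origin.copy())

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def structure_labels(self) -> list:
        """Sorted positive labels other than the LA body."""
        present = np.unique(self.labels)
        return [int(v) for v in present if v > Label.LA]

    def volume_mm3(self, label: int) -> float:
        return float(np.count_nonzero(self.labels == label)) * self.voxel_volume

    def with_labels(self, labels: np.ndarray) -> "AtriumLabelMap":
        return AtriumLabelMap(labels, self.spacing.copy(), self.origin.copy())
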