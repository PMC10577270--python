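"""NIfTI reading and writing for label maps and binary shells.

Volumes are reduced on load to the package's fixed anatomical frame
(+x = left, +y = anterior, +z = superior, i.e. "LAS" axis codes).  Oblique
orientation matrices are snapped to the nearest axis permutation with a
logged warning: the dissection itself is rotation-invariant, only the final
structure classification relies on the anatomical frame.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel import orientations as nio

from .grid import AtriumLabelMap, VoxelGrid

logger = logging.getLogger(__name__)

#: internal axis codes: +x left, +y anterior, +z superior
_INTERNAL_AXCODES = ("L", "A", "S")


class FormatError(ValueError):
    """Raised for NIfTI content the pipeline cannot interpret."""


def _is_axis_aligned(affine: np.ndarray, tol: float = 1e-4) -> bool:
    rot = affine[:3, :3]
    # exactly one non-negligible entry per row and column
    nz = np.abs(rot) > tol * np.max(np.abs(rot))
    return bool(np.all(nz.sum(axis=0) == 1) and np.all(nz.sum(axis=1) == 1))


def read_labelmap(path) -> AtriumLabelMap:
    """Read a NIfTI-1/2 integer (or binary) volume as an AtriumLabelMap.

    Spacing is taken from the header; data are reoriented to the internal
    LAS frame.  Non-integer voxel data are accepted only if every value is
    within 1e-6 of an integer.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    affine = img.affine
    if not _is_axis_aligned(affine):
        logger.warning(
            "%s has an oblique orientation matrix; snapping to the nearest "
            "axis permutation (classification may be unreliable)",
            path.name,
        )
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.round(data)
        if np.max(np.abs(data - rounded)) > 1e-6:
            raise FormatError(f"{path}: non-integer voxel values")
        data = rounded
    data = data.astype(np.int16)

    # reorient to internal LAS
    # reorder/flip to RAS, then flip x to obtain the internal LAS frame
    to_ras = nio.ornt_transform(nio.io_orientation(affine), nio.axcodes2ornt(("R", "A", "S")))
    data_ras = nio.apply_orientation(data, to_ras)
    aff_ras = affine @ nio.inv_ornt_aff(to_ras, data.shape)
    # flip the first axis: +i becomes Left
    data_las = data_ras[::-1, :, :].copy()
    nx = data_las.shape[0]
    spacing = np.abs(np.array([aff_ras[0, 0], aff_ras[1, 1], aff_ras[2, 2]], dtype=float))
    # world (internal LAS mm: x_left = -x_RAS) of voxel (0,0,0) of data_las,
    # which is voxel (nx-1, 0, 0) of data_ras
    origin_ras_x = aff_ras[0, 3] + (nx - 1) * aff_ras[0, 0]
    origin = np.array([-origin_ras_x, aff_ras[1, 3], aff_ras[2, 3]], dtype=float)
    return AtriumLabelMap(data_las, spacing, origin)


def write_labelmap(labelmap: AtriumLabelMap, path) -> None:
    """Write an AtriumLabelMap as NIfTI (gzip transparent, by extension).

    The affine encodes the internal LAS frame in standard RAS world
    coordinates so that ``read_labelmap`` round-trips losslessly.
    """
    path = Path(path)
    sx, sy, sz = labelmap.spacing
    ox, oy, oz = labelmap.origin
    affine = np.array(
        [
            [-sx, 0.0, 0.0, -ox],
            [0.0, sy, 0.0, oy],
            [0.0, 0.0, sz, oz],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    img = nib.Nifti1Image(labelmap.labels.astype(np.int16), affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, str(path))


def read_shell(path) -> VoxelGrid:
    """Read a binary shell; any positive label counts as foreground."""
    labelmap = read_labelmap(path)
    return labelmap.grid


def write_shell(grid: VoxelGrid, path) -> None:
    write_labelmap(
        AtriumLabelMap(grid.occupancy.astype(np.int16), grid.spacing, grid.origin), path
    )
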