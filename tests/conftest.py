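import logging

import numpy as np
import pytest

import vdissect as vd

logging.getLogger("vdissect").setLevel(logging.ERROR)


def ball_mask(radius_vox: int, size: int | None = None) -> np.ndarray:
    """Digital ball: voxels whose centre lies within radius (in voxels)."""
    size = size or (2 * radius_vox + 3)
    c = (size - 1) / 2.0
    x, y, z = np.ogrid[:size, :size, :size]
    return (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius_vox**2


def ellipsoid_grid(semiaxes, spacing=1.0, margin=3) -> vd.VoxelGrid:
    """Rasterized axis-aligned ellipsoid, centred in its own grid."""
    semiaxes = np.asarray(semiaxes, dtype=float)
    spacing = np.full(3, spacing, dtype=float)
    shape = (2 * np.ceil(semiaxes / spacing) + 2 * margin + 1).astype(int)
    center = (shape - 1) / 2.0 * spacing
    idx = np.indices(shape).transpose(1, 2, 3, 0) * spacing
    rel = (idx - center) / semiaxes
    occ = np.einsum("...i,...i", rel, rel) <= 1.0
    return vd.VoxelGrid(occ, spacing)


@pytest.fixture(scope="session")
def standard_case():
    """One standard four-PV synthetic atrium at 1 mm (shared, read-only)."""
    spec = vd.sample_spec(7, "standard4pv")
    shell, truth = vd.rasterize(spec)
    return spec, shell, truth


@pytest.fixture(scope="session")
def standard_dissection(standard_case):
    """Auto-rule dissection of the shared standard case."""
    _, shell, _ = standard_case
    return vd.dissect(shell)
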