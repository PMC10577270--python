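"""Medial centerlines and perpendicular-plane ostial refinement.

Centerlines from the LA centroid to each dissected structure's centroid
are computed as minimum-cost paths on the voxel graph under the medialness
potential ``1/(d + eps)^2`` (``d`` = interior Euclidean distance to the
background), the discrete analogue of a Voronoi/medial-axis centerline.
The erosion-dilation boundary of each structure is then refined by a
cutting plane through the point where the centerline leaves the LA,
oriented perpendicular to the centerline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.graph import MCP_Geometric

from .grid import AtriumLabelMap, Label, VoxelGrid

logger = logging.getLogger(__name__)

#: softening of the medialness potential, mm
MEDIAL_EPS = 0.1


class NoPathError(RuntimeError):
    """Start and end lie in different components of the shell."""


@dataclass
class Centerline:
    """Ordered polyline of mm points with per-point medial radii (mm)."""

    points: np.ndarray  # (n, 3) world mm
    radii: np.ndarray  # (n,) distance to shell boundary, mm
    voxels: np.ndarray  # (n, 3) integer voxel indices

    def __len__(self) -> int:
        return len(self.points)

    @property
    def length_mm(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


@dataclass
class CutPlane:
    """Refinement plane: point on the centerline, unit normal (tangent),
    and local radius of influence (mm)."""

    point: np.ndarray
    normal: np.ndarray
    radius: float
    label: int = 0


def interior_distance(shell: VoxelGrid) -> np.ndarray:
    """Per-voxel Euclidean distance (mm) to the nearest background voxel.

    Anisotropy-aware; everything outside the grid counts as background, so
    an all-foreground grid measures distance to the grid border.  Zero on
    background voxels.
    """
    if not shell.occupancy.any():
        raise ValueError("interior distance undefined for an empty shell")
    padded = np.pad(shell.occupancy, 1)
    dist = ndimage.distance_transform_edt(padded, sampling=shell.spacing)
    return dist[1:-1, 1:-1, 1:-1]


def _snap_to_foreground(shell: VoxelGrid, point_mm) -> tuple:
    """Nearest foreground voxel index to a world point."""
    idx = np.round((np.asarray(point_mm) - shell.origin) / shell.spacing).astype(int)
    idx = np.clip(idx, 0, np.asarray(shell.shape) - 1)
    if shell.occupancy[tuple(idx)]:
        return tuple(idx)
    fg = np.argwhere(shell.occupancy)
    d2 = np.sum(((fg - idx) * shell.spacing) ** 2, axis=1)
    return tuple(fg[int(np.argmin(d2))])


def _medial_costs(shell: VoxelGrid, distance: np.ndarray | None = None) -> np.ndarray:
    if distance is None:
        distance = interior_distance(shell)
    costs = np.full(shell.shape, np.inf)
    fg = shell.occupancy
    costs[fg] = 1.0 / (distance[fg] + MEDIAL_EPS) ** 2
    return costs


def _trace(
    shell: VoxelGrid, distance: np.ndarray, mcp: MCP_Geometric, end_voxel: tuple
) -> Centerline:
    path = np.asarray(mcp.traceback(end_voxel), dtype=int)
    points = shell.origin + path * shell.spacing
    radii = distance[tuple(path.T)]
    return Centerline(points=points, radii=radii, voxels=path)


def medial_path(shell: VoxelGrid, start_mm, end_mm) -> Centerline:
    """Medialness-weighted shortest path between two interior points.

    Endpoints are snapped to the nearest foreground voxel.  Per-step cost
    is the step length (mm) times the mean medialness ``1/(d+eps)^2`` of
    the two endpoints, which pulls the path onto the ridge of the interior
    distance field.  Deterministic.
    """
    distance = interior_distance(shell)
    start = _snap_to_foreground(shell, start_mm)
    end = _snap_to_foreground(shell, end_mm)
    if start == end:
        points = shell.origin + np.array([start]) * shell.spacing
        return Centerline(points=points, radii=distance[start][None], voxels=np.array([start]))
    mcp = MCP_Geometric(_medial_costs(shell, distance), sampling=tuple(shell.spacing))
    cum, _ = mcp.find_costs([start], [end])
    if not np.isfinite(cum[end]):
        raise NoPathError("start and end lie in different shell components")
    return _trace(shell, distance, mcp, end)


def _tangent(points: np.ndarray, i: int, window: int = 3) -> np.ndarray:
    """Central-difference tangent over +/-window samples (one-sided at ends)."""
    lo = max(0, i - window)
    hi = min(len(points) - 1, i + window)
    vec = points[hi] - points[lo]
    norm = np.linalg.norm(vec)
    if norm < 1e-9:
        return np.array([1.0, 0.0, 0.0])
    return vec / norm


def fit_la_ellipsoid(
    labelmap: AtriumLabelMap,
    label: int = Label.LA,
    trim_mm: float = 2.5,
    iterations: int = 3,
) -> tuple:
    """Trimmed moment-matched ellipsoid of the LA body.

    For a uniform solid ellipsoid the voxel-centre covariance equals
    ``diag(a^2, b^2, c^2) / 5`` in its principal frame, so the fitted
    semiaxes are ``sqrt(5 * eigenvalues)``.  Appendage tissue wrongly
    carried by the LA label (e.g. a swallowed appendage lens) inflates the
    fit along its axis, so the fit is re-run a few times excluding voxels
    protruding more than ``trim_mm`` beyond the current surface.

    Returns ``(center mm, principal-axis matrix (columns), semiaxes mm)``.
    """
    idx = np.argwhere(labelmap.labels == label)
    if len(idx) < 10:
        raise ValueError("too few LA voxels for an ellipsoid fit")
    pts = idx * labelmap.spacing
    keep = np.ones(len(pts), bool)
    for _ in range(max(1, iterations)):
        center = pts[keep].mean(axis=0)
        cov = np.cov((pts[keep] - center).T)
        eigvals, eigvecs = np.linalg.eigh(cov)
        semiaxes = np.sqrt(5.0 * np.clip(eigvals, 1e-9, None))
        rel = (pts - center) @ eigvecs
        q = np.linalg.norm(rel / semiaxes, axis=1)
        dist = np.linalg.norm(rel, axis=1)
        protrusion = (q - 1.0) * dist / np.maximum(q, 1e-9)
        new_keep = protrusion <= trim_mm
        if new_keep.sum() < 10 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    return labelmap.origin + center, eigvecs, semiaxes


def refine_boundaries(
    labelmap: AtriumLabelMap, shell: VoxelGrid | None = None
) -> tuple:
    """Refine LA-structure boundaries with perpendicular cut planes.

    The LA body is, by the model's core assumption, an ellipsoid; its
    moment-matched fit defines the reference surface at which every
    appendage ostium lies.  For each structure the medial centerline is
    traced from the LA centroid to the structure centroid, a cut plane is
    placed where the centerline crosses the fitted ellipsoid surface
    (falling back to the point where the centerline leaves LA-labelled
    voxels if it never crosses), oriented perpendicular to the local
    centerline tangent.  Voxels of the LA or that structure within twice
    the local medial radius of the crossing are reassigned by plane side
    (structure side = side of the structure centroid; voxels exactly on
    the plane go to the LA).  Boundaries already planar and in place to
    within one voxel are left untouched.  The shell partition is
    preserved.

    Returns ``(refined labelmap, list of CutPlane)``.
    """
    if shell is None:
        shell = labelmap.grid
    structures = labelmap.structure_labels()
    labels = labelmap.labels.copy()
    planes: list = []
    if not structures:
        return labelmap.with_labels(labels), planes

    la_mask = labelmap.labels == Label.LA
    if not la_mask.any():
        raise ValueError("labelmap has no LA body")
    grid_index = lambda m: shell.origin + np.mean(np.argwhere(m), axis=0) * shell.spacing
    la_centroid = grid_index(la_mask)
    distance = interior_distance(shell)
    start = _snap_to_foreground(shell, la_centroid)
    ends = {}
    for lab in structures:
        ends[lab] = _snap_to_foreground(shell, grid_index(labelmap.labels == lab))
    mcp = MCP_Geometric(_medial_costs(shell, distance), sampling=tuple(shell.spacing))
    cum, _ = mcp.find_costs([start], list(ends.values()))
    try:
        ell_center, ell_axes, ell_semiaxes = fit_la_ellipsoid(labelmap)
    except ValueError:
        ell_center = None

    for lab in structures:
        end = ends[lab]
        if not np.isfinite(cum[end]):
            logger.warning(
                "no centerline to %s; boundary left unrefined", Label.name(lab)
            )
            continue
        line = _trace(shell, distance, mcp, end)

        point = None
        cross = None
        if ell_center is not None:
            # last upward crossing of the fitted LA surface along the path
            q = np.linalg.norm(((line.points - ell_center) @ ell_axes) / ell_semiaxes, axis=1)
            ups = np.flatnonzero((q[:-1] <= 1.0) & (q[1:] > 1.0))
            if len(ups):
                i = int(ups[-1])
                f = (1.0 - q[i]) / (q[i + 1] - q[i])
                point = line.points[i] + f * (line.points[i + 1] - line.points[i])
                cross = i + 1
        if point is None:
            # fallback: where the centerline leaves LA-labelled voxels
            on_la = labels[tuple(line.voxels.T)] == Label.LA
            if on_la.all():
                logger.warning(
                    "centerline to %s never leaves the LA; boundary left unrefined",
                    Label.name(lab),
                )
                continue
            cross = int(np.argmin(on_la))
            point = line.points[cross]

        if ell_center is not None:
            # appendages attach radially in the ellipsoid model, so the
            # radial direction at the crossing is the ostial-plane normal;
            # it also guarantees the whole (convex) LA body lies on the
            # atrial side of the cut
            normal = point - ell_center
            normal = normal / np.linalg.norm(normal)
        else:
            normal = _tangent(line.points, cross)
        struct_centroid = grid_index(labelmap.labels == lab)
        side = np.sign(np.dot(struct_centroid - point, normal))
        if side == 0:
            side = 1.0
        # boundaries already planar to within ~one voxel are left alone:
        # a planar recut could only re-voxelize them
        faces = boundary_face_centers(labelmap, lab)
        already_planar = False
        if len(faces):
            axial = (faces - point) @ normal
            flatness = float(np.mean(np.abs(axial - np.median(axial))))
            already_planar = flatness <= float(np.max(shell.spacing))
        near = int(np.argmin(np.linalg.norm(line.points - point, axis=1)))
        # the influence region must span both the wavefront overshoot and
        # any invaded lens between the plane and the structure, so it grows
        # to the structure's farthest voxel when that is the larger scale
        struct_pts = shell.origin + np.argwhere(labelmap.labels == lab) * shell.spacing
        struct_reach = float(np.max(np.linalg.norm(struct_pts - point, axis=1)))
        radius = max(
            2.0 * max(float(line.radii[near]), float(np.max(shell.spacing))),
            struct_reach,
        )
        planes.append(CutPlane(point=point, normal=normal * side, radius=radius, label=lab))
        if already_planar:
            continue

        # bounded, local reassignment inside the influence sphere
        lo = np.maximum(
            np.floor((point - radius - shell.origin) / shell.spacing).astype(int), 0
        )
        hi = np.minimum(
            np.ceil((point + radius - shell.origin) / shell.spacing).astype(int) + 1,
            np.asarray(shell.shape),
        )
        sub = tuple(slice(lo[i], hi[i]) for i in range(3))
        sub_labels = labels[sub]
        eligible = (sub_labels == Label.LA) | (sub_labels == lab)
        if not eligible.any():
            continue
        ii, jj, kk = np.meshgrid(
            np.arange(lo[0], hi[0]),
            np.arange(lo[1], hi[1]),
            np.arange(lo[2], hi[2]),
            indexing="ij",
        )
        coords = shell.origin + np.stack([ii, jj, kk], axis=-1) * shell.spacing
        rel = coords - point
        within = np.einsum("...i,...i", rel, rel) <= radius**2
        dot = rel @ (normal * side)
        region = eligible & within
        sub_labels[region & (dot > 0)] = lab
        sub_labels[region & (dot <= 0)] = Label.LA
        labels[sub] = sub_labels

    return labelmap.with_labels(labels), planes


def boundary_face_centers(
    labelmap: AtriumLabelMap, structure: int, other: int = Label.LA
) -> np.ndarray:
    """World-mm centres of faces shared between ``other`` and ``structure``."""
    la = labelmap.labels == other
    st = labelmap.labels == structure
    spacing, origin = labelmap.spacing, labelmap.origin
    centers = []
    for axis in range(3):
        for a, b in ((la, st), (st, la)):
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[axis] = slice(0, -1)
            sl_hi[axis] = slice(1, None)
            pairs = a[tuple(sl_lo)] & b[tuple(sl_hi)]
            idx = np.argwhere(pairs).astype(float)
            if len(idx):
                idx[:, axis] += 0.5
                centers.append(origin + idx * spacing)
    if not centers:
        return np.empty((0, 3))
    # the two orderings cover (other below structure) and (structure below
    # other) separately, so every shared face appears exactly once
    return np.vstack(centers)


class AdjacencyError(ValueError):
    """Structure absent or not face-adjacent to the LA."""


def centroid_boundary_distance(
    labelmap: AtriumLabelMap, structure: int, centroid: np.ndarray | None = None
) -> float:
    """Mean distance (mm) from the whole-shell centroid to the LA-structure
    boundary face centres.

    ``centroid`` overrides the default whole-shell (all positive labels)
    centroid, e.g. to use the LA body alone.
    """
    if not (labelmap.labels == structure).any():
        raise AdjacencyError(f"structure {structure} absent from labelmap")
    faces = boundary_face_centers(labelmap, structure)
    if len(faces) == 0:
        raise AdjacencyError(f"structure {structure} is not face-adjacent to the LA")
    if centroid is None:
        centroid = labelmap.grid.centroid_mm()
    return float(np.mean(np.linalg.norm(faces - np.asarray(centroid), axis=1)))
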