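"""Parametric digital atria with analytic ground truth.

A synthetic shell composites an ellipsoidal left atrium (LA), circular
cylinders for the pulmonary veins (PVs) and a paraboloid for the left
atrial appendage (LAA), optionally perturbed by a smooth random "bump"
field added to the implicit level set.  Each shell comes with analytic
ground truth: the owning primitive of every voxel, the ostial plane where
each appendage meets the ellipsoid, and the expected centroid-to-boundary
distance of each ostium.

Anatomical frame: +x = left, +y = anterior, +z = superior.  The four
standard PVs sit in the posterior (y < 0) left/right x superior/inferior
octants; the LAA points left-anterior-superior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import AtriumLabelMap, Label, VoxelGrid

logger = logging.getLogger(__name__)

VARIANTS = ("standard4pv", "common_left_trunk", "supplemental_pv", "no_laa")

#: CT-like resolution of typical cardiac acquisitions (in-plane x slice, mm)
CT_SPACING = (0.42, 0.42, 0.7)
#: fast isotropic preset used throughout the test suite
DEFAULT_SPACING = (1.0, 1.0, 1.0)

_LA_VOLUME_RANGE_ML = (71.0, 140.0)
_PV_RADIUS_RANGE = (4.0, 9.0)
_PV_LENGTH_RANGE = (15.0, 30.0)
_LAA_MOUTH_RANGE = (6.0, 12.0)
_LAA_DEPTH_RANGE = (15.0, 30.0)
_TRUNK_RADIUS_RANGE = (7.0, 9.0)
_SUPP_RADIUS_RANGE = (4.0, 6.0)

# canonical attachment directions (unnormalized), jittered per case
_PV_DIRECTIONS = {
    Label.LSPV: (1.0, -1.0, 1.0),
    Label.LIPV: (1.0, -1.0, -1.0),
    Label.RSPV: (-1.0, -1.0, 1.0),
    Label.RIPV: (-1.0, -1.0, -1.0),
}
_TRUNK_DIRECTION = (1.0, -1.0, 0.0)
_SUPP_DIRECTION = (-1.0, -1.0, 0.0)  # right middle PV
_LAA_DIRECTION = (1.0, 1.0, 0.7)


class GenerationError(RuntimeError):
    """Raised when a spec cannot be rasterized into a connected shell."""


@dataclass(frozen=True)
class PVSpec:
    """One tubular appendage: unit attach direction, radius and length (mm)."""

    direction: tuple
    radius: float
    length: float
    label: int


@dataclass(frozen=True)
class LAASpec:
    """Paraboloidal appendage: unit axis, mouth radius and depth (mm)."""

    axis: tuple
    mouth_radius: float
    depth: float


@dataclass(frozen=True)
class AtriumSpec:
    """Parametric description of one synthetic atrium."""

    la_semiaxes: tuple
    la_center: tuple
    pv_specs: tuple
    laa_spec: LAASpec | None
    bump_amplitude: float
    variant: str
    seed: int

    @property
    def la_volume_ml(self) -> float:
        a, b, c = self.la_semiaxes
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0


@dataclass
class GroundTruth:
    """Analytic truth for a rasterized atrium."""

    labelmap: AtriumLabelMap
    #: per structure label: (point mm, unit normal) of the ostial plane
    ostial_planes: dict
    #: per structure label: analytic mean centroid-to-ostial-boundary distance (mm)
    analytic_cbd: dict


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _jitter_direction(rng: np.random.Generator, direction, max_deg: float) -> np.ndarray:
    """Rotate ``direction`` by a random angle <= max_deg about a random axis."""
    d = _unit(direction)
    angle = np.deg2rad(rng.uniform(0.0, max_deg))
    # random axis perpendicular to d
    r = rng.normal(size=3)
    axis = r - np.dot(r, d) * d
    if np.linalg.norm(axis) < 1e-9:
        axis = np.array([d[1], -d[0], 0.0])
    axis = _unit(axis)
    return d * np.cos(angle) + np.cross(axis, d) * np.sin(angle)


def sample_spec(seed: int, variant: str = "standard4pv") -> AtriumSpec:
    """Draw a reproducible atrium spec with LA volume uniform in 71-140 ml.

    PV radii are uniform in [4, 9] mm (clamped below half the smallest LA
    semiaxis), lengths in [15, 30] mm; the LAA mouth radius is uniform in
    [6, 12] mm with depth in [15, 30] mm.  Variants transform the standard
    four-PV layout: ``common_left_trunk`` merges the left PVs into one
    trunk, ``supplemental_pv`` adds a fifth (right middle) vein, ``no_laa``
    removes the appendage.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))

    volume_ml = rng.uniform(*_LA_VOLUME_RANGE_ML)
    ratio_b = rng.uniform(0.78, 0.95)
    ratio_c = rng.uniform(0.62, 0.85)
    a = (volume_ml * 1000.0 * 3.0 / (4.0 * np.pi * ratio_b * ratio_c)) ** (1.0 / 3.0)
    semiaxes = (a, ratio_b * a, ratio_c * a)
    min_axis = min(semiaxes)
    max_radius = min_axis / 2.0 - 0.5

    def pv(label: int, direction, radius_range, jitter_deg=15.0) -> PVSpec:
        d = _jitter_direction(rng, direction, jitter_deg)
        radius = min(rng.uniform(*radius_range), max_radius)
        length = rng.uniform(*_PV_LENGTH_RANGE)
        return PVSpec(tuple(d), float(radius), float(length), label)

    pv_specs = []
    if variant == "common_left_trunk":
        pv_specs.append(pv(Label.COMMON_LEFT_TRUNK, _TRUNK_DIRECTION, _TRUNK_RADIUS_RANGE))
    else:
        pv_specs.append(pv(Label.LSPV, _PV_DIRECTIONS[Label.LSPV], _PV_RADIUS_RANGE))
        pv_specs.append(pv(Label.LIPV, _PV_DIRECTIONS[Label.LIPV], _PV_RADIUS_RANGE))
    pv_specs.append(pv(Label.RSPV, _PV_DIRECTIONS[Label.RSPV], _PV_RADIUS_RANGE))
    pv_specs.append(pv(Label.RIPV, _PV_DIRECTIONS[Label.RIPV], _PV_RADIUS_RANGE))
    if variant == "supplemental_pv":
        # tighter jitter keeps the extra vein clear of its neighbours
        pv_specs.append(pv(Label.SUPPLEMENTAL, _SUPP_DIRECTION, _SUPP_RADIUS_RANGE, jitter_deg=8.0))

    laa = None
    if variant != "no_laa":
        axis = _jitter_direction(rng, _LAA_DIRECTION, 15.0)
        laa = LAASpec(
            axis=tuple(axis),
            mouth_radius=float(min(rng.uniform(*_LAA_MOUTH_RANGE), max_radius + 2.0)),
            depth=float(rng.uniform(*_LAA_DEPTH_RANGE)),
        )

    return AtriumSpec(
        la_semiaxes=tuple(float(s) for s in semiaxes),
        la_center=(0.0, 0.0, 0.0),
        pv_specs=tuple(pv_specs),
        laa_spec=laa,
        bump_amplitude=1.5,
        variant=variant,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# implicit geometry


def _ellipsoid_sdf(points: np.ndarray, center, semiaxes) -> np.ndarray:
    """Approximate signed distance (mm) to an axis-aligned ellipsoid."""
    p = (points - np.asarray(center)) / np.asarray(semiaxes)
    rho = np.linalg.norm(p, axis=-1)
    grad = np.linalg.norm(p / np.asarray(semiaxes), axis=-1)
    grad = np.maximum(grad, 1e-9)
    return (rho - 1.0) * rho / grad


def _ray_ellipsoid_surface(origin, direction, center, semiaxes) -> np.ndarray:
    """Intersection of the ray origin + t*direction (t > 0) with the surface."""
    o = (np.asarray(origin) - np.asarray(center)) / np.asarray(semiaxes)
    d = np.asarray(direction) / np.asarray(semiaxes)
    A = np.dot(d, d)
    B = 2.0 * np.dot(o, d)
    C = np.dot(o, o) - 1.0
    disc = B * B - 4.0 * A * C
    if disc < 0:
        raise GenerationError("appendage axis does not intersect the ellipsoid")
    t = (-B + np.sqrt(disc)) / (2.0 * A)
    return np.asarray(origin) + t * np.asarray(direction)


def _cylinder_sdf(points: np.ndarray, p0, direction, radius, length) -> np.ndarray:
    """Signed distance to a capped cylinder from p0 along direction."""
    d = _unit(direction)
    rel = points - np.asarray(p0)
    t = rel @ d
    radial = np.linalg.norm(rel - t[..., None] * d, axis=-1)
    dr = radial - radius
    da = np.maximum(-t, t - length)
    outside = np.sqrt(np.maximum(dr, 0.0) ** 2 + np.maximum(da, 0.0) ** 2)
    inside = np.minimum(np.maximum(dr, da), 0.0)
    return outside + inside


def _paraboloid_sdf(points: np.ndarray, mouth, axis, mouth_radius, depth) -> np.ndarray:
    """Approximate signed distance to a paraboloid pouch.

    The pouch opens at ``mouth`` and closes at ``mouth + depth*axis``; the
    radius at axial depth t is ``mouth_radius * sqrt(1 - t/depth)``.
    """
    d = _unit(axis)
    rel = points - np.asarray(mouth)
    t = rel @ d
    radial = np.linalg.norm(rel - t[..., None] * d, axis=-1)
    frac = np.clip(1.0 - t / depth, 0.0, None)
    r_t = mouth_radius * np.sqrt(frac)
    # radial implicit, normalized to ~mm by the local gradient magnitude
    dr = (radial**2 - r_t**2) / (2.0 * mouth_radius)
    # the mouth reaches 6 mm into the LA so the pouch stays attached even at
    # oblique incidence on a curved, bump-perturbed surface (LA owns overlaps)
    da = np.maximum(-t - 6.0, t - depth)
    return np.maximum(dr, da)


def _bump_field(spec: AtriumSpec, points: np.ndarray) -> np.ndarray:
    """Smooth zero-mean perturbation: sum of 10 random-direction cosines."""
    if spec.bump_amplitude <= 0:
        return np.zeros(points.shape[:-1])
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xB0B5]))
    n_waves = 10
    out = np.zeros(points.shape[:-1])
    for _ in range(n_waves):
        k = _unit(rng.normal(size=3)) * (2.0 * np.pi / rng.uniform(30.0, 60.0))
        phase = rng.uniform(0.0, 2.0 * np.pi)
        out += np.cos(points @ k + phase)
    return spec.bump_amplitude * out / np.sqrt(n_waves)


def _primitive_sdfs(spec: AtriumSpec, points: np.ndarray) -> dict:
    """Signed distances of every primitive, keyed by structure label (LA = 1)."""
    center = np.asarray(spec.la_center)
    semiaxes = np.asarray(spec.la_semiaxes)
    sdfs = {Label.LA: _ellipsoid_sdf(points, center, semiaxes)}
    for pv in spec.pv_specs:
        attach = _ray_ellipsoid_surface(center, pv.direction, center, semiaxes)
        # 8 mm overlap into the LA keeps wide, obliquely attached veins
        # connected across the curved, bump-perturbed surface
        p0 = attach - 8.0 * _unit(pv.direction)
        sdfs[pv.label] = _cylinder_sdf(points, p0, pv.direction, pv.radius, pv.length + 8.0)
    if spec.laa_spec is not None:
        attach = _ray_ellipsoid_surface(center, spec.laa_spec.axis, center, semiaxes)
        sdfs[Label.LAA] = _paraboloid_sdf(
            points, attach, spec.laa_spec.axis, spec.laa_spec.mouth_radius, spec.laa_spec.depth
        )
    return sdfs


def _ostial_planes(spec: AtriumSpec) -> dict:
    """Analytic planes where each appendage axis pierces the ellipsoid."""
    center = np.asarray(spec.la_center)
    semiaxes = np.asarray(spec.la_semiaxes)
    planes = {}
    for pv in spec.pv_specs:
        point = _ray_ellipsoid_surface(center, pv.direction, center, semiaxes)
        planes[pv.label] = (point, _unit(pv.direction))
    if spec.laa_spec is not None:
        point = _ray_ellipsoid_surface(center, spec.laa_spec.axis, center, semiaxes)
        planes[Label.LAA] = (point, _unit(spec.laa_spec.axis))
    return planes


def _structure_radius(spec: AtriumSpec, label: int) -> float:
    if spec.laa_spec is not None and label == Label.LAA:
        return spec.laa_spec.mouth_radius
    for pv in spec.pv_specs:
        if pv.label == label:
            return pv.radius
    raise KeyError(label)


def _analytic_cbd(spec: AtriumSpec, centroid: np.ndarray, n_samples: int = 512) -> dict:
    """Quadrature of mean centroid-to-ostial-boundary distance per structure.

    Boundary points are sampled on the ideal ellipsoid surface inside each
    appendage's cross-section (the truth LA/appendage interface, since the
    LA owns all overlaps).
    """
    center = np.asarray(spec.la_center)
    semiaxes = np.asarray(spec.la_semiaxes)
    out = {}
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xCBD]))
    for label, (point, normal) in _ostial_planes(spec).items():
        radius = _structure_radius(spec, label)
        # orthonormal basis of the ostial plane
        u = np.cross(normal, [0.0, 0.0, 1.0])
        if np.linalg.norm(u) < 1e-6:
            u = np.cross(normal, [0.0, 1.0, 0.0])
        u = _unit(u)
        v = np.cross(normal, u)
        rr = radius * np.sqrt(rng.uniform(0.0, 1.0, n_samples))
        th = rng.uniform(0.0, 2.0 * np.pi, n_samples)
        disc = point + rr[:, None] * (np.cos(th)[:, None] * u + np.sin(th)[:, None] * v)
        surf = np.array(
            [_ray_ellipsoid_surface(center, q - center, center, semiaxes) for q in disc]
        )
        out[label] = float(np.mean(np.linalg.norm(surf - centroid, axis=1)))
    return out


def rasterize(spec: AtriumSpec, spacing=DEFAULT_SPACING) -> tuple:
    """Voxelize a spec into a binary shell and its ground truth.

    The grid is auto-sized to the union of primitives with a 5-voxel
    margin.  Truth labels assign each shell voxel to its owning primitive,
    the LA winning all overlaps (so truth boundaries coincide with the
    analytic ostial surfaces).  The shell is guaranteed one 6-connected
    component; negligible bump-induced specks (< 1% of the foreground) are
    dropped, anything larger raises :class:`GenerationError`.
    """
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")

    center = np.asarray(spec.la_center)
    semiaxes = np.asarray(spec.la_semiaxes)
    # bounding box over all primitives
    lo = center - semiaxes
    hi = center + semiaxes
    for pv in spec.pv_specs:
        tip = _ray_ellipsoid_surface(center, pv.direction, center, semiaxes) + (
            pv.length * _unit(pv.direction)
        )
        lo = np.minimum(lo, tip - pv.radius)
        hi = np.maximum(hi, tip + pv.radius)
    if spec.laa_spec is not None:
        attach = _ray_ellipsoid_surface(center, spec.laa_spec.axis, center, semiaxes)
        tip = attach + spec.laa_spec.depth * _unit(spec.laa_spec.axis)
        lo = np.minimum(lo, tip - spec.laa_spec.mouth_radius)
        hi = np.maximum(hi, tip + spec.laa_spec.mouth_radius)
    margin = spec.bump_amplitude + 5.0 * spacing
    lo -= margin
    hi += margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    origin = lo

    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    points = origin + np.stack([ii, jj, kk], axis=-1) * spacing

    sdfs = _primitive_sdfs(spec, points)
    bump = _bump_field(spec, points)
    stack_labels = list(sdfs.keys())
    stack = np.stack([sdfs[l] for l in stack_labels], axis=0) - bump[None]

    shell = np.any(stack < 0, axis=0)
    if not shell.any():
        raise GenerationError("spec rasterized to an empty shell")

    # keep a single 6-connected component
    comp, n_comp = ndimage.label(shell, structure=ndimage.generate_binary_structure(3, 1))
    if n_comp > 1:
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n_comp + 1))
        main = int(np.argmax(sizes)) + 1
        stray = shell.sum() - sizes[main - 1]
        if stray > 0.01 * shell.sum():
            raise GenerationError(
                f"shell disconnected: {n_comp} components, {stray:.0f} stray voxels"
            )
        logger.debug("dropping %d stray speck voxels", int(stray))
        shell = comp == main

    # ownership: LA wins overlaps; otherwise nearest primitive by signed value
    owner_idx = np.argmin(stack, axis=0)
    labels = np.zeros(shape, dtype=np.int16)
    labels[shell] = np.asarray(stack_labels, dtype=np.int16)[owner_idx[shell]]
    la_inside = sdfs[Label.LA] - bump < 0
    labels[shell & la_inside] = Label.LA

    labelmap = AtriumLabelMap(labels, spacing, origin)
    shell_grid = VoxelGrid(shell, spacing, origin)
    centroid = shell_grid.centroid_mm()
    truth = GroundTruth(
        labelmap=labelmap,
        ostial_planes=_ostial_planes(spec),
        analytic_cbd=_analytic_cbd(spec, centroid),
    )
    return shell_grid, truth


# ---------------------------------------------------------------------------
# cohort generation


def allocate_variants(n: int, mix: dict) -> list:
    """Deterministic largest-remainder allocation of variants to n cases."""
    if not mix:
        mix = {"standard4pv": 1.0}
    total = sum(mix.values())
    items = sorted(mix.items())
    raw = [(name, n * w / total) for name, w in items]
    counts = {name: int(np.floor(x)) for name, x in raw}
    remainder = n - sum(counts.values())
    by_frac = sorted(raw, key=lambda t: (-(t[1] - np.floor(t[1])), t[0]))
    for name, _ in by_frac[:remainder]:
        counts[name] += 1
    out = []
    for name, _ in items:
        out.extend([name] * counts[name])
    return out


def generate_cohort(
    n: int,
    seed: int,
    variant_mix: dict | None = None,
    spacing=DEFAULT_SPACING,
    output_dir=None,
) -> pd.DataFrame:
    """Write ``n`` shell/truth NIfTI pairs plus a manifest table.

    Case seeds are ``seed, seed+1, ...``; variants follow a deterministic
    largest-remainder allocation of ``variant_mix``.  Returns the manifest
    (also written as ``manifest.csv`` when ``output_dir`` is given).
    """
    from .io import write_labelmap, write_shell

    if n < 1:
        raise ValueError("n must be >= 1")
    variants = allocate_variants(n, variant_mix or {"standard4pv": 1.0})
    rows = []
    for i, variant in enumerate(variants):
        case_seed = int(seed) + i
        spec = sample_spec(case_seed, variant)
        shell, truth = rasterize(spec, spacing)
        row = {
            "case": f"case_{i:03d}",
            "seed": case_seed,
            "variant": variant,
            "la_volume_ml": spec.la_volume_ml,
        }
        for label, cbd in sorted(truth.analytic_cbd.items()):
            row[f"cbd_{Label.name(label)}_mm"] = cbd
        if output_dir is not None:
            out = Path(output_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_shell(shell, out / f"{row['case']}_shell.nii.gz")
            write_labelmap(truth.labelmap, out / f"{row['case']}_truth.nii.gz")
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if output_dir is not None:
        manifest.to_csv(Path(output_dir) / "manifest.csv", index=False, float_format="%.6f")
    return manifest
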