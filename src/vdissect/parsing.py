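"""Anatomical identity assignment and SVM iteration-count prediction.

Dissected remnants are named (LSPV/LIPV/RSPV/RIPV/LAA, common left trunk,
supplemental) by the octant of their centroid relative to the LA centroid
in the fixed anatomical frame (+x left, +y anterior, +z superior).  A pair
of small SVM classifiers, trained on a handful of "seed" shells whose
optimal iteration counts were found by exhaustive sweep against ground
truth, predicts erosion and dilation counts for new shells from global
shape features.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.svm import SVR

from .grid import PROVISIONAL_BASE, AtriumLabelMap, Label, StructuringElement, VoxelGrid
from .metrics import surface_area_mm2
from .morphology import binary_dilate_geodesic, dissect_raw, erosion_index

logger = logging.getLogger(__name__)

_FACE6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class ShapeFeatures:
    """Global 3D shape descriptors of a shell, the SVM feature set."""

    volume_mm3: float
    surface_area_mm2: float
    sphericity: float
    solidity: float
    extent_x_mm: float
    extent_y_mm: float
    extent_z_mm: float
    elongation: float

    def as_vector(self) -> np.ndarray:
        return np.array(
            [
                self.volume_mm3,
                self.surface_area_mm2,
                self.sphericity,
                self.solidity,
                self.extent_x_mm,
                self.extent_y_mm,
                self.extent_z_mm,
                self.elongation,
            ]
        )

    NAMES = (
        "volume_mm3",
        "surface_area_mm2",
        "sphericity",
        "solidity",
        "extent_x_mm",
        "extent_y_mm",
        "extent_z_mm",
        "elongation",
    )


def extract_features(shell: VoxelGrid) -> ShapeFeatures:
    """Compute shape features of a (whole) shell.

    Volume by voxel count, surface area by boundary-face counting,
    isoperimetric sphericity, solidity (the erosion index of the shell),
    bounding-box extents in mm and the major/minor principal-axis
    elongation from the voxel-centre covariance.
    """
    occ = shell.occupancy
    if not occ.any():
        raise ValueError("cannot extract features from an empty shell")
    volume = np.count_nonzero(occ) * shell.voxel_volume
    area = surface_area_mm2(occ, shell.spacing)
    sphericity = float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area)
    solidity = erosion_index(shell)
    idx = np.argwhere(occ)
    extents = (idx.max(axis=0) - idx.min(axis=0) + 1) * shell.spacing
    centred = (idx - idx.mean(axis=0)) * shell.spacing
    if len(centred) > 1:
        eigvals = np.linalg.eigvalsh(np.cov(centred.T))
        eigvals = np.clip(eigvals, 1e-12, None)
        elongation = float(np.sqrt(eigvals[-1] / eigvals[0]))
    else:
        elongation = 1.0
    return ShapeFeatures(
        volume_mm3=float(volume),
        surface_area_mm2=float(area),
        sphericity=sphericity,
        solidity=float(solidity),
        extent_x_mm=float(extents[0]),
        extent_y_mm=float(extents[1]),
        extent_z_mm=float(extents[2]),
        elongation=elongation,
    )


# ---------------------------------------------------------------------------
# remnant classification


def classify_structures(raw: AtriumLabelMap, la_centroid=None) -> AtriumLabelMap:
    """Assign anatomical labels to provisional dissection remnants.

    Rules, applied to the remnant centroid relative to the LA centroid:
    left is x > 0, right x < 0; anterior-left remnants are the LAA
    (largest wins, extras become supplemental); posterior remnants split
    left/right and then superior/inferior by z.  A single left posterior
    remnant where two are expected is the common left trunk (label 7);
    remnants beyond the expected set become supplemental (8, 9, ...).
    Deterministic and independent of remnant enumeration order.
    """
    labels = raw.labels.copy()
    provisional = sorted(int(v) for v in np.unique(labels) if v >= PROVISIONAL_BASE)
    if not provisional:
        return raw.with_labels(labels)
    if la_centroid is None:
        la_mask = labels == Label.LA
        if not la_mask.any():
            raise ValueError("labelmap has no LA body")
        la_centroid = raw.origin + np.mean(np.argwhere(la_mask), axis=0) * raw.spacing
    la_centroid = np.asarray(la_centroid, dtype=float)

    info = []
    for p in provisional:
        mask = labels == p
        centroid = raw.origin + np.mean(np.argwhere(mask), axis=0) * raw.spacing
        rel = centroid - la_centroid
        info.append(
            {
                "provisional": p,
                "rel": rel,
                "volume": float(np.count_nonzero(mask)) * raw.voxel_volume,
            }
        )
    # enumeration-order independence: canonical ordering by centroid
    info.sort(key=lambda r: tuple(np.round(r["rel"], 6)))

    assignment: dict = {}
    supplemental: list = []

    left_anterior = [r for r in info if r["rel"][0] > 0 and r["rel"][1] > 0]
    left_posterior = [r for r in info if r["rel"][0] > 0 and r["rel"][1] <= 0]
    right_posterior = [r for r in info if r["rel"][0] <= 0 and r["rel"][1] <= 0]
    right_anterior = [r for r in info if r["rel"][0] <= 0 and r["rel"][1] > 0]

    if left_anterior:
        laa = max(left_anterior, key=lambda r: r["volume"])
        assignment[laa["provisional"]] = Label.LAA
        supplemental.extend(r for r in left_anterior if r is not laa)

    def split_superior_inferior(group, sup_label, inf_label, trunk_label=None):
        group = sorted(group, key=lambda r: -r["rel"][2])  # superior first
        if not group:
            return
        if len(group) == 1:
            if trunk_label is not None:
                assignment[group[0]["provisional"]] = trunk_label
            else:
                lab = sup_label if group[0]["rel"][2] > 0 else inf_label
                assignment[group[0]["provisional"]] = lab
            return
        assignment[group[0]["provisional"]] = sup_label
        assignment[group[-1]["provisional"]] = inf_label
        supplemental.extend(group[1:-1])

    split_superior_inferior(
        left_posterior, Label.LSPV, Label.LIPV, trunk_label=Label.COMMON_LEFT_TRUNK
    )
    split_superior_inferior(right_posterior, Label.RSPV, Label.RIPV)
    supplemental.extend(right_anterior)

    next_supp = Label.SUPPLEMENTAL
    for r in supplemental:
        assignment[r["provisional"]] = next_supp
        next_supp += 1

    out = labels.copy()
    for prov, final in assignment.items():
        out[labels == prov] = final
    return raw.with_labels(out)


def rescue_missed_structures(
    labelmap: AtriumLabelMap,
    min_structure_volume: float = 300.0,
    min_thickness: float = 2.5,
    min_protrusion: float = 3.0,
) -> AtriumLabelMap:
    """Detect appendages the erosion-dilation stage failed to separate.

    The LA body is modelled as an ellipsoid; LA-labelled voxels protruding
    more than ``min_protrusion`` mm beyond its moment-matched fit form
    residual components.  A residual that is structure-scale (volume and
    interior-radius thresholds as in the dissection stage) and not
    face-adjacent to an already-detected structure is a missed appendage
    (typically a wide-mouthed LAA the restored LA swallowed) and receives
    a fresh provisional label.
    """
    from .centerline import fit_la_ellipsoid
    from .morphology import structure_remnants

    try:
        center, axes, semiaxes = fit_la_ellipsoid(labelmap)
    except ValueError:
        return labelmap
    la_mask = labelmap.labels == Label.LA
    pts = labelmap.origin + np.argwhere(la_mask) * labelmap.spacing
    rel = (pts - center) @ axes
    q = np.linalg.norm(rel / semiaxes, axis=1)
    dist = np.linalg.norm(rel, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        protrusion = (q - 1.0) * dist / np.maximum(q, 1e-9)
    outside = np.zeros(labelmap.shape, bool)
    outside[tuple(np.argwhere(la_mask)[protrusion > min_protrusion].T)] = True
    if not outside.any():
        return labelmap
    comp, keep, _ = structure_remnants(
        outside, labelmap.spacing, min_structure_volume, min_thickness
    )
    if not keep:
        return labelmap
    labels = labelmap.labels.copy()
    existing = labels * ((labels > Label.LA) & (labels < PROVISIONAL_BASE))
    grown = ndimage.binary_dilation(existing > 0, structure=_FACE6)
    next_label = int(max(labels.max() + 1, PROVISIONAL_BASE))
    added = 0
    for ci in keep:
        mask = comp == ci
        if (mask & grown).any():
            continue  # touches a detected structure: it is that structure's lens
        labels[mask] = next_label
        next_label += 1
        added += 1
    if added:
        logger.info("ellipsoid-residual rescue added %d structure(s)", added)
    return labelmap.with_labels(labels)


# ---------------------------------------------------------------------------
# sweep-optimal iteration counts


def _structure_iou_mean(pred: AtriumLabelMap, truth: AtriumLabelMap) -> float:
    """Mean IoU over the truth's appendage structures (0 for an absent or
    non-overlapping prediction; 0.0 when the truth has no structures)."""
    truth_labels = truth.structure_labels()
    if not truth_labels:
        return 0.0
    total = 0.0
    for lab in truth_labels:
        t = truth.labels == lab
        p = pred.labels == lab
        union = np.count_nonzero(t | p)
        total += (np.count_nonzero(t & p) / union) if union else 0.0
    return total / len(truth_labels)


def dissection_score(
    shell: VoxelGrid,
    truth: AtriumLabelMap,
    n_e: int,
    n_d: int,
    element: StructuringElement = StructuringElement.FACE6,
    min_structure_volume: float = 300.0,
) -> float:
    """Mean structure IoU of a forced-(n_e, n_d) dissection against truth."""
    raw, _ = dissect_raw(
        shell, element, n_e=n_e, n_d=n_d, min_structure_volume=min_structure_volume
    )
    return _structure_iou_mean(classify_structures(raw), truth)


def sweep_optimal_iterations(
    shell: VoxelGrid,
    truth,
    n_max: int = 12,
    element: StructuringElement = StructuringElement.FACE6,
    min_structure_volume: float = 300.0,
    n_d_extra: int = 4,
) -> tuple:
    """Exhaustive search for the best erosion/dilation counts.

    Scans ``n_e`` in [1, n_max] and ``n_d`` in [0, n_e + n_d_extra],
    covering the same dilation range as the automatic rule, maximizing
    mean per-structure IoU against ground truth (ties to the smallest
    ``(n_e, n_d)`` lexicographically).  ``truth`` may be a GroundTruth or
    an AtriumLabelMap.

    Erosions and geodesic dilations are shared across the scan, so the
    cost is ~n_max erosions + O(n_max^2) incremental dilation steps.
    """
    truth_map = truth.labelmap if hasattr(truth, "labelmap") else truth
    footprint = element.footprint()
    best_score, best_pair = -1.0, (1, 0)
    eroded = shell.occupancy
    for n_e in range(1, n_max + 1):
        eroded = ndimage.binary_erosion(eroded, structure=footprint, border_value=0)
        if not eroded.any():
            break
        comp, n_comp = ndimage.label(eroded, structure=_FACE6)
        if n_comp > 1:
            sizes = np.bincount(comp.ravel())[1:]
            core = comp == (int(np.argmax(sizes)) + 1)
        else:
            core = eroded.astype(bool)
        eroded = core
        current = core
        for n_d in range(0, n_e + n_d_extra + 1):
            if n_d > 0:
                grown = (
                    ndimage.binary_dilation(current, structure=footprint)
                    & shell.occupancy
                )
                if np.array_equal(grown, current) and n_d > 1:
                    break
                current = grown
            labels = np.zeros(shell.shape, dtype=np.int16)
            labels[shell.occupancy] = Label.LA
            remnant = shell.occupancy & ~current
            rcomp, rn = ndimage.label(remnant, structure=_FACE6)
            next_label = PROVISIONAL_BASE
            if rn:
                sizes = np.bincount(rcomp.ravel())[1:] * shell.voxel_volume
                for ci in range(1, rn + 1):
                    if sizes[ci - 1] >= min_structure_volume:
                        labels[rcomp == ci] = next_label
                        next_label += 1
            raw = AtriumLabelMap(labels, shell.spacing, shell.origin)
            score = _structure_iou_mean(classify_structures(raw), truth_map)
            if score > best_score + 1e-12:
                best_score, best_pair = score, (n_e, n_d)
    return best_pair


# ---------------------------------------------------------------------------
# SVM predictor


class IterationPredictor:
    """Two SVMs predicting optimal erosion/dilation iteration counts.

    RBF-kernel support-vector *regression* on standardized shape features,
    rounded to the nearest integer and clamped to the observed training
    range — iteration counts are ordinal, and with the handful of seed
    cases typical here regression degrades gracefully toward the central
    training value where classification would latch onto the majority
    class.  With a single observed count the predictor degenerates to a
    constant.  Serializes to portable JSON by storing the (tiny) training
    set and refitting on load.
    """

    def __init__(self, X: np.ndarray, y_e: np.ndarray, y_d: np.ndarray, seed: int = 0):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) < 1:
            raise ValueError("need at least one training case")
        self.X = X
        self.y_e = np.asarray(y_e, dtype=int)
        self.y_d = np.asarray(y_d, dtype=int)
        self.seed = int(seed)
        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0)
        self.std_[self.std_ == 0] = 1.0
        Xs = (X - self.mean_) / self.std_
        self._clf_e = self._fit_one(Xs, self.y_e)
        self._clf_d = self._fit_one(Xs, self.y_d)

    def _fit_one(self, Xs, y):
        if len(np.unique(y)) < 2:
            return int(y[0])  # constant predictor
        reg = SVR(kernel="rbf", C=1.0, epsilon=0.5)
        reg.fit(Xs, y)
        return (reg, int(y.min()), int(y.max()))

    def _predict_one(self, clf, Xs):
        if isinstance(clf, int):
            return np.full(len(Xs), clf, dtype=int)
        reg, lo, hi = clf
        return np.clip(np.round(reg.predict(Xs)), lo, hi).astype(int)

    def predict(self, features) -> tuple:
        """Predicted ``(n_e, n_d)`` for one ShapeFeatures or feature vector."""
        vec = features.as_vector() if isinstance(features, ShapeFeatures) else np.asarray(features)
        Xs = (vec[None, :] - self.mean_) / self.std_
        return int(self._predict_one(self._clf_e, Xs)[0]), int(
            self._predict_one(self._clf_d, Xs)[0]
        )

    def save(self, path) -> None:
        payload = {
            "feature_names": list(ShapeFeatures.NAMES),
            "X": self.X.tolist(),
            "y_erosion": self.y_e.tolist(),
            "y_dilation": self.y_d.tolist(),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path) -> "IterationPredictor":
        payload = json.loads(Path(path).read_text())
        return cls(
            np.asarray(payload["X"]),
            np.asarray(payload["y_erosion"]),
            np.asarray(payload["y_dilation"]),
            payload.get("seed", 0),
        )


def fit_iteration_predictor(cases, seed: int = 0) -> IterationPredictor:
    """Fit the predictor from ``(ShapeFeatures, n_e, n_d)`` training cases."""
    if not cases:
        raise ValueError("empty case list")
    X = np.array(
        [
            (c[0].as_vector() if isinstance(c[0], ShapeFeatures) else np.asarray(c[0]))
            for c in cases
        ]
    )
    y_e = np.array([c[1] for c in cases], dtype=int)
    y_d = np.array([c[2] for c in cases], dtype=int)
    return IterationPredictor(X, y_e, y_d, seed=seed)
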