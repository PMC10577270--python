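"""Segmentation agreement metrics and cohort statistics.

Per-structure overlap (Dice, IoU with the IoU > 0.5 success criterion),
boundary accuracy (average surface distance, centroid-boundary distance)
and cohort-level agreement (Bland-Altman limits, Pearson correlation,
McNemar's exact test on paired success flags).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .centerline import AdjacencyError, centroid_boundary_distance
from .grid import AtriumLabelMap, Label

_FACE6 = ndimage.generate_binary_structure(3, 1)


def _check_same_grid(shape_a, shape_b):
    if tuple(shape_a) != tuple(shape_b):
        raise ValueError(f"grid mismatch: {shape_a} vs {shape_b}")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); 1 when both empty."""
    _check_same_grid(a.shape, b.shape)
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = np.count_nonzero(a) + np.count_nonzero(b)
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / denom


def iou_success(a: np.ndarray, b: np.ndarray, threshold: float = 0.5) -> tuple:
    """Jaccard index and the strict IoU > threshold success flag.

    A parse is deemed successful only when the overlap is strictly larger
    than the threshold (default 0.5).  Both-empty inputs score IoU 1 and
    success, by convention.
    """
    _check_same_grid(a.shape, b.shape)
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0, True
    iou = np.count_nonzero(a & b) / union
    return iou, bool(iou > threshold)


def _boundary_points(mask: np.ndarray, spacing) -> np.ndarray:
    """Centres (mm) of foreground voxels with a face-adjacent background
    neighbour; the outside of the grid counts as background."""
    padded = np.pad(mask, 1)
    eroded = ndimage.binary_erosion(padded, structure=_FACE6, border_value=0)
    boundary = padded & ~eroded
    idx = np.argwhere(boundary[1:-1, 1:-1, 1:-1])
    return idx * np.asarray(spacing)


def average_surface_distance(
    pred: np.ndarray, ref: np.ndarray, spacing=(1.0, 1.0, 1.0), symmetric: bool = False
) -> float:
    """Mean distance (mm) from prediction boundary points to the reference
    boundary.  ``symmetric=True`` averages both directions."""
    _check_same_grid(pred.shape, ref.shape)
    if not np.asarray(pred).any() or not np.asarray(ref).any():
        raise ValueError("average surface distance undefined for empty inputs")
    bp = _boundary_points(np.asarray(pred, dtype=bool), spacing)
    br = _boundary_points(np.asarray(ref, dtype=bool), spacing)
    forward = float(np.mean(cKDTree(br).query(bp)[0]))
    if not symmetric:
        return forward
    backward = float(np.mean(cKDTree(bp).query(br)[0]))
    return 0.5 * (forward + backward)


def la_volume(labelmap: AtriumLabelMap) -> float:
    """LA-body volume in ml (1 ml = 1000 mm^3)."""
    count = np.count_nonzero(labelmap.labels == Label.LA)
    if count == 0:
        raise ValueError("labelmap has no LA body")
    return count * labelmap.voxel_volume / 1000.0


def surface_area_mm2(mask: np.ndarray, spacing) -> float:
    """Exposed-face surface area of a voxel mask (boundary-face counting)."""
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    area = 0.0
    padded = np.pad(mask, 1)
    for axis in range(3):
        diff = np.diff(padded, axis=axis)
        face = np.prod(np.delete(spacing, axis))
        area += np.count_nonzero(diff) * face
    return float(area)


def sphericity_index(labelmap: AtriumLabelMap, label: int = Label.LA) -> float:
    """Isoperimetric sphericity pi^(1/3) (6V)^(2/3) / A of the LA body.

    Voxel face-counted surface area overestimates the area of smooth
    shapes (by roughly 1.5x for a sphere), so absolute values carry a
    consistent discretization bias; comparisons between maps on the same
    grid are unaffected.
    """
    mask = labelmap.labels == label
    if not mask.any():
        raise ValueError(f"label {label} absent")
    volume = np.count_nonzero(mask) * labelmap.voxel_volume
    area = surface_area_mm2(mask, labelmap.spacing)
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area)


def bland_altman(pairs) -> tuple:
    """Mean difference and 95% limits of agreement for paired measurements.

    ``pairs`` is a sequence of (prediction, reference); differences are
    prediction - reference; limits are mean ± 1.96 sd (n-1 denominator).
    Returns ``(mean_diff, lower_loa, upper_loa)``.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise ValueError("bland_altman needs >= 2 (prediction, reference) pairs")
    d = arr[:, 0] - arr[:, 1]
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def pearson_r(pairs) -> tuple:
    """Sample Pearson correlation and its two-sided p (t transform)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
        raise ValueError("pearson_r needs >= 3 pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson_r undefined with zero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def mcnemar_paired_success(flags_a, flags_b) -> float:
    """Exact binomial McNemar test on paired success flags.

    With ``b`` = cases where only method A succeeded and ``c`` = cases
    where only B succeeded, the two-sided p is
    ``min(1, 2 * BinomCDF(min(b, c); b + c, 0.5))``.
    """
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise ValueError("flag lists must be equal-length, non-empty")
    only_a = int(np.count_nonzero(a & ~b))
    only_b = int(np.count_nonzero(~a & b))
    n = only_a + only_b
    if n == 0:
        return 1.0
    return float(min(1.0, 2.0 * stats.binom.cdf(min(only_a, only_b), n, 0.5)))


@dataclass
class StructureMetrics:
    label: int
    name: str
    dice: float
    iou: float
    success: bool
    asd_mm: float | None
    cbd_pred_mm: float | None
    cbd_ref_mm: float | None


@dataclass
class AgreementReport:
    """Per-structure metric bundle for one case, plus the whole-shell Dice."""

    structures: list = field(default_factory=list)
    shell_dice: float = 1.0

    @property
    def all_success(self) -> bool:
        return all(s.success for s in self.structures)

    def metric(self, name: str) -> dict:
        return {s.label: getattr(s, name) for s in self.structures}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.structures])


def evaluate_case(pred: AtriumLabelMap, truth: AtriumLabelMap) -> AgreementReport:
    """Compare a predicted label map against ground truth.

    Every structure label present in either map is scored; a structure
    missing from one map gets Dice 0 and a failed success flag.  The LA
    body is scored like any structure; the whole-shell Dice is reported
    separately.
    """
    _check_same_grid(pred.shape, truth.shape)
    labels = sorted(
        set(np.unique(pred.labels)) | set(np.unique(truth.labels)) - {Label.BACKGROUND}
    )
    labels = [int(l) for l in labels if l > 0]
    report = AgreementReport(shell_dice=dice(pred.labels > 0, truth.labels > 0))
    for lab in labels:
        mask_p = pred.labels == lab
        mask_t = truth.labels == lab
        d = dice(mask_p, mask_t)
        iou, success = iou_success(mask_p, mask_t)
        if mask_p.any() and mask_t.any():
            asd = average_surface_distance(mask_p, mask_t, pred.spacing)
        else:
            asd, d, iou, success = None, 0.0, 0.0, False
        cbd_p = cbd_t = None
        if lab != Label.LA:
            try:
                cbd_p = centroid_boundary_distance(pred, lab)
            except AdjacencyError:
                pass
            try:
                cbd_t = centroid_boundary_distance(truth, lab)
            except AdjacencyError:
                pass
        report.structures.append(
            StructureMetrics(
                label=lab,
                name=Label.name(lab),
                dice=d,
                iou=iou,
                success=success,
                asd_mm=asd,
                cbd_pred_mm=cbd_p,
                cbd_ref_mm=cbd_t,
            )
        )
    return report


def summarize_cohort(reports: list) -> dict:
    """Cohort summary: per-case success, LA Dice median/IQR, success rate."""
    case_success = [r.all_success for r in reports]
    la_dice = [
        s.dice for r in reports for s in r.structures if s.label == Label.LA
    ]
    return {
        "n": len(reports),
        "success_rate": float(np.mean(case_success)) if reports else float("nan"),
        "la_dice_median": float(np.median(la_dice)) if la_dice else float("nan"),
        "la_dice_iqr": (
            (float(np.percentile(la_dice, 25)), float(np.percentile(la_dice, 75)))
            if la_dice
            else (float("nan"), float("nan"))
        ),
    }
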