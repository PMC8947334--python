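"""Spatial and volumetric evaluation of thrombus segmentations.

Spatial measures: Dice overlap, surface Dice at a millimetre tolerance,
95th-percentile Hausdorff distance (HD95), the number of predicted
connected components with no ground-truth overlap, and the fraction of
missed cases (Dice = 0).  Volumetric measures: the intraclass correlation
coefficient ICC(A,1) -- two-way model, absolute agreement, single measure --
between predicted and reference volumes, and Bland-Altman limits of
agreement.

Surface semantics: a surface point is the centre of a foreground voxel with
at least one six-connected background neighbour (voxels beyond the grid
count as background).  Distances between surface point sets are Euclidean
in mm, so anisotropic spacing is handled.  This voxel-centre definition
differs from area-weighted surface elements; at ~1 mm isotropic spacing the
difference is small, and the semantics are pinned by brute-force oracle
tests.  HD95 pools both directed distance sets before taking the
percentile (linear interpolation); it is undefined (NaN) for an empty
prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree


class MetricsError(ValueError):
    """Raised on metric contract violations (shape mismatch, empty inputs)."""


@dataclass(frozen=True)
class SurfaceSpec:
    """Tolerance (mm) for surface Dice."""

    tolerance_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.tolerance_mm < 0:
            raise MetricsError("tolerance must be >= 0")


@dataclass
class CaseMetrics:
    dice: float
    surface_dice: float
    hd95_mm: float  # NaN when the prediction is empty
    n_nonoverlap_components: int
    precision: float
    recall: float
    volume_gt_mm3: float
    volume_pred_mm3: float
    missed: bool


@dataclass
class CohortMetrics:
    n_cases: int
    dice_mean: float
    dice_ci: Tuple[float, float]
    surface_dice_mean: float
    surface_dice_ci: Tuple[float, float]
    hd95_mean_mm: float
    hd95_ci: Tuple[float, float]
    precision_mean: float
    recall_mean: float
    nonoverlap_components_mean: float
    nonoverlap_components_ci: Tuple[float, float]
    volume_icc: float
    bland_altman_mean_mm3: float
    bland_altman_loa_mm3: Tuple[float, float]
    missed_percentage: float


def _check_shapes(gt: np.ndarray, pred: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    gt = np.asarray(gt, dtype=bool)
    pred = np.asarray(pred, dtype=bool)
    if gt.shape != pred.shape:
        raise MetricsError(f"shape mismatch {gt.shape} vs {pred.shape}")
    return gt, pred


def dice(gt: np.ndarray, pred: np.ndarray) -> float:
    """Dice overlap 2|Vgt n Vp| / (|Vgt| + |Vp|); undefined if both empty."""
    gt, pred = _check_shapes(gt, pred)
    a, b = int(gt.sum()), int(pred.sum())
    if a + b == 0:
        raise MetricsError("Dice undefined for two empty masks")
    return 2.0 * int((gt & pred).sum()) / (a + b)


def precision_recall(gt: np.ndarray, pred: np.ndarray) -> Tuple[float, float]:
    """Voxel-wise precision and recall; 0 when the denominator is empty."""
    gt, pred = _check_shapes(gt, pred)
    tp = int((gt & pred).sum())
    p = tp / int(pred.sum()) if pred.any() else 0.0
    r = tp / int(gt.sum()) if gt.any() else 0.0
    return p, r


def surface_points(mask: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Centres (mm) of foreground voxels with a 6-connected background neighbour."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.empty((0, 3))
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    boundary = mask & ~interior
    return np.argwhere(boundary) * np.asarray(spacing, dtype=float)


def surface_dice(
    gt: np.ndarray,
    pred: np.ndarray,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    spec: SurfaceSpec | None = None,
) -> float:
    """Fraction of the two surfaces lying within the tolerance of each other.

    Counts ground-truth surface points within tolerance of the prediction
    surface and vice versa, over the total number of surface points.  An
    empty prediction scores 0; the ground truth must be non-empty.
    """
    spec = spec or SurfaceSpec()
    gt, pred = _check_shapes(gt, pred)
    if not gt.any():
        raise MetricsError("ground truth must be non-empty")
    if not pred.any():
        return 0.0
    s_gt = surface_points(gt, spacing)
    s_pred = surface_points(pred, spacing)
    d_gt = cKDTree(s_pred).query(s_gt)[0]
    d_pred = cKDTree(s_gt).query(s_pred)[0]
    tau = spec.tolerance_mm
    overlap = int((d_gt <= tau).sum()) + int((d_pred <= tau).sum())
    return overlap / (len(s_gt) + len(s_pred))


def hd95(
    gt: np.ndarray, pred: np.ndarray, spacing: Sequence[float] = (1.0, 1.0, 1.0)
) -> float:
    """95th percentile of pooled directed surface distances, in mm.

    Returns NaN when the prediction is empty (the distance is then not
    calculated and such cases are excluded from cohort averages).
    """
    gt, pred = _check_shapes(gt, pred)
    if not gt.any():
        raise MetricsError("ground truth must be non-empty")
    if not pred.any():
        return float("nan")
    s_gt = surface_points(gt, spacing)
    s_pred = surface_points(pred, spacing)
    d_gt = cKDTree(s_pred).query(s_gt)[0]
    d_pred = cKDTree(s_gt).query(s_pred)[0]
    return float(np.percentile(np.concatenate([d_gt, d_pred]), 95))


def icc_volumes(gt_volumes: Sequence[float], pred_volumes: Sequence[float]) -> float:
    """ICC(A,1): two-way model, absolute agreement, single measure.

    From the two-way ANOVA decomposition with n subjects and k = 2 raters:
    (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE)).
    """
    x = np.asarray(gt_volumes, dtype=float)
    y = np.asarray(pred_volumes, dtype=float)
    if x.shape != y.shape:
        raise MetricsError("volume lists must have equal length")
    n = len(x)
    if n < 2:
        raise MetricsError("need at least 2 cases for ICC")
    data = np.stack([x, y], axis=1)  # n subjects x k raters
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise MetricsError("ICC undefined: no variance in the data")
    return float((msr - mse) / denom)


def bland_altman(
    gt_volumes: Sequence[float], pred_volumes: Sequence[float]
) -> Tuple[float, float, float]:
    """Mean difference (pred - gt) and 95% limits of agreement.

    Limits are mean(d) +- 1.96 x sd(d) with the sample standard deviation
    (n - 1 denominator).
    """
    x = np.asarray(gt_volumes, dtype=float)
    y = np.asarray(pred_volumes, dtype=float)
    if x.shape != y.shape:
        raise MetricsError("volume lists must have equal length")
    if len(x) < 2:
        raise MetricsError("need at least 2 cases")
    d = y - x
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def nonoverlap_components(
    gt: np.ndarray, pred: np.ndarray, connectivity: int = 26
) -> int:
    """Predicted connected components with zero ground-truth overlap."""
    gt, pred = _check_shapes(gt, pred)
    structure = ndimage.generate_binary_structure(3, 3 if connectivity == 26 else 1)
    labels, n = ndimage.label(pred, structure=structure)
    if n == 0:
        return 0
    overlapping = np.unique(labels[gt & pred])
    return int(n - np.count_nonzero(overlapping))


def evaluate_case(
    gt: np.ndarray,
    pred: np.ndarray,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    spec: SurfaceSpec | None = None,
) -> CaseMetrics:
    """All per-case measures for one (ground truth, prediction) pair."""
    gt, pred = _check_shapes(gt, pred)
    if not gt.any():
        raise MetricsError("ground truth must be non-empty")
    d = dice(gt, pred) if pred.any() else 0.0
    p, r = precision_recall(gt, pred)
    voxel_volume = float(np.prod(np.asarray(spacing, dtype=float)))
    return CaseMetrics(
        dice=d,
        surface_dice=surface_dice(gt, pred, spacing, spec),
        hd95_mm=hd95(gt, pred, spacing),
        n_nonoverlap_components=nonoverlap_components(gt, pred),
        precision=p,
        recall=r,
        volume_gt_mm3=float(gt.sum()) * voxel_volume,
        volume_pred_mm3=float(pred.sum()) * voxel_volume,
        missed=(d == 0.0),
    )


def _mean_ci(values: np.ndarray) -> Tuple[float, Tuple[float, float]]:
    """Mean with a normal-approximation 95% CI (mean +- 1.96 sem)."""
    values = np.asarray(values, dtype=float)
    m = float(values.mean())
    if len(values) < 2:
        return m, (m, m)
    sem = float(values.std(ddof=1)) / np.sqrt(len(values))
    return m, (m - 1.96 * sem, m + 1.96 * sem)


def evaluate_cohort(
    cases: Sequence[Tuple[np.ndarray, np.ndarray, Sequence[float]]],
    spec: SurfaceSpec | None = None,
) -> Tuple[CohortMetrics, pd.DataFrame]:
    """Per-case table plus cohort summary for (gt, pred, spacing) triples.

    HD95 is averaged only over cases where it exists (non-empty prediction);
    the missed percentage is 100 x #(Dice = 0) / n.
    """
    if len(cases) == 0:
        raise MetricsError("empty cohort")
    rows = [asdict(evaluate_case(gt, pred, sp, spec)) for gt, pred, sp in cases]
    table = pd.DataFrame(rows)
    table.insert(0, "case_id", [f"case_{i:03d}" for i in range(len(rows))])

    dice_mean, dice_ci = _mean_ci(table["dice"].to_numpy())
    sd_mean, sd_ci = _mean_ci(table["surface_dice"].to_numpy())
    hd_vals = table["hd95_mm"].to_numpy()
    hd_vals = hd_vals[~np.isnan(hd_vals)]
    hd_mean, hd_ci = _mean_ci(hd_vals) if len(hd_vals) else (float("nan"), (float("nan"),) * 2)
    noc_mean, noc_ci = _mean_ci(table["n_nonoverlap_components"].to_numpy())
    gt_vols = table["volume_gt_mm3"].to_numpy()
    pred_vols = table["volume_pred_mm3"].to_numpy()
    if len(cases) >= 2:
        try:
            icc = icc_volumes(gt_vols, pred_vols)
        except MetricsError:
            icc = float("nan")
        ba = bland_altman(gt_vols, pred_vols)
    else:
        icc = float("nan")
        ba = (float(pred_vols[0] - gt_vols[0]), float("nan"), float("nan"))
    summary = CohortMetrics(
        n_cases=len(cases),
        dice_mean=dice_mean,
        dice_ci=dice_ci,
        surface_dice_mean=sd_mean,
        surface_dice_ci=sd_ci,
        hd95_mean_mm=hd_mean,
        hd95_ci=hd_ci,
        precision_mean=float(table["precision"].mean()),
        recall_mean=float(table["recall"].mean()),
        nonoverlap_components_mean=noc_mean,
        nonoverlap_components_ci=noc_ci,
        volume_icc=icc,
        bland_altman_mean_mm3=ba[0],
        bland_altman_loa_mm3=(ba[1], ba[2]),
        missed_percentage=100.0 * float((table["dice"] == 0).sum()) / len(cases),
    )
    return summary, table
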