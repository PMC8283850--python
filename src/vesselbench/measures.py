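"""The 22 segmentation performance measures.

Eighteen measures are functions of the voxel confusion counts (TP, FP, TN,
FN): overlap based (Dice, Jaccard, sensitivity, specificity, sensibility,
global consistency error, conformity, accuracy, precision), volume based
(volumetric similarity), pair counting based (Rand index, adjusted Rand
index), information theoretic (mutual information, variation of
information), and probabilistic (interclass correlation, probabilistic
distance, Cohen's kappa, AUC for crisp masks). Four are spatial distance
measures computed between the full voxel point sets in voxel units: HD95,
average Hausdorff distance (AHD), balanced average Hausdorff distance
(bAHD), and Mahalanobis distance between the point-cloud centroids.

Conventions worth stating:

* bAHD normalises *both* directed distance sums by the ground-truth voxel
  count, so a large false-positive set cannot dilute the average the way it
  does for AHD; unlike AHD it is therefore not symmetric in its arguments.
* HD95 combines the two directed distance multisets by taking the maximum of
  their 95th percentiles (linear interpolation).
* Mutual information and variation of information use natural logarithms.
* Sensibility is 1 - FP/(TP+FN): a specificity replacement whose reference
  count is the (small) foreground rather than the enormous background, which
  gives it a usable score range on sparse targets.
* Measures undefined for degenerate counts (e.g. conformity and precision at
  TP = 0) are returned as flagged NaN sentinels instead of aborting a batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ConfusionCounts",
    "MeasureValue",
    "EmptyMaskError",
    "MEASURE_IDS",
    "LOWER_BETTER",
    "confusion_counts",
    "statistical_measures",
    "directed_average_distance",
    "distance_measures",
    "evaluate_all",
    "SegmentationEvaluator",
]

#: the 22 measure abbreviations, in report order
MEASURE_IDS = (
    "DICE", "JAC", "SNS", "SP", "SB", "GCE", "CNF", "ACC", "PRC", "VS",
    "RI", "ARI", "MI", "VOI", "ICC", "PBD", "KAP", "AUC",
    "HD95", "bAHD", "AHD", "MHD",
)

#: measures for which smaller values mean better segmentations
LOWER_BETTER = frozenset({"HD95", "bAHD", "AHD", "MHD", "VOI", "GCE", "PBD"})


def polarity_of(measure_id: str) -> str:
    return "lower_better" if measure_id in LOWER_BETTER else "higher_better"


class EmptyMaskError(ValueError):
    """A distance measure was asked to evaluate an empty point set."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MeasureValue:
    measure_id: str
    value: float
    polarity: str
    defined: bool = True


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype == bool:
        return mask
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} mask is not binary (values {vals[:5]}...)")
    return mask.astype(bool)


def confusion_counts(gt_mask: np.ndarray, seg_mask: np.ndarray) -> ConfusionCounts:
    """Voxel confusion counts of a segmentation against the ground truth."""
    gt = _as_binary(gt_mask, "ground truth")
    seg = _as_binary(seg_mask, "segmentation")
    if gt.shape != seg.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {seg.shape}")
    tp = int(np.logical_and(gt, seg).sum())
    fp = int(np.logical_and(~gt, seg).sum())
    fn = int(np.logical_and(gt, ~seg).sum())
    tn = gt.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------------
# confusion-count measures


def _entropy(*probs: float) -> float:
    return -sum(p * math.log(p) for p in probs if p > 0)


def statistical_measures(c: ConfusionCounts) -> list[MeasureValue]:
    """The 18 confusion-count measures, in report order."""
    tp, fp, tn, fn = float(c.tp), float(c.fp), float(c.tn), float(c.fn)
    n = tp + fp + tn + fn
    if n <= 0:
        raise ValueError("empty volume")
    out: dict[str, tuple[float, bool]] = {}

    def put(mid, value, defined=True):
        out[mid] = (float(value) if defined else float("nan"), defined)

    dice_den = 2 * tp + fp + fn
    put("DICE", 2 * tp / dice_den if dice_den else float("nan"), dice_den > 0)
    jac_den = tp + fp + fn
    put("JAC", tp / jac_den if jac_den else float("nan"), jac_den > 0)
    put("SNS", tp / (tp + fn) if tp + fn else float("nan"), tp + fn > 0)
    put("SP", tn / (tn + fp) if tn + fp else float("nan"), tn + fp > 0)
    put("SB", 1 - fp / (tp + fn) if tp + fn else float("nan"), tp + fn > 0)

    # global consistency error (min over the two conditioning directions)
    def _gce_term(e1, e2, d1, e3, e4, d2):
        t1 = e1 * (e1 + 2 * e2) / d1 if d1 else 0.0
        t2 = e3 * (e3 + 2 * e4) / d2 if d2 else 0.0
        return t1 + t2

    gce = min(
        _gce_term(fn, tp, tp + fn, fp, tn, tn + fp),
        _gce_term(fp, tp, tp + fp, fn, tn, tn + fn),
    ) / n
    put("GCE", gce)

    put("CNF", 1 - (fp + fn) / tp if tp else float("nan"), tp > 0)
    put("ACC", (tp + tn) / n)
    put("PRC", tp / (tp + fp) if tp else float("nan"), tp > 0)
    vs_den = 2 * tp + fp + fn
    put("VS", 1 - abs(fp - fn) / vs_den if vs_den else float("nan"), vs_den > 0)

    # pair-counting measures on the implicit 2-partition of voxel pairs
    a = 0.5 * (tp * (tp - 1) + fp * (fp - 1) + tn * (tn - 1) + fn * (fn - 1))
    sq = tp**2 + fp**2 + tn**2 + fn**2
    b = 0.5 * ((tp + fn) ** 2 + (tn + fp) ** 2 - sq)
    cc = 0.5 * ((tp + fp) ** 2 + (tn + fn) ** 2 - sq)
    d = n * (n - 1) / 2 - (a + b + cc)
    put("RI", (a + d) / (a + b + cc + d))
    ari_den = cc**2 + b**2 + 2 * a * d + (a + d) * (cc + b)
    if ari_den:
        put("ARI", 2 * (a * d - b * cc) / ari_den)
    else:
        put("ARI", 1.0 if b == cc == 0 else float("nan"), b == cc == 0)

    # information-theoretic measures (natural log)
    p_g1, p_s1 = (tp + fn) / n, (tp + fp) / n
    h1 = _entropy(p_g1, 1 - p_g1)
    h2 = _entropy(p_s1, 1 - p_s1)
    h12 = _entropy(tp / n, fn / n, fp / n, tn / n)
    mi = h1 + h2 - h12
    put("MI", mi)
    put("VOI", h1 + h2 - 2 * mi)

    # interclass correlation of the two binary "raters"
    ms_w = (fp + fn) / (2 * n)
    grand = (2 * tp + fp + fn) / (2 * n)
    ss_b = tp * (1 - grand) ** 2 + (fp + fn) * (0.5 - grand) ** 2 + tn * grand**2
    ms_b = 2 * ss_b / (n - 1) if n > 1 else 0.0
    icc_den = ms_b + ms_w
    put("ICC", (ms_b - ms_w) / icc_den if icc_den else float("nan"), icc_den > 0)

    put("PBD", (fp + fn) / (2 * tp) if tp else float("nan"), tp > 0)

    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n**2
    if pe < 1:
        put("KAP", (po - pe) / (1 - pe))
    else:
        put("KAP", 1.0 if po == 1 else float("nan"), po == 1)

    if tp + fn > 0 and tn + fp > 0:
        put("AUC", 1 - 0.5 * (fp / (fp + tn) + fn / (fn + tp)))
    else:
        put("AUC", float("nan"), False)

    return [
        MeasureValue(mid, out[mid][0], polarity_of(mid), out[mid][1])
        for mid in MEASURE_IDS
        if mid not in ("HD95", "bAHD", "AHD", "MHD")
    ]


# ---------------------------------------------------------------------------
# distance measures


def directed_average_distance(a_points: np.ndarray, b_points: np.ndarray) -> float:
    """Mean Euclidean distance (voxels) from each point of A to its nearest in B."""
    a_points = np.atleast_2d(np.asarray(a_points, float))
    b_points = np.atleast_2d(np.asarray(b_points, float))
    if len(a_points) == 0 or len(b_points) == 0:
        raise EmptyMaskError("directed average distance of an empty point set")
    d, _ = cKDTree(b_points).query(a_points)
    return float(np.mean(d))


def _mahalanobis(g_points: np.ndarray, s_points: np.ndarray) -> float:
    mu_g = g_points.mean(axis=0)
    mu_s = s_points.mean(axis=0)
    n_g, n_s = len(g_points), len(s_points)
    cov_g = np.cov(g_points.T, bias=True) if n_g > 1 else np.zeros((3, 3))
    cov_s = np.cov(s_points.T, bias=True) if n_s > 1 else np.zeros((3, 3))
    common = (n_g * cov_g + n_s * cov_s) / (n_g + n_s)
    diff = mu_g - mu_s
    d2 = float(diff @ np.linalg.pinv(common) @ diff)
    return math.sqrt(max(d2, 0.0))


def _distance_values(g_points, s_points, d_g2s, d_s2g, n_g) -> dict[str, float]:
    ahd = max(float(d_g2s.mean()), float(d_s2g.mean()))
    bahd = 0.5 * (float(d_g2s.sum()) + float(d_s2g.sum())) / n_g
    hd95 = max(float(np.percentile(d_g2s, 95)), float(np.percentile(d_s2g, 95)))
    return {"HD95": hd95, "bAHD": bahd, "AHD": ahd, "MHD": _mahalanobis(g_points, s_points)}


def distance_measures(gt_mask: np.ndarray, seg_mask: np.ndarray) -> list[MeasureValue]:
    """HD95, bAHD, AHD and Mahalanobis distance between two binary masks.

    Raises :class:`EmptyMaskError` naming the empty side. Distances are
    between full voxel sets (not extracted surfaces), in voxel units.
    """
    gt = _as_binary(gt_mask, "ground truth")
    seg = _as_binary(seg_mask, "segmentation")
    if gt.shape != seg.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {seg.shape}")
    g_points = np.argwhere(gt).astype(float)
    s_points = np.argwhere(seg).astype(float)
    if len(g_points) == 0:
        raise EmptyMaskError("empty mask: ground truth")
    if len(s_points) == 0:
        raise EmptyMaskError("empty mask: segmentation")
    d_g2s, _ = cKDTree(s_points).query(g_points)
    d_s2g, _ = cKDTree(g_points).query(s_points)
    vals = _distance_values(g_points, s_points, d_g2s, d_s2g, len(g_points))
    return [
        MeasureValue(mid, vals[mid], polarity_of(mid)) for mid in ("HD95", "bAHD", "AHD", "MHD")
    ]


def evaluate_all(gt_mask, seg_mask, on_empty: str = "raise") -> list[MeasureValue]:
    """All 22 measures of a segmentation against the ground truth.

    ``on_empty="flag"`` returns flagged NaN sentinels for the four distance
    measures when the segmentation is empty, instead of raising; this keeps
    batch evaluation of a whole variation set alive.
    """
    c = confusion_counts(gt_mask, seg_mask)
    values = statistical_measures(c)
    try:
        values += distance_measures(gt_mask, seg_mask)
    except EmptyMaskError:
        if on_empty != "flag":
            raise
        values += [
            MeasureValue(mid, float("nan"), polarity_of(mid), defined=False)
            for mid in ("HD95", "bAHD", "AHD", "MHD")
        ]
    assert len(values) == len(MEASURE_IDS)
    return values


class SegmentationEvaluator:
    """Evaluates many segmentations against one fixed ground truth.

    Caches the ground-truth point set and its KD-tree, which dominate the
    per-segmentation cost when evaluating hundreds of variations.
    """

    def __init__(self, gt_mask: np.ndarray):
        self.gt = _as_binary(gt_mask, "ground truth")
        self.g_points = np.argwhere(self.gt).astype(float)
        if len(self.g_points) == 0:
            raise EmptyMaskError("empty mask: ground truth")
        self._g_tree = cKDTree(self.g_points)

    def evaluate(self, seg_mask: np.ndarray, on_empty: str = "flag") -> dict[str, MeasureValue]:
        seg = _as_binary(seg_mask, "segmentation")
        if seg.shape != self.gt.shape:
            raise ValueError(f"shape mismatch: {self.gt.shape} vs {seg.shape}")
        values = statistical_measures(confusion_counts(self.gt, seg))
        s_points = np.argwhere(seg).astype(float)
        if len(s_points) == 0:
            if on_empty != "flag":
                raise EmptyMaskError("empty mask: segmentation")
            values += [
                MeasureValue(mid, float("nan"), polarity_of(mid), defined=False)
                for mid in ("HD95", "bAHD", "AHD", "MHD")
            ]
        else:
            d_g2s, _ = cKDTree(s_points).query(self.g_points)
            d_s2g, _ = self._g_tree.query(s_points)
            vals = _distance_values(self.g_points, s_points, d_g2s, d_s2g, len(self.g_points))
            values += [
                MeasureValue(mid, vals[mid], polarity_of(mid))
                for mid in ("HD95", "bAHD", "AHD", "MHD")
            ]
        return {v.measure_id: v for v in values}
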