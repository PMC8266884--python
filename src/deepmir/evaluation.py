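"""Lesion-level detection scoring and cohort statistics.

Predicted and reference masks are decomposed into connected components
(26-connectivity by default — small lesions touching diagonally should not
fragment; 6-connectivity is selectable).  Predicted and reference lesions
are matched one-to-one greedily in ascending centroid distance; a pair
counts as a true positive when the Euclidean centroid distance is strictly
below the tolerance (3 voxels for CMBs, 5 for the larger, more dispersed
iron deposits).  Per participant:

    sensitivity S = TP / (TP + FN)      precision P = TP / (TP + FP)

and at cohort level the average S and P across participants, their
combined "magnitude accuracy" sqrt(S_bar^2 + P_bar^2), the Pearson
correlation between predicted and reference lesion burden (lesion *count*
for CMBs, total label *volume* for iron deposits), Bland-Altman agreement
(mean difference and md +/- 1.96 SD limits), and Wilcoxon signed-rank
comparisons between models.

Ratios with zero denominators (a participant with no reference lesions, or
no predictions) are undefined — reported as NaN and excluded from averages,
with exclusion counts reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io_types import (
    CLASS_CMB,
    CLASS_IRON,
    DEFAULT_VOXEL_DIMS,
    ExperimentConfig,
    LabelVolume,
    ValidationError,
)


@dataclass
class Lesion:
    id: int
    voxels: np.ndarray  # (n, 3) integer coordinates
    centroid: tuple  # unweighted mean, voxel units
    volume_mm3: float


@dataclass
class LesionSet:
    lesions: list
    source_class: Optional[int] = None
    voxel_dims: tuple = DEFAULT_VOXEL_DIMS

    def __len__(self) -> int:
        return len(self.lesions)

    @property
    def centroids(self) -> np.ndarray:
        if not self.lesions:
            return np.empty((0, 3))
        return np.array([l.centroid for l in self.lesions])

    @property
    def total_volume_mm3(self) -> float:
        return float(sum(l.volume_mm3 for l in self.lesions))


@dataclass
class DetectionCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValidationError("detection counts must be >= 0")


def binarize(prob_map: np.ndarray, task: str = "single_class_cmb",
             threshold: float = 0.5) -> np.ndarray:
    """Probability map(s) -> integer class map.

    Single-class tasks: a voxel is labeled (with the task's class) iff its
    probability is >= threshold.  Multiclass: a (K, ...) probability stack
    is reduced by per-voxel argmax; ties resolve to the lowest class index.
    """
    p = np.asarray(prob_map, dtype=np.float64)
    if p.min() < -1e-6 or p.max() > 1 + 1e-6:
        raise ValidationError("probabilities outside [0, 1]")
    if task == "multiclass":
        if p.ndim < 2:
            raise ValidationError("multiclass expects a (K, ...) probability stack")
        return p.argmax(axis=0).astype(np.int16)
    cls = CLASS_CMB if task == "single_class_cmb" else CLASS_IRON
    return (p >= threshold).astype(np.int16) * cls


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def extract_lesions(mask: np.ndarray, voxel_dims=DEFAULT_VOXEL_DIMS,
                    connectivity: int = 26,
                    source_class: Optional[int] = None) -> LesionSet:
    """Connected components of a binary 3D mask.

    Centroids are the unweighted mean of member voxel coordinates (voxel
    units); volume is voxel count x voxel volume.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValidationError("extract_lesions expects a 3D mask")
    if connectivity not in _STRUCTURES:
        raise ValidationError("connectivity must be 6, 18 or 26")
    voxel_volume = float(np.prod(voxel_dims))
    labeled, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    lesions = []
    for i in range(1, n + 1):
        voxels = np.argwhere(labeled == i)
        lesions.append(Lesion(
            id=i,
            voxels=voxels,
            centroid=tuple(voxels.mean(axis=0)),
            volume_mm3=len(voxels) * voxel_volume,
        ))
    return LesionSet(lesions=lesions, source_class=source_class,
                     voxel_dims=tuple(voxel_dims))


def match_lesions(pred: LesionSet, ref: LesionSet, tolerance: float,
                  use_mm: bool = False):
    """Greedy one-to-one centroid matching.

    Candidate pairs are processed in ascending centroid distance; a pair is
    a true positive when its distance is strictly below *tolerance*
    (voxel units by default, mm with *use_mm*).  One-to-one matching
    prevents a single reference lesion from absorbing several predictions.

    Returns ``(DetectionCounts, pairs)`` with ``pairs`` a list of
    ``(pred_index, ref_index, distance)``.
    """
    if tolerance <= 0:
        raise ValidationError("tolerance must be positive")
    pc, rc = pred.centroids, ref.centroids
    if use_mm:
        dims = np.asarray(pred.voxel_dims)
        pc, rc = pc * dims, rc * dims
    pairs = []
    if len(pc) and len(rc):
        d = np.linalg.norm(pc[:, None, :] - rc[None, :, :], axis=2)
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
        used_p, used_r = set(), set()
        for i, j in order:
            if d[i, j] >= tolerance:
                break
            if i in used_p or j in used_r:
                continue
            used_p.add(i)
            used_r.add(j)
            pairs.append((int(i), int(j), float(d[i, j])))
    tp = len(pairs)
    counts = DetectionCounts(TP=tp, FP=len(pred) - tp, FN=len(ref) - tp)
    return counts, pairs


def sensitivity(counts: DetectionCounts) -> float:
    """TP / (TP + FN); NaN when the participant has no reference lesions."""
    denom = counts.TP + counts.FN
    return math.nan if denom == 0 else counts.TP / denom


def precision(counts: DetectionCounts) -> float:
    """TP / (TP + FP); NaN when there are no predictions."""
    denom = counts.TP + counts.FP
    return math.nan if denom == 0 else counts.TP / denom


def accuracy(counts: DetectionCounts) -> float:
    """(TP + TN) / total — requires TN, so only defined at voxel level."""
    if counts.TN is None:
        raise ValidationError("accuracy requires TN (voxel-level counts)")
    denom = counts.TP + counts.TN + counts.FP + counts.FN
    return math.nan if denom == 0 else (counts.TP + counts.TN) / denom


def magnitude_accuracy(mean_sensitivity: float, mean_precision: float) -> float:
    """sqrt(S_bar^2 + P_bar^2): Euclidean norm of the two averages."""
    return float(np.hypot(mean_sensitivity, mean_precision))


def correlate_counts(pred_values, ref_values):
    """Pearson r and two-sided p between per-participant burdens."""
    pred = np.asarray(pred_values, dtype=float)
    ref = np.asarray(ref_values, dtype=float)
    if len(pred) != len(ref):
        raise ValidationError("vectors must be the same length")
    if len(pred) < 3:
        return math.nan, math.nan
    if np.ptp(pred) == 0 or np.ptp(ref) == 0:
        return math.nan, math.nan
    r, p = stats.pearsonr(pred, ref)
    return float(r), float(p)


def bland_altman(pred_values, ref_values):
    """Mean difference and md +/- 1.96 SD limits of agreement.

    SD is the sample standard deviation (ddof=1) of the paired differences.
    """
    pred = np.asarray(pred_values, dtype=float)
    ref = np.asarray(ref_values, dtype=float)
    if len(pred) != len(ref):
        raise ValidationError("vectors must be the same length")
    if len(pred) < 2:
        return math.nan, math.nan, math.nan
    diff = pred - ref
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return md, md - 1.96 * sd, md + 1.96 * sd


def compare_models(metric_a, metric_b):
    """Two-tailed Wilcoxon signed-rank test between paired model metrics.

    Zero differences are dropped (Wilcoxon's convention); the exact null
    distribution is used where scipy supports it.  Returns ``(W, p)``, or
    ``(nan, nan)`` when every difference is zero.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if len(a) != len(b):
        raise ValidationError("paired vectors must be the same length")
    if np.all(a == b):
        return math.nan, math.nan
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                         method="auto")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# cohort evaluation


_CLASS_NAMES = {CLASS_CMB: "cmb", CLASS_IRON: "iron_deposit"}


@dataclass
class MetricsReport:
    """Per-participant detection table plus cohort-level summaries.

    ``averages[cls]`` holds mean sensitivity/precision with SEM and the
    number of participants excluded for undefined ratios.
    ``magnitude_accuracy[cls]`` reports both averaging orders — the norm of
    the mean sensitivity/precision and the mean of per-participant norms —
    since the two differ whenever performance varies across participants.
    """

    per_participant: pd.DataFrame
    averages: dict = field(default_factory=dict)
    magnitude_accuracy: dict = field(default_factory=dict)
    pearson: dict = field(default_factory=dict)
    bland_altman: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "per_participant": self.per_participant.to_dict(orient="records"),
            "averages": {_CLASS_NAMES[c]: v for c, v in self.averages.items()},
            "magnitude_accuracy": {
                _CLASS_NAMES[c]: v for c, v in self.magnitude_accuracy.items()
            },
            "pearson": {_CLASS_NAMES[c]: v for c, v in self.pearson.items()},
            "bland_altman": {
                _CLASS_NAMES[c]: v for c, v in self.bland_altman.items()
            },
        }


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return math.nan
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def evaluate_cohort(
    preds: dict,
    refs: dict,
    config: Optional[ExperimentConfig] = None,
    connectivity: int = 26,
    impute_when_both_empty: bool = False,
) -> MetricsReport:
    """Full lesion-level evaluation of predicted vs reference label volumes.

    *preds* and *refs* map participant id -> :class:`LabelVolume` (or plain
    integer arrays with the default voxel geometry).  With
    *impute_when_both_empty*, a participant whose prediction and reference
    are both empty scores S = P = 1 instead of being excluded.
    """
    config = config or ExperimentConfig(task="multiclass",
                                        modalities=("swi", "qsm", "t2w"))
    if set(preds) != set(refs):
        raise ValidationError("prediction and reference participant sets differ")
    rows = []
    burdens = {c: {"pred": [], "ref": []} for c in config.target_classes}
    pids = sorted(preds)
    for pid in pids:
        pv, rv = preds[pid], refs[pid]
        p_arr = pv.labels if isinstance(pv, LabelVolume) else np.asarray(pv)
        r_arr = rv.labels if isinstance(rv, LabelVolume) else np.asarray(rv)
        dims = pv.voxel_dims if isinstance(pv, LabelVolume) else DEFAULT_VOXEL_DIMS
        if p_arr.shape != r_arr.shape:
            raise ValidationError(f"{pid}: prediction and reference shapes differ")
        for cls in config.target_classes:
            pset = extract_lesions(p_arr == cls, dims, connectivity, cls)
            rset = extract_lesions(r_arr == cls, dims, connectivity, cls)
            counts, _ = match_lesions(pset, rset, config.tolerance_for(cls))
            s, p = sensitivity(counts), precision(counts)
            if impute_when_both_empty and len(pset) == 0 and len(rset) == 0:
                s = p = 1.0
            rows.append({
                "participant_id": pid, "class": _CLASS_NAMES[cls],
                "TP": counts.TP, "FP": counts.FP, "FN": counts.FN,
                "n_pred": len(pset), "n_ref": len(rset),
                "pred_volume_mm3": pset.total_volume_mm3,
                "ref_volume_mm3": rset.total_volume_mm3,
                "sensitivity": s, "precision": p,
            })
            if cls == CLASS_CMB:
                burdens[cls]["pred"].append(len(pset))
                burdens[cls]["ref"].append(len(rset))
            else:
                burdens[cls]["pred"].append(pset.total_volume_mm3)
                burdens[cls]["ref"].append(rset.total_volume_mm3)

    table = pd.DataFrame(rows)
    report = MetricsReport(per_participant=table)
    for cls in config.target_classes:
        sub = table[table["class"] == _CLASS_NAMES[cls]]
        s_vals = sub["sensitivity"].dropna().to_numpy()
        p_vals = sub["precision"].dropna().to_numpy()
        s_bar = float(np.mean(s_vals)) if len(s_vals) else math.nan
        p_bar = float(np.mean(p_vals)) if len(p_vals) else math.nan
        report.averages[cls] = {
            "sensitivity": s_bar, "sensitivity_sem": _sem(s_vals),
            "precision": p_bar, "precision_sem": _sem(p_vals),
            "n_excluded_sensitivity": int(sub["sensitivity"].isna().sum()),
            "n_excluded_precision": int(sub["precision"].isna().sum()),
            "n_participants": len(sub),
        }
        per_part_norm = np.hypot(sub["sensitivity"], sub["precision"]).dropna()
        report.magnitude_accuracy[cls] = {
            "norm_of_means": magnitude_accuracy(s_bar, p_bar),
            "mean_of_norms": float(per_part_norm.mean())
            if len(per_part_norm) else math.nan,
        }
        r, pval = correlate_counts(burdens[cls]["pred"], burdens[cls]["ref"])
        report.pearson[cls] = {"r": r, "p": pval}
        md, lo, hi = bland_altman(burdens[cls]["pred"], burdens[cls]["ref"])
        report.bland_altman[cls] = {"md": md, "lower": lo, "upper": hi}
    return report
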