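"""Detection scoring: truth matching, per-group rates, composite arithmetic, ROC.

A detection hits a truth nodule when its centroid lies within the nodule's
radius of the truth center (the standard CAD hit criterion); matching is
one-to-one, nearest pair first.  Per-group metrics are the plain rates
sensitivity = TP/(TP+FN) and FPs/scan = FP/n_scans.

The composite arithmetic combines the two detection groups: the vessel-tree
group's final sensitivity is its prescreening sensitivity times the
classifier's sensitivity (and likewise FPs/scan times the classifier's
false-positive rate), and the overall sensitivity counts non-vessel true
positives plus the expected vessel-group detections over all true nodules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EvalReport:
    per_group: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    composite: dict = field(default_factory=dict)
    n_scans: int = 1
    criterion: str = "centroid-within-truth-radius"

    def to_dict(self) -> dict:
        return {"per_group": self.per_group, "classifier": self.classifier,
                "composite": self.composite, "n_scans": self.n_scans,
                "criterion": self.criterion}


def match_detections(detections, truths) -> tuple[int, int, int]:
    """Greedy nearest-first one-to-one matching.

    *detections*: iterable of centroid (z, y, x) positions in mm (or objects
    with a ``centroid_mm`` attribute).  *truths*: iterable of
    ``(center_mm, diameter_mm)`` pairs (or ``(type, center, diameter)``
    truth records).  A detection is a TP when its centroid lies within the
    truth radius; each truth matches at most one detection.

    Returns (TP, FP, FN).
    """
    det = [np.asarray(getattr(d, "centroid_mm", d), float) for d in detections]
    tru = []
    for t in truths:
        if len(t) == 3 and isinstance(t[0], str):
            _, center, diam = t
        else:
            center, diam = t
        tru.append((np.asarray(center, float), float(diam)))
    if not tru:
        return 0, len(det), 0
    pairs = []
    for i, d in enumerate(det):
        for j, (c, diam) in enumerate(tru):
            dist = float(np.linalg.norm(d - c))
            if dist <= diam / 2.0:
                pairs.append((dist, i, j))
    pairs.sort()
    used_det, used_tru = set(), set()
    tp = 0
    for dist, i, j in pairs:
        if i in used_det or j in used_tru:
            continue
        used_det.add(i)
        used_tru.add(j)
        tp += 1
    fp = len(det) - tp
    fn = len(tru) - tp
    return tp, fp, fn


def group_metrics(tp: int, fp: int, fn: int, n_scans: int) -> tuple[float, float]:
    """(sensitivity, FPs/scan) from raw counts."""
    if min(tp, fp, fn) < 0 or n_scans < 1:
        raise ValueError("counts must be >= 0 and n_scans >= 1")
    if tp + fn == 0:
        if tp == 0 and fp == 0:
            return 0.0, 0.0
        raise ValueError("sensitivity undefined: no truth objects")
    return tp / (tp + fn), fp / n_scans


def composite_performance(presc_sens: float, clf_sens: float, presc_fps: float,
                          clf_fp_rate: float, *, nonvessel_tp: int,
                          vessel_truth_count: int, total_truth: int,
                          nonvessel_fps_per_scan: float) -> dict:
    """Combine prescreening and classifier stages into scheme-level numbers.

    * vessel-group sensitivity = prescreening sensitivity x classifier
      sensitivity, and vessel-group FPs/scan = prescreening FPs/scan x
      classifier false-positive rate;
    * overall sensitivity = (non-vessel TP + vessel truth count x
      vessel-group sensitivity) / total truth count;
    * overall FPs/scan = sum of the two groups' FPs/scan.
    """
    for r in (presc_sens, clf_sens, clf_fp_rate):
        if not 0 <= r <= 1:
            raise ValueError("rates must lie in [0, 1]")
    vessel_sens = presc_sens * clf_sens
    vessel_fps = presc_fps * clf_fp_rate
    overall_sens = (nonvessel_tp + vessel_truth_count * vessel_sens) / total_truth
    overall_fps = nonvessel_fps_per_scan + vessel_fps
    return {
        "vessel_sensitivity": vessel_sens,
        "vessel_fps_per_scan": vessel_fps,
        "overall_sensitivity": overall_sens,
        "overall_fps_per_scan": overall_fps,
    }


def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """Trapezoidal AUC over all score thresholds, plus the ROC points.

    Returns ``(auc, points)`` with points as an (n, 2) array of
    (false-positive rate, true-positive rate) pairs.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = labels == 1
    if pos.all() or not pos.any():
        raise ValueError("ROC needs both classes")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = pos[order]
    # thresholds at distinct scores
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.concatenate([distinct, [len(s) - 1]])
    tps = np.cumsum(y)[idx]
    fps = np.cumsum(~y)[idx]
    tpr = np.concatenate([[0.0], tps / pos.sum()])
    fpr = np.concatenate([[0.0], fps / (~pos).sum()])
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])
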