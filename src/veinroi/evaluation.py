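"""Keypoint accuracy metric and confidence ROC analysis.

A predicted keypoint is correct when its Euclidean distance to the label is
strictly below the pixel threshold (a distance exactly equal to the threshold
counts as incorrect).  The canonical threshold is 40 px at the original
1920x1080 annotation resolution; at a working resolution it scales with the
image height (about 5 px at 128x128).  Accuracy is counted per keypoint, not
per image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve

REFERENCE_THRESHOLD_PX = 40.0
REFERENCE_HEIGHT = 1080


def scaled_threshold(height: int) -> float:
    """The 40-px rule transported to another resolution (5 px at height 128)."""
    return round(REFERENCE_THRESHOLD_PX * height / REFERENCE_HEIGHT * 8) / 8


@dataclass
class EvalRecord:
    predicted: tuple[float, float]
    label: tuple[float, float]
    d: float
    correct: bool
    threshold: float
    confidence: float = float("nan")


def keypoint_distance(pred, label) -> float:
    """Euclidean distance in pixels."""
    pred = np.asarray(pred, dtype=float)
    label = np.asarray(label, dtype=float)
    if not (np.isfinite(pred).all() and np.isfinite(label).all()):
        raise ValueError("non-finite coordinates")
    return float(np.hypot(pred[0] - label[0], pred[1] - label[1]))


def make_record(pred, label, threshold: float, scale: float = 1.0,
                confidence: float = float("nan")) -> EvalRecord:
    """Build one record; `scale` maps working-resolution pixels to the
    resolution the threshold is stated at (both coordinates are multiplied)."""
    p = np.asarray(pred, dtype=float) * scale
    l = np.asarray(label, dtype=float) * scale
    d = keypoint_distance(p, l)
    return EvalRecord(predicted=tuple(p), label=tuple(l), d=d,
                      correct=d < threshold, threshold=threshold,
                      confidence=confidence)


def accuracy(records: list[EvalRecord]) -> float:
    """Fraction of correct keypoints; strict inequality at the threshold."""
    if not records:
        raise ValueError("no records")
    return float(np.mean([r.correct for r in records]))


def accuracy_from_distances(distances, threshold: float) -> float:
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("no distances")
    return float(np.mean(d < threshold))


def confidence_roc(confidences, labels):
    """ROC of heatmap peak confidence as a correctness classifier.

    Returns (fpr, tpr, thresholds, auc); AUC by the trapezoid rule.  The
    positive class is a correctly localized keypoint.
    """
    conf = np.asarray(confidences, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if lab.all() or (~lab).all():
        raise ValueError("ROC needs both correct and incorrect keypoints")
    fpr, tpr, thr = roc_curve(lab.astype(int), conf)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thr, auc
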