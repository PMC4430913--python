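"""Pixel-level evaluation metrics for binary segmentation masks.

Accuracy, precision, sensitivity, specificity and the normalized sum of
false detections are computed from a pixelwise confusion table between a
predicted mask and a ground-truth mask of equal shape.  A metric whose
denominator is zero is reported as ``None`` ("undefined") rather than being
coerced to 0 or 1, so empty masks never inflate a score silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "confusion_counts", "metrics", "dice", "recall"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixelwise confusion table of a predicted vs. a truth binary mask.

    Attributes
    ----------
    tp, tn, fp, fn : int
        True positives (vessel pixels detected correctly), true negatives,
        false positives and false negatives.
    q : int
        Total number of pixels; always ``tp + tn + fp + fn``.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def q(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(pred, truth) -> ConfusionCounts:
    """Count pixelwise agreement between two binary masks of equal shape."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.shape} vs truth {truth.shape}"
        )
    tp = int(np.count_nonzero(pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(cc: ConfusionCounts) -> dict:
    """Segmentation quality scores from a confusion table.

    Returns a dict with keys ``accuracy``, ``precision``, ``sensitivity``,
    ``specificity`` and ``eps_f`` (the normalized sum of false detections,
    ``(Fp+Fn)/(2q)``).  Scores with a zero denominator are ``None``.
    """
    q = cc.q
    if q == 0:
        raise ValueError("empty confusion table (q = 0)")

    def _ratio(num: int, den: int):
        return num / den if den > 0 else None

    return {
        "accuracy": (cc.tp + cc.tn) / q,
        "precision": _ratio(cc.tp, cc.tp + cc.fp),
        "sensitivity": _ratio(cc.tp, cc.tp + cc.fn),
        "specificity": _ratio(cc.tn, cc.tn + cc.fp),
        "eps_f": (cc.fp + cc.fn) / (2 * q),
    }


def dice(pred, truth):
    """Dice overlap 2|A∩B| / (|A|+|B|); ``None`` when both masks are empty."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    denom = int(np.count_nonzero(pred)) + int(np.count_nonzero(truth))
    if denom == 0:
        return None
    return 2.0 * np.count_nonzero(pred & truth) / denom


def recall(pred, truth):
    """Voxel/pixel recall |pred ∩ truth| / |truth|; ``None`` on empty truth."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    n_truth = int(np.count_nonzero(truth))
    if n_truth == 0:
        return None
    return np.count_nonzero(pred & truth) / n_truth
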