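"""ROC analysis: curve construction, AUC, Youden-optimal cutoff.

The positive class is the co-deletion class and the score is its predicted
probability.  The ROC curve is built over all distinct score thresholds;
classification at a cutoff uses the inclusive rule (positive iff score >=
cutoff).  AUC is the area under that curve, which equals the Mann-Whitney
pair statistic (ties counted one half).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "RocCurve",
    "roc_auc",
    "youden_cutoff",
    "sens_spec_at",
    "write_report",
]

logger = logging.getLogger(__name__)


@dataclass
class RocCurve:
    thresholds: np.ndarray  # descending, one per distinct score
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    youden_cutoff: float
    youden_j: float


def _as_positive_mask(labels: Sequence, pos_label) -> np.ndarray:
    y = np.asarray(labels)
    if pos_label is not None:
        return y == pos_label
    return y.astype(bool)


def roc_auc(labels: Sequence, scores: Sequence[float],
            pos_label=None) -> RocCurve:
    """Build the ROC curve and AUC for ``scores`` against binary labels.

    ``pos_label`` selects the positive class; when None, labels are taken
    as booleans.  Raises if only one class is present or scores are not
    finite.
    """
    pos = _as_positive_mask(labels, pos_label)
    s = np.asarray(scores, dtype=float)
    if s.shape != pos.shape:
        raise ValueError("labels and scores must have equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    n_pos = int(pos.sum())
    n_neg = int(len(pos) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")

    thresholds = np.unique(s)[::-1]
    tp = np.array([(pos & (s >= t)).sum() for t in thresholds])
    fp = np.array([(~pos & (s >= t)).sum() for t in thresholds])
    tpr = tp / n_pos
    fpr = fp / n_neg
    auc = float(np.trapezoid(np.r_[0.0, tpr], np.r_[0.0, fpr]))

    # exact integer comparison so mathematically tied J values resolve to
    # the highest threshold instead of whichever float rounded larger
    j_scaled = tp * n_neg - fp * n_pos
    best = int(np.argmax(j_scaled))  # first index = highest threshold
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
                    youden_cutoff=float(thresholds[best]),
                    youden_j=float(j_scaled[best] / (n_pos * n_neg)))


def youden_cutoff(curve: RocCurve) -> Tuple[float, float]:
    """Threshold maximizing J = tpr - fpr; ties go to the highest threshold."""
    return curve.youden_cutoff, curve.youden_j


def sens_spec_at(labels: Sequence, scores: Sequence[float], cutoff: float,
                 pos_label=None) -> Tuple[float, float]:
    """Sensitivity and specificity of the rule (score >= cutoff => positive).

    An absent class makes the corresponding metric NaN (flagged, not 0).
    """
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    pos = _as_positive_mask(labels, pos_label)
    s = np.asarray(scores, dtype=float)
    pred = s >= cutoff
    n_pos = int(pos.sum())
    n_neg = int(len(pos) - n_pos)
    if n_pos == 0:
        logger.warning("no positive samples: sensitivity undefined")
        sens = float("nan")
    else:
        sens = float((pred & pos).sum() / n_pos)
    if n_neg == 0:
        logger.warning("no negative samples: specificity undefined")
        spec = float("nan")
    else:
        spec = float((~pred & ~pos).sum() / n_neg)
    return sens, spec


def write_report(curve: RocCurve, path, sensitivity: Optional[float] = None,
                 specificity: Optional[float] = None) -> None:
    """Write the threshold grid plus a summary block as TSV."""
    with open(path, "w") as fh:
        fh.write("threshold\ttpr\tfpr\tyouden_j\n")
        for t, tp, fp in zip(curve.thresholds, curve.tpr, curve.fpr):
            fh.write(f"{t:.6g}\t{tp:.6g}\t{fp:.6g}\t{tp - fp:.6g}\n")
        fh.write(f"# auc\t{curve.auc:.6g}\n")
        fh.write(f"# youden_cutoff\t{curve.youden_cutoff:.6g}\n")
        fh.write(f"# youden_j\t{curve.youden_j:.6g}\n")
        if sensitivity is not None:
            fh.write(f"# sensitivity\t{sensitivity:.6g}\n")
        if specificity is not None:
            fh.write(f"# specificity\t{specificity:.6g}\n")
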