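"""Biomarker evaluation: ROC/AUC on a scored cohort and clinical correlations.

A candidate biomarker here is any per-sample score (typically the log2
circ/lin ratio of a circRNA) evaluated for its ability to separate DM1
patients (positives) from controls (negatives).  The ROC curve is swept
over unique score thresholds, higher score predicting disease; the area
under it is computed by the trapezoid rule and cross-checked against the
Mann-Whitney identity AUC = U / (n+ * n-), which holds exactly under the
mid-rank tie convention.  Any strictly monotone transform of the score
(ratio vs log-ratio) leaves the ROC unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = ["RocResult", "roc_auc", "pearson_correlation"]


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores, labels, positive_label="DM1") -> RocResult:
    """ROC curve and AUC for a scored two-class cohort.

    ``labels`` may be any binary labelling; ``positive_label`` marks the
    disease class.  The returned curve starts at (0, 0) and ends at (1, 1);
    AUC is the trapezoid area, which is verified to equal the rank-based
    U / (n+ * n-) (ties contribute one half) to numerical precision.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    y = labels == positive_label
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    fpr, tpr, thr = roc_curve(y.astype(int), scores)
    auc_trap = float(np.trapezoid(tpr, fpr))

    # rank identity: U = sum of positive ranks - n+(n+ + 1)/2
    ranks = stats.rankdata(scores)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    auc_rank = float(u / (n_pos * n_neg))
    if abs(auc_trap - auc_rank) > 1e-9:
        raise AssertionError(
            f"trapezoid AUC {auc_trap} disagrees with rank AUC {auc_rank}; "
            "this indicates an internal inconsistency"
        )
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc_trap)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-based p-value.

    ``p`` is derived from ``t = r * sqrt((n - 2) / (1 - r^2))`` on n - 2
    degrees of freedom.  Requires n >= 3, finite values and nonzero
    variance in both variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
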