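"""CpG-wise ROC / partial-AUC evaluation of DMR-caller scores.

Performance is scored per CpG: inside a true DMR a detected CpG is a true
positive and a missed one a false negative; outside, the criteria flip.
The headline metric is the partial area under the ROC curve over the
high-specificity window FPR in [0, 1 - specificity_floor] (default floor
0.75, so the unnormalized maximum is 0.25): in practice only calls made at
low false-positive rates matter for follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

__all__ = [
    "ROCResult",
    "cpg_confusion",
    "roc_and_pauc",
    "ranking_score",
    "compare_methods",
]


def cpg_confusion(calls, truth):
    """(TP, FP, TN, FN) of binary per-CpG detections against truth."""
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must have equal length")
    tp = int(np.sum(calls & truth))
    fp = int(np.sum(calls & ~truth))
    tn = int(np.sum(~calls & ~truth))
    fn = int(np.sum(~calls & truth))
    return tp, fp, tn, fn


@dataclass
class ROCResult:
    """ROC points and unnormalized partial AUC at high specificity."""

    fpr: np.ndarray
    tpr: np.ndarray
    pauc: float
    specificity_floor: float

    @property
    def pauc_normalized(self) -> float:
        return self.pauc / (1.0 - self.specificity_floor)


def roc_and_pauc(scores, truth, specificity_floor: float = 0.75,
                 normalized: bool = False) -> ROCResult:
    """ROC over all score thresholds (ties grouped) and trapezoidal pAUC
    over FPR in [0, 1 - specificity_floor].

    ``normalized=True`` additionally rescales the reported pAUC to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if truth.all() or not truth.any():
        raise ValueError("both classes must be present in truth")
    fpr, tpr, _ = roc_curve(truth.astype(int), scores)
    fmax = 1.0 - specificity_floor
    # interpolate the curve at the window edge, then integrate
    tpr_edge = float(np.interp(fmax, fpr, tpr))
    inside = fpr < fmax
    fx = np.concatenate([fpr[inside], [fmax]])
    fy = np.concatenate([tpr[inside], [tpr_edge]])
    pauc = float(np.trapezoid(fy, fx))
    if normalized:
        pauc /= fmax
    return ROCResult(fpr=fpr, tpr=tpr, pauc=pauc,
                     specificity_floor=specificity_floor)


def ranking_score(posteriors: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Default per-CpG ranking score: 1 - P(z = "0"), ties broken by |d|.

    The tie-break enters as a vanishing additive term so score order equals
    lexicographic order on (1 - p_null, |d|).
    """
    p_null = np.asarray(posteriors)[:, 1]
    return (1.0 - p_null) + 1e-9 * np.abs(np.asarray(d, dtype=float))


def compare_methods(paucs: pd.DataFrame,
                    tie_tolerance: float = 0.01) -> pd.DataFrame:
    """Best method per dataset with ties within a relative pAUC margin.

    ``paucs``: rows = datasets, columns = methods, values = pAUC.  Methods
    whose pAUC is within ``tie_tolerance`` (relative) of the best are
    reported as tied.
    """
    if paucs.shape[1] < 1:
        raise ValueError("at least one method required")
    rows = []
    for dataset, row in paucs.iterrows():
        best = row.idxmax()
        best_val = float(row.max())
        tied = [m for m in row.index
                if m != best and row[m] >= best_val * (1 - tie_tolerance)]
        rows.append({"dataset": dataset, "best": best,
                     "best_pauc": best_val, "tied_with": tied,
                     "is_tie": bool(tied)})
    return pd.DataFrame(rows).set_index("dataset")
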