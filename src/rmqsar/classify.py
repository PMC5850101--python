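"""Regression-to-classification scoring.

The fitted regression is turned into a binary classifier by thresholding
IC50: a compound is *highly active* when IC50 <= threshold (1000 nM by
default; boundary compounds count as active). The threshold is applied in
log10 space to both observed and predicted activities, and the resulting
confusion matrix is summarized with the Cooper statistics (accuracy,
sensitivity, specificity) and the Matthews correlation coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import DataError

DEFAULT_THRESHOLD_NM = 1000.0


@dataclass
class ClassificationReport:
    threshold_nm: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy_pct: float
    sensitivity: float
    specificity: float
    mcc: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def classify_and_score(
    y_obs_log: np.ndarray,
    y_pred_log: np.ndarray,
    threshold_nm: float = DEFAULT_THRESHOLD_NM,
) -> ClassificationReport:
    """Confusion matrix and Cooper/MCC statistics at an IC50 cutoff.

    Active (positive) means log10 IC50 <= log10(threshold). MCC is 0 by
    convention whenever a marginal count is 0 (the usual zero-denominator
    rule).
    """
    if threshold_nm <= 0:
        raise DataError("threshold must be positive")
    y_obs_log = np.asarray(y_obs_log, dtype=float)
    y_pred_log = np.asarray(y_pred_log, dtype=float)
    if y_obs_log.size != y_pred_log.size:
        raise DataError("length mismatch")
    cut = math.log10(threshold_nm)
    obs_active = y_obs_log <= cut
    pred_active = y_pred_log <= cut
    tp = int(np.sum(obs_active & pred_active))
    fn = int(np.sum(obs_active & ~pred_active))
    fp = int(np.sum(~obs_active & pred_active))
    tn = int(np.sum(~obs_active & ~pred_active))
    n = tp + fp + tn + fn
    acc = 100.0 * (tp + tn) / n if n else float("nan")
    se = tp / (tp + fn) if (tp + fn) else float("nan")
    sp = tn / (tn + fp) if (tn + fp) else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return ClassificationReport(
        threshold_nm=threshold_nm, tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy_pct=acc, sensitivity=se, specificity=sp, mcc=float(mcc),
    )
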