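"""Applicability domain (AD) assessment.

A QSAR prediction is only trustworthy for compounds structurally inside
the region the model was trained on. Two complementary definitions are
implemented:

* **Leverage approach** — a query is inside if its leverage on the
  intercept-augmented training design stays below the warning leverage
  h* = 3(d+1)/n_train (the conventional threshold separating
  interpolation from extrapolation).
* **Standardization approach** — each of the query's d descriptor values
  is expressed as an absolute standardized deviation s_ik from the
  training mean/SD of that descriptor. Inside if max_k s_ik <= 3;
  otherwise, if min_k s_ik < 3, the fallback statistic
  s_new = mean(s_ik) + 1.28 * SD(s_ik) decides (inside iff s_new <= 3);
  if even the minimum is >= 3 the compound is outside. The 1.28 factor is
  the standard-normal 90th percentile.

The Williams table (leverage vs standardized residual per compound) is
the data behind the classic AD diagnostic plot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ActivitySet, DataError, DescriptorMatrix, LinearModel, SubsetPartition
from .mlr import leverages_for, predict

SNEW_QUANTILE_FACTOR = 1.28
S_CUTOFF = 3.0


@dataclass
class ADReport:
    h_star: float
    table: pd.DataFrame  # per-compound: leverage, s_ik stats, inside flags

    @property
    def inside_leverage(self) -> np.ndarray:
        return self.table["inside_leverage"].to_numpy()

    @property
    def inside_standardization(self) -> np.ndarray:
        return self.table["inside_standardization"].to_numpy()

    @property
    def agreement(self) -> float:
        return float(np.mean(self.inside_leverage == self.inside_standardization))


def warning_leverage(d: int, n_train: int) -> float:
    """h* = 3 (d + 1) / n_train."""
    if n_train <= d + 1:
        raise DataError("warning leverage needs n_train > d + 1")
    return 3.0 * (d + 1) / n_train


def leverage_ad(
    X_train: np.ndarray, X_query: np.ndarray, d: int | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """(h_i, inside flag, h*) per query row on the training design."""
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    X_query = np.atleast_2d(np.asarray(X_query, dtype=float))
    if d is None:
        d = X_train.shape[1]
    h_star = warning_leverage(d, X_train.shape[0])
    h = leverages_for(X_train, X_query)
    return h, h < h_star, h_star


def standardization_ad(
    X_train: np.ndarray, X_query: np.ndarray
) -> pd.DataFrame:
    """Standardization-approach AD flags for each query row.

    Returns per-compound s_ik_max, s_ik_min, s_new (NaN unless the
    fallback rule applied), and the inside flag.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    X_query = np.atleast_2d(np.asarray(X_query, dtype=float))
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=1)
    usable = sd > 0
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} zero-variance training column(s) excluded "
            "from standardization AD", stacklevel=2)
        if not usable.any():
            raise DataError("no usable (nonzero-SD) training columns")
    S = np.abs(X_query[:, usable] - mu[usable]) / sd[usable]
    s_max = S.max(axis=1)
    s_min = S.min(axis=1)
    # sample SD over the d standardized values of each compound
    s_sd = S.std(axis=1, ddof=1) if S.shape[1] > 1 else np.zeros(S.shape[0])
    s_new = np.where(
        (s_max > S_CUTOFF) & (s_min < S_CUTOFF),
        S.mean(axis=1) + SNEW_QUANTILE_FACTOR * s_sd,
        np.nan,
    )
    inside = (s_max <= S_CUTOFF) | (
        (s_min < S_CUTOFF) & (np.nan_to_num(s_new, nan=np.inf) <= S_CUTOFF)
    )
    return pd.DataFrame({
        "s_ik_max": s_max, "s_ik_min": s_min, "s_new": s_new,
        "inside_standardization": inside,
    })


def assess_ad(
    model: LinearModel, train_dm: DescriptorMatrix, query_dm: DescriptorMatrix
) -> ADReport:
    """Run both AD approaches on the model's descriptor columns."""
    Xt = train_dm.matrix(model.descriptor_names)
    Xq = query_dm.matrix(model.descriptor_names)
    h, inside_h, h_star = leverage_ad(Xt, Xq, d=model.d)
    std_tab = standardization_ad(Xt, Xq)
    table = pd.DataFrame({
        "compound_id": query_dm.compound_ids,
        "leverage": h,
        "inside_leverage": inside_h,
    })
    table = pd.concat([table, std_tab], axis=1)
    return ADReport(h_star=h_star, table=table)


def williams_table(
    model: LinearModel,
    dm: DescriptorMatrix,
    act: ActivitySet,
    part: SubsetPartition,
    s_train: float,
) -> pd.DataFrame:
    """Per-compound (subset, leverage, standardized residual) — the data of
    the Williams plot. Compounds beyond h* or |std. residual| > 3 are
    flagged as leverage/residual breaches.
    """
    if dm.compound_ids != act.compound_ids or dm.compound_ids != part.compound_ids:
        raise DataError("williams_table needs aligned inputs")
    train_idx = part.indices("train")
    Xt = dm.matrix(model.descriptor_names)[train_idx]
    h_star = warning_leverage(model.d, train_idx.size)
    X_all = dm.matrix(model.descriptor_names)
    h = leverages_for(Xt, X_all)
    resid = act.log10_ic50 - predict(model, dm)
    std_resid = resid / s_train
    return pd.DataFrame({
        "compound_id": dm.compound_ids,
        "subset": part.labels,
        "leverage": h,
        "std_residual": std_resid,
        "h_star": h_star,
        "beyond_h_star": h >= h_star,
        "residual_outlier": np.abs(std_resid) > 3.0,
    })
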