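"""Internal and external validation of a fitted QSAR model.

Internal: leave-one-out and leave-n%-out cross-validation (the descriptor
subset is held fixed — only the coefficients are re-estimated per fold, as
is standard when the subset was selected once on the full training set),
and Y-randomization (refitting after permuting the response; a real
structure-activity relationship must fit scrambled activities markedly
worse, i.e. S_rand > S_train).

External: the Golbraikh–Tropsha through-origin criteria on the test-set
predictions, plus the o3 outlier count (training residuals beyond
3 * S_train).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DataError
from .mlr import fit_ols, subset_stats

GT_R0_TOL = 0.1
GT_K_LOW, GT_K_HIGH = 0.85, 1.15
GT_RM2_MIN = 0.5


@dataclass
class GtBlock:
    """Golbraikh–Tropsha external-validation block."""

    r2: float
    r0sq: float          # CoD of the through-origin pred-on-obs line
    r0sq_prime: float    # CoD of the through-origin obs-on-pred line
    k: float             # through-origin slope, pred on obs
    k_prime: float       # through-origin slope, obs on pred
    rm2: float
    pass_r0: bool
    pass_k: bool
    pass_rm2: bool

    @property
    def passes(self) -> bool:
        return self.pass_r0 and self.pass_k and self.pass_rm2


@dataclass
class ValidationReport:
    r2_loo: float = float("nan")
    s_loo: float = float("nan")
    r2_lno: float = float("nan")
    s_lno: float = float("nan")
    lno_pct: float = float("nan")
    lno_cases: int = 0
    r2_rand: float = float("nan")
    s_rand: float = float("nan")
    n_permutations: int = 0
    yrand_pass: bool | None = None
    gt: GtBlock | None = None
    o3_count: int = 0
    o3_ids: list[str] | None = None


def loo_cv(X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Leave-one-out cross-validation of a fixed descriptor subset.

    Uses the hat-matrix identity e_i^{loo} = e_i / (1 - h_i), which equals
    the naive n-refit procedure exactly for OLS (a standing oracle test).
    Returns (r2_loo, s_loo) with s_loo = sqrt(PRESS / (n - d - 1)).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    if n <= d + 2:
        raise DataError(f"LOO needs n > d + 2 (n={n}, d={d})")
    _, stats = fit_ols(X, y)
    e_loo = stats.residuals / (1.0 - stats.leverages)
    y_pred = y - e_loo
    press = float(e_loo @ e_loo)
    s_loo = float(np.sqrt(press / (n - d - 1)))
    if np.std(y_pred) == 0 or np.std(y) == 0:
        return float("nan"), s_loo
    r = float(np.corrcoef(y, y_pred)[0, 1])
    return r * r, s_loo


def loo_cv_naive(X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """n explicit refits — the oracle the shortcut is checked against."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    y_pred = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        model, _ = fit_ols(X[keep], y[keep])
        y_pred[i] = model.intercept + X[i] @ model.coefficients
    press = float(np.sum((y - y_pred) ** 2))
    s_loo = float(np.sqrt(press / (n - d - 1)))
    r = float(np.corrcoef(y, y_pred)[0, 1])
    return r * r, s_loo


def leave_n_pct_out(
    X: np.ndarray, y: np.ndarray, pct: float = 0.30,
    n_cases: int = 5000, seed: int = 0,
) -> tuple[float, float]:
    """Leave-n%-out cross-validation: ``n_cases`` random draws each hold
    out round(pct * n) compounds; the model (fixed subset) is refit on the
    remainder and predicts the held-out block. All (obs, pred) pairs are
    pooled before computing r^2 and s.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    if not (0.0 < pct < 0.5):
        raise DataError("pct must lie in (0, 0.5)")
    n_out = int(round(pct * n))
    if n_out < 1:
        raise DataError("pct leaves out no compounds")
    if n - n_out <= d + 2:
        raise DataError("remainder after holdout is too small to refit")
    rng = np.random.default_rng(seed)
    obs_all = np.empty(n_cases * n_out)
    pred_all = np.empty(n_cases * n_out)
    for c in range(n_cases):
        out = rng.choice(n, size=n_out, replace=False)
        keep = np.setdiff1d(np.arange(n), out, assume_unique=False)
        A = np.hstack([X[keep], np.ones((keep.size, 1))])
        coef, _, _, _ = np.linalg.lstsq(A, y[keep], rcond=None)
        B = np.hstack([X[out], np.ones((n_out, 1))])
        sl = slice(c * n_out, (c + 1) * n_out)
        obs_all[sl] = y[out]
        pred_all[sl] = B @ coef
    return subset_stats(obs_all, pred_all, d)


def y_randomization(
    X: np.ndarray, y: np.ndarray, n_permutations: int = 2000,
    seed: int = 0, s_train: float | None = None,
) -> tuple[float, float, bool]:
    """Mean (R^2, S) over refits of the same descriptor subset against
    permuted responses, plus the pass flag mean(S_rand) > S_train.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    rng = np.random.default_rng(seed)
    A = np.hstack([X, np.ones((n, 1))])
    Q, _ = np.linalg.qr(A)
    dof = n - d - 1
    r2s = np.empty(n_permutations)
    ss = np.empty(n_permutations)
    identity = np.arange(n)
    for p in range(n_permutations):
        perm = rng.permutation(n)
        while n > 1 and np.array_equal(perm, identity):
            perm = rng.permutation(n)  # a scramble must actually scramble
        yp = y[perm]
        resid = yp - Q @ (Q.T @ yp)
        rss = float(resid @ resid)
        tss = float(np.sum((yp - yp.mean()) ** 2))
        r2s[p] = 1.0 - rss / tss if tss > 0 else np.nan
        ss[p] = np.sqrt(rss / dof)
    r2_rand = float(np.nanmean(r2s))
    s_rand = float(np.mean(ss))
    if s_train is None:
        _, stats = fit_ols(X, y)
        s_train = stats.s
    return r2_rand, s_rand, bool(s_rand > s_train)


def rm_squared(r2: float, r0sq: float) -> float:
    """Rm^2 = R^2 (1 - sqrt(R^2 - R0^2)); the sqrt argument is clamped at 0
    for the degenerate case R0^2 > R^2."""
    return float(r2 * (1.0 - np.sqrt(max(r2 - r0sq, 0.0))))


def _through_origin(x: np.ndarray, z: np.ndarray) -> tuple[float, float]:
    """Slope k of z = k x (no intercept) and the coefficient of
    determination of that line on the z axis."""
    k = float(np.sum(x * z) / np.sum(x * x))
    resid = z - k * x
    tss = float(np.sum((z - z.mean()) ** 2))
    r0sq = 1.0 - float(resid @ resid) / tss if tss > 0 else float("nan")
    return k, r0sq


def golbraikh_tropsha(y_obs: np.ndarray, y_pred: np.ndarray) -> GtBlock:
    """External-validation criteria on held-out predictions.

    k and R0^2 come from the through-origin regression of predictions on
    observations; the primed pair from the swapped regression. The model
    passes when (1 - R0^2/R^2 < 0.1 or 1 - R0'^2/R^2 < 0.1), the slope k
    or k' lies in [0.85, 1.15], and Rm^2 = R^2 (1 - sqrt(R^2 - R0^2)) > 0.5.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.size < 3 or y_obs.size != y_pred.size:
        raise DataError("GT criteria need equal-length vectors, n >= 3")
    if np.std(y_obs) == 0 or np.std(y_pred) == 0:
        raise DataError("GT criteria undefined for zero-variance inputs")
    r = float(np.corrcoef(y_obs, y_pred)[0, 1])
    r2 = r * r
    k, r0sq = _through_origin(y_obs, y_pred)
    k_prime, r0sq_prime = _through_origin(y_pred, y_obs)
    rm2 = rm_squared(r2, r0sq)
    pass_r0 = (1.0 - r0sq / r2 < GT_R0_TOL) or (1.0 - r0sq_prime / r2 < GT_R0_TOL)
    pass_k = (GT_K_LOW <= k <= GT_K_HIGH) or (GT_K_LOW <= k_prime <= GT_K_HIGH)
    return GtBlock(
        r2=r2, r0sq=r0sq, r0sq_prime=r0sq_prime, k=k, k_prime=k_prime,
        rm2=float(rm2), pass_r0=bool(pass_r0), pass_k=bool(pass_k),
        pass_rm2=bool(rm2 > GT_RM2_MIN),
    )


def count_outliers(
    residuals: np.ndarray, s_train: float, ids: list[str] | None = None
) -> tuple[int, list[str]]:
    """Training compounds whose |residual| exceeds 3 * S_train (the o3 rule)."""
    if s_train <= 0:
        raise DataError("count_outliers needs s_train > 0")
    residuals = np.asarray(residuals, dtype=float)
    hits = np.nonzero(np.abs(residuals) > 3.0 * s_train)[0]
    if ids is None:
        ids = [str(i) for i in range(residuals.size)]
    return int(hits.size), [ids[i] for i in hits]
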