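"""Ordinary least-squares core.

Every statistic downstream (selection, validation, applicability domain)
is defined in terms of an OLS fit with intercept on a d-descriptor design:

    S  = sqrt(RSS / (n - d - 1))        regression standard deviation
    R2 = 1 - RSS/TSS                    training coefficient of determination
    h_i = diag of the hat matrix        leverages of the intercept-augmented design

The parameter count in S's denominator includes the intercept; this
convention is pinned by the warning-leverage identity h* = 3(d+1)/n used
by the applicability-domain stage.

Solves go through orthogonal decompositions (QR / SVD), never the normal
equations, so the engine stays stable on near-collinear pools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DataError, LinearModel

#: relative singular-value cutoff below which a design is treated as rank-deficient
RANK_RCOND = 1e-10


@dataclass
class FitStats:
    """Training-fit statistics of an OLS model."""

    r2: float
    s: float
    n: int
    d: int
    residuals: np.ndarray
    leverages: np.ndarray
    coef_se: np.ndarray  # standard errors of (coefficients..., intercept)


def _augment(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.hstack([X, np.ones((X.shape[0], 1))])


def _check_rank(A: np.ndarray, names: list[str] | None) -> None:
    # SVD-based rank test relative to the largest singular value
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[-1] <= RANK_RCOND * sv[0]:
        if names is not None and A.shape[1] == len(names) + 1:
            # point at the columns involved: those whose removal restores rank
            offenders = []
            for j, name in enumerate(names):
                sub = np.delete(A, j, axis=1)
                s2 = np.linalg.svd(sub, compute_uv=False)
                if s2[-1] > RANK_RCOND * s2[0]:
                    offenders.append(name)
            raise DataError(f"rank-deficient design; offending columns: {offenders}")
        raise DataError("rank-deficient design (with intercept)")


def fit_ols(
    X: np.ndarray, y: np.ndarray, names: list[str] | None = None
) -> tuple[LinearModel, FitStats]:
    """Fit y = b0 + sum_k b_k x_k by least squares.

    Parameters
    ----------
    X : (n, d) design of descriptor columns (no intercept column).
    y : (n,) response, log10 IC50.
    names : descriptor names for the returned model; positional names
        ``x0..x{d-1}`` when omitted.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    if names is None:
        names = [f"x{j}" for j in range(d)]
    if n <= d + 1:
        raise DataError(f"need n > d + 1 (got n={n}, d={d})")
    A = _augment(X)
    _check_rank(A, names)
    Q, R = np.linalg.qr(A)
    beta = np.linalg.solve(R, Q.T @ y)
    fitted = A @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    dof = n - d - 1
    s = float(np.sqrt(rss / dof))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    leverages = np.einsum("ij,ij->i", Q, Q)
    # SE(beta) from the inverse Gram via R: (A'A)^-1 = R^-1 R^-T
    Rinv = np.linalg.inv(R)
    cov_unscaled = Rinv @ Rinv.T
    coef_se = s * np.sqrt(np.diag(cov_unscaled))
    model = LinearModel(list(names), beta[:d], float(beta[d]), train_stats=(r2, s))
    stats = FitStats(r2=r2, s=s, n=n, d=d, residuals=resid, leverages=leverages,
                     coef_se=coef_se)
    return model, stats


def predict(model: LinearModel, dm_or_X, names: list[str] | None = None) -> np.ndarray:
    """Predict log10 IC50. Columns are matched by name, never by position.

    Accepts a DescriptorMatrix (names resolved from it) or a plain array
    plus the ``names`` of its columns.
    """
    if hasattr(dm_or_X, "matrix"):
        X = dm_or_X.matrix(model.descriptor_names)
    else:
        X = np.asarray(dm_or_X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if names is None:
            if X.shape[1] != model.d:
                raise DataError("column names required to match descriptors")
        else:
            lookup = {nm: j for j, nm in enumerate(names)}
            try:
                idx = [lookup[nm] for nm in model.descriptor_names]
            except KeyError as exc:
                raise DataError(f"missing model descriptor: {exc.args[0]!r}") from None
            X = X[:, idx]
    return model.intercept + X @ model.coefficients


def subset_stats(y_obs: np.ndarray, y_pred: np.ndarray, d: int) -> tuple[float, float]:
    """(R2, S) of predictions on a held-out subset.

    R2 is the squared Pearson correlation of observed vs predicted —
    the convention of the external-validation (Golbraikh–Tropsha)
    framework; S keeps the training denominator n - d - 1.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    n = y_obs.size
    if n < 3 or n != y_pred.size:
        raise DataError("subset_stats needs equal-length vectors, n >= 3")
    s = float(np.sqrt(np.sum((y_obs - y_pred) ** 2) / (n - d - 1)))
    if np.std(y_obs) == 0 or np.std(y_pred) == 0:
        return float("nan"), s
    r = float(np.corrcoef(y_obs, y_pred)[0, 1])
    return r * r, s


def vif_and_corr(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Variance inflation factors and the pairwise r^2 matrix of a design.

    VIF_k = 1/(1 - R2_k) where R2_k regresses column k on the other model
    columns (with intercept). Perfect multicollinearity yields inf.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if d < 2:
        raise DataError("VIF needs at least two columns")
    corr = np.corrcoef(X, rowvar=False)
    r2_matrix = corr ** 2
    vifs = np.empty(d)
    for k in range(d):
        others = np.delete(X, k, axis=1)
        A = _augment(others)
        coef, _, _, _ = np.linalg.lstsq(A, X[:, k], rcond=None)
        resid = X[:, k] - A @ coef
        tss = float(np.sum((X[:, k] - X[:, k].mean()) ** 2))
        rss = float(resid @ resid)
        r2k = 1.0 - rss / tss if tss > 0 else 0.0
        vifs[k] = np.inf if r2k >= 1.0 - 1e-12 else 1.0 / (1.0 - r2k)
    return vifs, r2_matrix


def max_pairwise_r2(X: np.ndarray) -> float:
    """Largest off-diagonal squared pairwise correlation among model columns."""
    _, r2m = vif_and_corr(X)
    mask = ~np.eye(r2m.shape[0], dtype=bool)
    return float(np.max(r2m[mask]))


def leverages_for(X_train: np.ndarray, X_query: np.ndarray) -> np.ndarray:
    """h_i = x_i' (A'A)^-1 x_i for query rows on the intercept-augmented
    training design A."""
    A = _augment(X_train)
    _check_rank(A, None)
    Q, R = np.linalg.qr(A)
    B = _augment(X_query)
    # h_i = || R^-T b_i ||^2
    W = np.linalg.solve(R.T, B.T)
    return np.einsum("ji,ji->i", W, W)
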