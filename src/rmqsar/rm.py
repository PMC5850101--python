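"""Replacement-method (RM) descriptor subset selection.

RM searches for the d-descriptor multivariable linear regression with the
smallest training standard deviation S over a pool of D descriptors
(d << D), without enumerating all C(D, d) subsets. Starting from a random
subset, it repeatedly attacks the weakest position — the descriptor whose
coefficient has the largest relative error |SE(b)/b| in the current fit —
and tries every pool descriptor in its place, keeping the replacement
that lowers S the most. A sweep visits every position once (in decreasing
relative-error order, re-ranked after each accepted replacement); the
search converges when a full sweep accepts no replacement. Multiple random
starts guard against local minima; on small pools the result matches the
exhaustive search almost always (a standing oracle test).

Candidate scoring is vectorized: with the other d-1 columns and the
intercept projected out, the RSS drop from each candidate column follows
from one pass of dot products. Correctness is *defined* by the naive
refit-per-candidate (``scan="naive"``), which the fast path must match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .data import DataError, DescriptorMatrix, LinearModel
from .mlr import fit_ols, predict, subset_stats

_EPS_IMPROVE = 1e-12  # relative RSS improvement below this is "no change"
_EPS_RANK = 1e-12  # residual column energy below this fraction is rank-deficient


@dataclass
class RmConfig:
    d: int = 8
    n_starts: int = 30
    max_sweeps: int = 50
    seed: int = 0
    scan: str = "fast"  # "fast" (projected) or "naive" (refit per candidate)


@dataclass
class SearchTrace:
    start_index: int
    sweep_strain: list[float] = field(default_factory=list)
    n_replacements: int = 0
    converged: bool = False


def _rss_of_subset(X: np.ndarray, y: np.ndarray, subset: tuple[int, ...]) -> float:
    A = np.hstack([X[:, list(subset)], np.ones((X.shape[0], 1))])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    r = y - A @ coef
    return float(r @ r)


def _strain(rss: float, n: int, d: int) -> float:
    return float(np.sqrt(max(rss, 0.0) / (n - d - 1)))


def _scan_position_fast(
    X: np.ndarray, y: np.ndarray, col_ss: np.ndarray,
    subset: list[int], pos: int,
) -> np.ndarray:
    """RSS obtained when each pool column replaces ``subset[pos]``.

    Columns that would make the design rank-deficient (including the other
    subset members) come back as +inf.
    """
    n, D = X.shape
    fixed = [c for i, c in enumerate(subset) if i != pos]
    A = np.hstack([X[:, fixed], np.ones((n, 1))])
    Q, _ = np.linalg.qr(A)
    r_y = y - Q @ (Q.T @ y)
    rss_fixed = float(r_y @ r_y)
    R = X - Q @ (Q.T @ X)  # residual pool columns
    r_norm2 = np.einsum("ij,ij->j", R, R)
    num = R.T @ r_y
    with np.errstate(divide="ignore", invalid="ignore"):
        rss = rss_fixed - np.where(r_norm2 > 0, num * num / r_norm2, 0.0)
    rss = np.maximum(rss, 0.0)
    rss[r_norm2 <= _EPS_RANK * np.maximum(col_ss, _EPS_RANK)] = np.inf
    rss[fixed] = np.inf
    return rss


def _scan_position_naive(
    X: np.ndarray, y: np.ndarray, col_ss: np.ndarray,
    subset: list[int], pos: int,
) -> np.ndarray:
    """Oracle scan: refit the full model for every candidate."""
    n, D = X.shape
    fixed = [c for i, c in enumerate(subset) if i != pos]
    rss = np.full(D, np.inf)
    for j in range(D):
        if j in fixed:
            continue
        A = np.hstack([X[:, fixed + [j]], np.ones((n, 1))])
        if np.linalg.matrix_rank(A, tol=1e-8) < A.shape[1]:
            continue
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        r = y - A @ coef
        rss[j] = float(r @ r)
    return rss


def _relative_errors(X: np.ndarray, y: np.ndarray, subset: list[int]) -> np.ndarray:
    model, stats = fit_ols(X[:, subset], y)
    beta = model.coefficients
    se = stats.coef_se[: len(subset)]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(beta != 0, np.abs(se / beta), np.inf)
    return rel


def _random_full_rank_subset(
    X: np.ndarray, d: int, rng: np.random.Generator, max_tries: int = 200
) -> list[int]:
    n, D = X.shape
    for _ in range(max_tries):
        cand = sorted(rng.choice(D, size=d, replace=False).tolist())
        A = np.hstack([X[:, cand], np.ones((n, 1))])
        if np.linalg.matrix_rank(A, tol=1e-8) == d + 1:
            return cand
    raise DataError("could not draw a full-rank starting subset")


def _run_one_start(
    X: np.ndarray, y: np.ndarray, col_ss: np.ndarray, subset: list[int],
    cfg: RmConfig, start_index: int,
) -> tuple[list[int], float, SearchTrace]:
    n, D = X.shape
    d = len(subset)
    scan = _scan_position_fast if cfg.scan == "fast" else _scan_position_naive
    trace = SearchTrace(start_index=start_index)
    rss_current = _rss_of_subset(X, y, tuple(subset))
    for _ in range(cfg.max_sweeps):
        frozen: set[int] = set()
        changed = False
        while len(frozen) < d:
            rel = _relative_errors(X, y, subset)
            order = np.argsort(-rel, kind="stable")
            pos = next(int(p) for p in order if int(p) not in frozen)
            rss = scan(X, y, col_ss, subset, pos)
            j_best = int(np.argmin(rss))  # argmin breaks ties at lowest pool index
            if (j_best != subset[pos]
                    and rss[j_best] < rss_current * (1.0 - _EPS_IMPROVE)
                    and rss[j_best] < rss_current):
                subset[pos] = j_best
                rss_current = float(rss[j_best])
                trace.n_replacements += 1
                changed = True
            frozen.add(pos)
        trace.sweep_strain.append(_strain(rss_current, n, d))
        if not changed:
            trace.converged = True
            break
    return subset, rss_current, trace


def rm_select(
    pool: DescriptorMatrix,
    y: np.ndarray,
    cfg: RmConfig,
    initial_subsets: list[list[int]] | None = None,
) -> tuple[LinearModel, list[SearchTrace]]:
    """Best d-descriptor linear model found by RM over all starts.

    ``initial_subsets`` (pool column indices) are run as extra warm starts
    before the ``n_starts`` random ones. Deterministic given the seed.
    """
    X = pool.values
    y = np.asarray(y, dtype=float)
    n, D = X.shape
    d = cfg.d
    if not (1 <= d <= D):
        raise DataError(f"d={d} outside pool size D={D}")
    if n <= d + 1:
        raise DataError(f"need n > d + 1 for d={d} (n={n})")
    if pool.missing_mask.any():
        raise DataError("RM requires a pool with no missing values")
    rng = np.random.default_rng(cfg.seed)
    col_ss = np.einsum("ij,ij->j", X, X)

    starts: list[list[int]] = [sorted(s) for s in (initial_subsets or [])]
    if d == D:
        starts = [list(range(D))]
        n_random = 0
    else:
        n_random = cfg.n_starts
    for _ in range(n_random):
        starts.append(_random_full_rank_subset(X, d, rng))

    best_subset: list[int] | None = None
    best_rss = np.inf
    traces: list[SearchTrace] = []
    for i, s0 in enumerate(starts):
        subset, rss, trace = _run_one_start(X, y, col_ss, list(s0), cfg, i)
        traces.append(trace)
        key = (rss, tuple(sorted(subset)))
        if best_subset is None or key < (best_rss, tuple(sorted(best_subset))):
            best_subset, best_rss = sorted(subset), rss
    names = [pool.descriptor_names[j] for j in best_subset]
    model, _ = fit_ols(X[:, best_subset], y, names=names)
    return model, traces


def exhaustive_select(
    pool: DescriptorMatrix, y: np.ndarray, d: int
) -> tuple[LinearModel, float]:
    """Full combinatorial search over all C(D, d) subsets — the oracle RM
    is measured against on small pools. Returns the optimum model and its
    training S; ties broken by lexicographically lowest index tuple.
    """
    X = pool.values
    y = np.asarray(y, dtype=float)
    n, D = X.shape
    best: tuple[float, tuple[int, ...]] | None = None
    for subset in combinations(range(D), d):
        A = np.hstack([X[:, list(subset)], np.ones((n, 1))])
        coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        if rank < A.shape[1]:
            continue
        r = y - A @ coef
        rss = float(r @ r)
        if best is None or (rss, subset) < best:
            best = (rss, subset)
    if best is None:
        raise DataError("no full-rank subset of the requested size")
    rss, subset = best
    names = [pool.descriptor_names[j] for j in subset]
    model, stats = fit_ols(X[:, list(subset)], y, names=names)
    return model, stats.s


def model_ladder(
    train_dm: DescriptorMatrix,
    y_train: np.ndarray,
    d_range: range | list[int],
    cfg: RmConfig,
    val_dm: DescriptorMatrix,
    y_val: np.ndarray,
    test_dm: DescriptorMatrix | None = None,
    y_test: np.ndarray | None = None,
    warm_start: bool = True,
    selection_tol: float = 0.01,
) -> tuple[pd.DataFrame, dict[int, LinearModel], int]:
    """Best RM model per size d, with validation (and optional test) stats.

    The *selected* size is the smallest d whose validation S lies within
    ``selection_tol`` of the ladder's minimum — the parsimony rule that
    prefers an equally predictive smaller model. With ``warm_start`` on,
    each size seeds one start with the previous optimum plus its best
    single extension, which makes the training-S ladder non-increasing.
    """
    d_range = sorted(d_range)
    rows = []
    models: dict[int, LinearModel] = {}
    prev_subset: list[int] | None = None
    X = train_dm.values
    col_ss = np.einsum("ij,ij->j", X, X)
    for d in d_range:
        size_cfg = RmConfig(d=d, n_starts=cfg.n_starts, max_sweeps=cfg.max_sweeps,
                            seed=cfg.seed + d, scan=cfg.scan)
        inits: list[list[int]] = []
        if warm_start and prev_subset is not None and len(prev_subset) == d - 1:
            # extend the previous optimum by the best single addition
            rss = _scan_position_fast(X, y_train, col_ss, prev_subset + [-1],
                                      len(prev_subset))
            j = int(np.argmin(rss))
            if np.isfinite(rss[j]):
                inits.append(prev_subset + [j])
        model, _ = rm_select(train_dm, y_train, size_cfg, initial_subsets=inits)
        models[d] = model
        prev_subset = sorted(train_dm.column_index(model.descriptor_names).tolist())
        r2_tr, s_tr = model.train_stats
        r2_v, s_v = subset_stats(y_val, predict(model, val_dm), d)
        row = {"d": d, "descriptors": ";".join(model.descriptor_names),
               "r2_train": r2_tr, "s_train": s_tr, "r2_val": r2_v, "s_val": s_v}
        if test_dm is not None and y_test is not None:
            r2_t, s_t = subset_stats(y_test, predict(model, test_dm), d)
            row.update({"r2_test": r2_t, "s_test": s_t})
        rows.append(row)
    table = pd.DataFrame(rows)
    s_min = table["s_val"].min()
    selected_d = int(table.loc[table["s_val"] <= s_min + selection_tol, "d"].min())
    table["selected"] = table["d"] == selected_d
    return table, models, selected_d
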