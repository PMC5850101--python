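"""Descriptor-pool reduction: drop uninformative and collinear columns.

Raw descriptor pools from fingerprint/descriptor software are dominated by
columns that cannot enter a linear model: constants, near-constants (a
single modal value in almost every compound), columns with missing
entries, and exact or near-exact linear copies. The two filters here
reduce the pool to linearly independent, informative columns before any
subset search runs; neither looks at the response, so the reduction
cannot bias selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DataError, DescriptorMatrix

DEFAULT_NEAR_CONST_FRAC = 0.95
DEFAULT_COLLINEAR_R2 = 0.998


@dataclass
class PrefilterReport:
    removed_constant: list[str] = field(default_factory=list)
    removed_near_constant: list[str] = field(default_factory=list)
    removed_missing: list[str] = field(default_factory=list)
    removed_collinear: list[tuple[str, str]] = field(default_factory=list)  # (kept, dropped)
    pool_size_before: int = 0
    pool_size_after: int = 0

    @property
    def n_removed(self) -> int:
        return (len(self.removed_constant) + len(self.removed_near_constant)
                + len(self.removed_missing) + len(self.removed_collinear))

    def to_frame(self) -> pd.DataFrame:
        rows = [("missing", nm, "") for nm in self.removed_missing]
        rows += [("constant", nm, "") for nm in self.removed_constant]
        rows += [("near_constant", nm, "") for nm in self.removed_near_constant]
        rows += [("collinear", dropped, kept) for kept, dropped in self.removed_collinear]
        return pd.DataFrame(rows, columns=["reason", "dropped", "kept_partner"])


def _modal_fraction(col: np.ndarray) -> float:
    _, counts = np.unique(col, return_counts=True)
    return counts.max() / col.size


def drop_uninformative(
    dm: DescriptorMatrix, near_const_frac: float = DEFAULT_NEAR_CONST_FRAC
) -> tuple[DescriptorMatrix, PrefilterReport]:
    """Remove columns with any missing value, constant columns, and columns
    whose modal value frequency is >= ``near_const_frac``.

    A column qualifying under several rules is reported once, with the
    missing-value rule taking priority (it is checked on the raw column,
    before the value distribution is even meaningful).
    """
    if dm.n_compounds < 2:
        raise DataError("drop_uninformative needs at least 2 compounds")
    report = PrefilterReport(pool_size_before=dm.n_descriptors)
    keep: list[int] = []
    for j, name in enumerate(dm.descriptor_names):
        col = dm.values[:, j]
        if dm.missing_mask[:, j].any():
            report.removed_missing.append(name)
            continue
        if np.all(col == col[0]):
            report.removed_constant.append(name)
            continue
        if _modal_fraction(col) >= near_const_frac:
            report.removed_near_constant.append(name)
            continue
        keep.append(j)
    if not keep:
        raise DataError("prefilter removed every descriptor column")
    out = DescriptorMatrix(
        list(dm.compound_ids),
        [dm.descriptor_names[j] for j in keep],
        dm.values[:, keep].copy(),
        dm.missing_mask[:, keep].copy(),
    )
    report.pool_size_after = out.n_descriptors
    return out, report


def drop_collinear(
    dm: DescriptorMatrix, r2_threshold: float = DEFAULT_COLLINEAR_R2
) -> tuple[DescriptorMatrix, PrefilterReport]:
    """Greedy scan in column order: a column whose squared Pearson
    correlation with any already-kept column is >= ``r2_threshold`` is
    dropped (the earlier column of the pair wins — deterministic and
    order-stable). The kept pool satisfies all pairwise r^2 < threshold.
    """
    if dm.missing_mask.any():
        raise DataError("drop_collinear requires a pool with no missing values "
                        "(run drop_uninformative first)")
    report = PrefilterReport(pool_size_before=dm.n_descriptors)
    V = dm.values
    n = V.shape[0]
    # standardized columns: r(a, b) = za . zb / n
    mu = V.mean(axis=0)
    sd = V.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (V - mu) / sd_safe
    Z[:, sd == 0] = 0.0  # zero-variance columns correlate with nothing

    kept: list[int] = []
    Zk = np.empty((n, dm.n_descriptors))
    for j, name in enumerate(dm.descriptor_names):
        if kept:
            r = Zk[:, : len(kept)].T @ Z[:, j] / n
            hits = np.nonzero(r * r >= r2_threshold)[0]
            if hits.size:
                partner = dm.descriptor_names[kept[int(hits[0])]]
                report.removed_collinear.append((partner, name))
                continue
        Zk[:, len(kept)] = Z[:, j]
        kept.append(j)
    out = DescriptorMatrix(
        list(dm.compound_ids),
        [dm.descriptor_names[j] for j in kept],
        V[:, kept].copy(),
        dm.missing_mask[:, kept].copy(),
    )
    report.pool_size_after = out.n_descriptors
    return out, report


def prefilter_pool(
    dm: DescriptorMatrix,
    near_const_frac: float = DEFAULT_NEAR_CONST_FRAC,
    r2_threshold: float = DEFAULT_COLLINEAR_R2,
) -> tuple[DescriptorMatrix, PrefilterReport]:
    """Full reduction: uninformative columns first, then collinear pairs."""
    dm1, rep1 = drop_uninformative(dm, near_const_frac)
    dm2, rep2 = drop_collinear(dm1, r2_threshold)
    merged = PrefilterReport(
        removed_constant=rep1.removed_constant,
        removed_near_constant=rep1.removed_near_constant,
        removed_missing=rep1.removed_missing,
        removed_collinear=rep2.removed_collinear,
        pool_size_before=rep1.pool_size_before,
        pool_size_after=rep2.pool_size_after,
    )
    return dm2, merged
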