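"""Balanced subsets splitting (BSM) via k-means in descriptor space.

The splitter clusters compounds with Euclidean k-means on (optionally
autoscaled) descriptors and then spreads every cluster across the
train/validation/test subsets, so each subset samples the whole region of
descriptor space the model will be asked to cover. Within a cluster,
members closest to the centroid go to the training set first — the most
representative compounds calibrate the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from sklearn.cluster import KMeans

from .data import ActivitySet, DataError, DescriptorMatrix, SubsetPartition, SUBSETS


@dataclass
class BsmConfig:
    fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    k_clusters: int | None = None  # default ceil(N / 20)
    standardize: bool = True
    seed: int = 0
    n_init: int = 10

    def validate(self, n: int) -> int:
        if any(f <= 0 for f in self.fractions):
            raise DataError("subset fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise DataError("subset fractions must sum to 1")
        k = self.k_clusters if self.k_clusters is not None else int(np.ceil(n / 20))
        k = max(k, 2)
        if k > n:
            raise DataError(f"k_clusters={k} exceeds N={n}")
        return k


def subset_sizes(n: int, fractions: tuple[float, float, float]) -> dict[str, int]:
    """floor(N * fraction) per subset; the remaining units go to the largest
    fractional parts, ties resolved train then val then test.

    For N = 530 at (0.5, 0.25, 0.25) this yields 265/133/132.
    """
    exact = [n * f for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    rem = n - sum(base)
    order = sorted(range(3), key=lambda j: (-(exact[j] - base[j]), j))
    for i in range(rem):
        base[order[i]] += 1
    return dict(zip(SUBSETS, base))


def split(dm: DescriptorMatrix, cfg: BsmConfig) -> tuple[SubsetPartition, np.ndarray]:
    """Partition compounds into train/val/test.

    Returns the partition and the per-compound k-means cluster labels.
    Deterministic for a fixed seed and input.
    """
    if dm.missing_mask.any():
        raise DataError("BSM split requires a pool with no missing values")
    n = dm.n_compounds
    if n < 10:
        raise DataError("BSM split needs at least 10 compounds")
    k = cfg.validate(n)
    X = dm.values.astype(float)
    if cfg.standardize:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=k, n_init=cfg.n_init, random_state=cfg.seed)
    clusters = km.fit_predict(X)
    dists = np.linalg.norm(X - km.cluster_centers_[clusters], axis=1)

    targets = subset_sizes(n, cfg.fractions)
    labels = np.empty(n, dtype=object)
    rank_in_cluster = np.empty(n, dtype=int)  # distance rank, 0 = closest

    # per-cluster proportional round-robin over members sorted by centroid
    # distance; ties resolved train > val > test so the closest member of
    # every cluster lands in train
    for c in range(k):
        members = np.nonzero(clusters == c)[0]
        members = members[np.argsort(dists[members], kind="stable")]
        assigned = {s: 0 for s in SUBSETS}
        for i, idx in enumerate(members):
            scores = [cfg.fractions[j] * (i + 1) - assigned[s]
                      for j, s in enumerate(SUBSETS)]
            s = SUBSETS[int(np.argmax(scores))]
            labels[idx] = s
            assigned[s] += 1
            rank_in_cluster[idx] = i

    # reconcile with the exact global sizes: move the least representative
    # (farthest-from-centroid) members out of over-full subsets, preferring
    # clusters that keep at least one member in the donor subset
    counts = {s: int(np.sum(labels == s)) for s in SUBSETS}
    while counts != targets:
        donor = next(s for s in SUBSETS if counts[s] > targets[s])
        receiver = max(SUBSETS, key=lambda s: targets[s] - counts[s])
        cand = np.nonzero(labels == donor)[0]
        cluster_counts = {c: 0 for c in range(k)}
        for idx in cand:
            cluster_counts[clusters[idx]] += 1
        # sort key: keep-cluster-covered first, then farthest, then index
        best = min(
            cand,
            key=lambda idx: (
                cluster_counts[clusters[idx]] <= 1,
                -dists[idx],
                idx,
            ),
        )
        labels[best] = receiver
        counts[donor] -= 1
        counts[receiver] += 1

    part = SubsetPartition(list(dm.compound_ids), list(labels))
    return part, clusters


def random_split(
    n_or_ids, fractions: tuple[float, float, float] = (0.5, 0.25, 0.25), seed: int = 0
) -> SubsetPartition:
    """Plain seeded random split with the same size contract — the naive
    baseline BSM is compared against."""
    ids = ([f"CPD{i + 1:04d}" for i in range(n_or_ids)]
           if isinstance(n_or_ids, int) else list(n_or_ids))
    n = len(ids)
    sizes = subset_sizes(n, fractions)
    pool = list(np.random.default_rng(seed).permutation(n))
    labels = np.empty(n, dtype=object)
    start = 0
    for s in SUBSETS:
        for i in pool[start:start + sizes[s]]:
            labels[i] = s
        start += sizes[s]
    return SubsetPartition(ids, list(labels))


def balance_diagnostics(part: SubsetPartition, act: ActivitySet) -> pd.DataFrame:
    """Per-subset activity summary plus the Kolmogorov–Smirnov distance of
    each held-out subset's activity distribution from the training set's.
    Diagnostic only — no decision is taken on it.
    """
    if part.compound_ids != act.compound_ids:
        raise DataError("partition and activities must be aligned")
    y = act.log10_ic50
    y_train = y[part.indices("train")]
    rows = []
    for s in SUBSETS:
        ys = y[part.indices(s)]
        ks = 0.0 if s == "train" else float(ks_2samp(y_train, ys).statistic)
        rows.append({
            "subset": s, "n": ys.size, "mean": float(ys.mean()),
            "sd": float(ys.std(ddof=1)) if ys.size > 1 else 0.0,
            "min": float(ys.min()), "max": float(ys.max()),
            "ks_vs_train": ks,
        })
    return pd.DataFrame(rows)
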