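"""Synthetic descriptor pools with a planted linear structure-activity signal.

The generator emulates the statistical shape of a curated kinase-inhibitor
QSAR dataset: a few hundred compounds, activities spanning several log10
units of IC50, and a large descriptor pool mixing continuous (E-state-like)
columns and binary (fingerprint-bit-like) columns, contaminated with
constant, near-constant, missing-valued, and pairwise-collinear columns —
exactly the pathologies the prefilter stage removes.

A small number of continuous columns carry the true linear model

    log10 IC50 = b0 + sum_k b_k x_k + Normal(0, noise_sd)

and everything else is independent of the response. The clean (pre-noise)
activity is affine-mapped onto ``activity_range``, so the absolute scale
of the drawn coefficients cancels; the planted *effective* coefficients
(recorded in PlantedTruth) are what any refit should recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import ActivitySet, DescriptorMatrix

# default activity range of the modeled IC50 window, log10 nM: 0.8 .. 145,000 nM
DEFAULT_ACTIVITY_RANGE = (math.log10(0.8), math.log10(145_000.0))


class SpecError(ValueError):
    """Infeasible generator specification."""


@dataclass
class SyntheticSpec:
    """Generator configuration.

    Defaults describe the study conditions this package targets: 530
    compounds, a 2,000-column pool, an 8-descriptor planted model, and
    residual noise of 0.8 log10 units.
    """

    n_compounds: int = 530
    n_descriptors: int = 2000
    n_signal: int = 8
    noise_sd: float = 0.8
    collinear_block_count: int = 20
    collinear_block_size: int = 3
    frac_binary: float = 0.6
    frac_constant: float = 0.02
    frac_near_constant: float = 0.03
    frac_missing_cols: float = 0.02
    activity_range: tuple[float, float] = DEFAULT_ACTIVITY_RANGE
    seed: int = 0

    def validate(self) -> None:
        if self.n_compounds < 2:
            raise SpecError("need at least 2 compounds")
        if not (0 <= self.n_signal <= self.n_descriptors):
            raise SpecError("n_signal must lie in [0, n_descriptors]")
        for name in ("frac_binary", "frac_constant", "frac_near_constant",
                     "frac_missing_cols"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SpecError(f"{name} must lie in [0, 1] (got {v})")
        if self.frac_constant + self.frac_near_constant + self.frac_missing_cols > 1.0:
            raise SpecError("contamination fractions jointly exceed 1")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if self.activity_range[0] >= self.activity_range[1]:
            raise SpecError("activity_range must be (min, max) with min < max")
        if self.collinear_block_count and self.collinear_block_size < 2:
            raise SpecError("collinear blocks need size >= 2")
        if self._counts()["plain"] < max(1, self.collinear_block_count):
            raise SpecError(
                "infeasible spec: constant/near-constant/missing/collinear columns "
                "leave too few plain decoys for the requested pool"
            )

    def _counts(self) -> dict[str, int]:
        D = self.n_descriptors
        n_const = round(self.frac_constant * D)
        n_near = round(self.frac_near_constant * D)
        n_miss = round(self.frac_missing_cols * D)
        n_collin = self.collinear_block_count * (self.collinear_block_size - 1)
        plain = D - self.n_signal - n_const - n_near - n_miss - n_collin
        return {"const": n_const, "near": n_near, "miss": n_miss,
                "collin_extra": n_collin, "plain": plain}


@dataclass
class PlantedTruth:
    """Ground truth of the planted model, on the effective (post-mapping) scale."""

    signal_names: list[str]
    beta: dict[str, float]
    intercept: float
    noise_sd: float
    collinear_pairs: list[tuple[str, str]] = field(default_factory=list)


def generate(spec: SyntheticSpec) -> tuple[DescriptorMatrix, ActivitySet, PlantedTruth]:
    """Generate (descriptors, activities, truth) for one seed.

    Identical seed gives bit-identical output. Decoy columns are i.i.d.
    standard normal (continuous) or Bernoulli (binary); planted coefficient
    magnitudes are drawn within a <2x band of each other so every signal
    column contributes comparably, mirroring a selected model in which each
    retained descriptor carries detectable weight.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, D = spec.n_compounds, spec.n_descriptors
    counts = spec._counts()

    columns: list[np.ndarray] = []
    kinds: list[str] = []  # 'sig', 'cont', 'bin', 'const', 'near', 'miss', 'collin'

    # --- signal block: continuous, unit variance ---
    X_sig = rng.standard_normal((n, spec.n_signal))
    for j in range(spec.n_signal):
        columns.append(X_sig[:, j])
        kinds.append("sig")

    # --- plain decoys ---
    n_plain = counts["plain"]
    n_bin = round(spec.frac_binary * n_plain)
    n_cont = n_plain - n_bin
    for _ in range(n_cont):
        columns.append(rng.standard_normal(n))
        kinds.append("cont")
    for _ in range(n_bin):
        p = rng.uniform(0.05, 0.5)
        columns.append(rng.binomial(1, p, size=n).astype(float))
        kinds.append("bin")

    # --- collinear blocks: affine copies of continuous decoy parents ---
    cont_positions = [i for i, k in enumerate(kinds) if k == "cont"]
    collinear_parent_pos: list[int] = []
    if spec.collinear_block_count:
        parents = rng.choice(cont_positions, size=spec.collinear_block_count,
                             replace=False)
        for p_idx in parents:
            for _ in range(spec.collinear_block_size - 1):
                scale = rng.uniform(0.5, 2.0)
                shift = rng.uniform(-1.0, 1.0)
                columns.append(scale * columns[p_idx] + shift)
                kinds.append("collin")
                collinear_parent_pos.append(int(p_idx))

    # --- constant columns ---
    for _ in range(counts["const"]):
        columns.append(np.full(n, float(rng.integers(0, 10))))
        kinds.append("const")

    # --- near-constant columns: rare fingerprint bits, modal freq > 95% ---
    for _ in range(counts["near"]):
        mode_frac = rng.uniform(0.96, 0.995)
        col = np.zeros(n)
        n_hot = max(1, n - int(math.floor(mode_frac * n)))
        hot = rng.choice(n, size=n_hot, replace=False)
        col[hot] = 1.0
        columns.append(col)
        kinds.append("near")

    # --- columns with missing entries ---
    for _ in range(counts["miss"]):
        col = rng.standard_normal(n)
        n_nan = max(1, round(0.01 * n))
        col[rng.choice(n, size=n_nan, replace=False)] = np.nan
        columns.append(col)
        kinds.append("miss")

    assert len(columns) == D

    # shuffle column placement so type gives away nothing positionally
    order = rng.permutation(D)
    inv = np.empty(D, dtype=int)
    inv[order] = np.arange(D)

    names = [""] * D
    cont_kinds = {"sig", "cont", "collin", "const", "miss"}
    for new_pos, old_pos in enumerate(order):
        prefix = "E" if kinds[old_pos] in cont_kinds else "F"
        names[new_pos] = f"{prefix}{new_pos + 1:05d}"
    values = np.column_stack([columns[old] for old in order])
    ids = [f"CPD{i + 1:04d}" for i in range(n)]
    dm = DescriptorMatrix(ids, names, values)

    signal_names = [names[inv[j]] for j in range(spec.n_signal)]
    collinear_pairs = []
    child_positions = [i for i, k in enumerate(kinds) if k == "collin"]
    for child_old, parent_old in zip(child_positions, collinear_parent_pos):
        collinear_pairs.append((names[inv[parent_old]], names[inv[child_old]]))

    # --- planted response ---
    lo, hi = spec.activity_range
    if spec.n_signal == 0:
        y_clean = np.full(n, 0.5 * (lo + hi))
        beta_eff = np.zeros(0)
        b0 = 0.5 * (lo + hi)
    else:
        signs = rng.choice([-1.0, 1.0], size=spec.n_signal)
        beta_raw = signs * rng.uniform(0.75, 1.25, size=spec.n_signal)
        raw = X_sig @ beta_raw
        span = raw.max() - raw.min()
        if span <= 0:
            raise SpecError("degenerate planted signal (zero spread)")
        a = (hi - lo) / span
        b0 = lo - a * raw.min()
        y_clean = a * raw + b0
        beta_eff = a * beta_raw
    y = y_clean + spec.noise_sd * rng.standard_normal(n)
    act = ActivitySet.from_log10(ids, y)

    truth = PlantedTruth(
        signal_names=signal_names,
        beta={nm: float(b) for nm, b in zip(signal_names, beta_eff)},
        intercept=float(b0),
        noise_sd=spec.noise_sd,
        collinear_pairs=collinear_pairs,
    )
    return dm, act, truth


def write_truth(truth: PlantedTruth, path) -> None:
    """Serialize PlantedTruth as a key-value text file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"intercept\t{truth.intercept!r}\n")
        fh.write(f"noise_sd\t{truth.noise_sd!r}\n")
        for nm in truth.signal_names:
            fh.write(f"beta:{nm}\t{truth.beta[nm]!r}\n")
        for parent, child in truth.collinear_pairs:
            fh.write(f"collinear\t{parent}\t{child}\n")


def read_truth(path) -> PlantedTruth:
    intercept = noise_sd = 0.0
    beta: dict[str, float] = {}
    pairs: list[tuple[str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "intercept":
                intercept = float(parts[1])
            elif parts[0] == "noise_sd":
                noise_sd = float(parts[1])
            elif parts[0].startswith("beta:"):
                beta[parts[0][5:]] = float(parts[1])
            elif parts[0] == "collinear":
                pairs.append((parts[1], parts[2]))
    return PlantedTruth(list(beta), beta, intercept, noise_sd, pairs)
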