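"""Shared data model and delimited-text I/O.

The pipeline is driven by two tables: a compounds x descriptors matrix of
precomputed molecular descriptors, and a per-compound activity table
(IC50 in nM, modeled throughout on the log10 scale). Both are plain
delimited text; descriptor exporters disagree on delimiters, so the
reader sniffs among comma/tab/semicolon unless one is forced.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("rmqsar")

_DELIMITERS = (",", "\t", ";")

TRAIN, VAL, TEST = "train", "val", "test"
SUBSETS = (TRAIN, VAL, TEST)


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class DescriptorMatrix:
    """Compounds x descriptors numeric table with an explicit missing mask.

    ``values`` is an N x D float array; entries flagged in ``missing_mask``
    hold NaN and must be ignored (or filtered out) downstream. Both the
    raw pool (D columns) and a fitted model's d columns live in this type.
    """

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("descriptor values must be a 2-D array")
        n, d = self.values.shape
        if len(self.compound_ids) != n or len(self.descriptor_names) != d:
            raise DataError(
                f"shape mismatch: {n}x{d} grid vs {len(self.compound_ids)} ids, "
                f"{len(self.descriptor_names)} names"
            )
        if len(set(self.compound_ids)) != n:
            raise DataError("duplicate compound ids")
        if len(set(self.descriptor_names)) != d:
            seen: set[str] = set()
            dup = next(x for x in self.descriptor_names if x in seen or seen.add(x))
            raise DataError(f"duplicate descriptor name: {dup!r}")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise DataError("missing_mask shape mismatch")

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]

    def column_index(self, names: list[str]) -> np.ndarray:
        """Positions of ``names``; matching is by name, never by position."""
        lookup = {name: j for j, name in enumerate(self.descriptor_names)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:
            raise DataError(f"descriptor not in matrix: {exc.args[0]!r}") from None

    def select_columns(self, names: list[str]) -> "DescriptorMatrix":
        idx = self.column_index(names)
        return DescriptorMatrix(
            list(self.compound_ids),
            list(names),
            self.values[:, idx].copy(),
            self.missing_mask[:, idx].copy(),
        )

    def select_rows(self, row_idx: np.ndarray) -> "DescriptorMatrix":
        return DescriptorMatrix(
            [self.compound_ids[i] for i in row_idx],
            list(self.descriptor_names),
            self.values[row_idx].copy(),
            self.missing_mask[row_idx].copy(),
        )

    def matrix(self, names: list[str] | None = None) -> np.ndarray:
        """Dense array of the named columns (all columns when None)."""
        if names is None:
            return self.values
        return self.values[:, self.column_index(names)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.where(self.missing_mask, np.nan, self.values),
            index=pd.Index(self.compound_ids, name="compound_id"),
            columns=self.descriptor_names,
        )


@dataclass
class ActivitySet:
    """Per-compound IC50 (nM, strictly positive) and its log10 transform."""

    compound_ids: list[str]
    ic50: np.ndarray
    log10_ic50: np.ndarray

    def __post_init__(self) -> None:
        self.ic50 = np.asarray(self.ic50, dtype=float)
        self.log10_ic50 = np.asarray(self.log10_ic50, dtype=float)
        if not (len(self.compound_ids) == self.ic50.size == self.log10_ic50.size):
            raise DataError("activity table length mismatch")
        if np.any(self.ic50 <= 0) or np.any(~np.isfinite(self.ic50)):
            bad = self.compound_ids[int(np.argmax(~(self.ic50 > 0)))]
            raise DataError(f"nonpositive or non-finite IC50 for compound {bad!r}")
        if np.max(np.abs(self.log10_ic50 - np.log10(self.ic50))) > 1e-12:
            raise DataError("log10_ic50 inconsistent with ic50")

    @classmethod
    def from_ic50(cls, ids: list[str], ic50) -> "ActivitySet":
        ic50 = np.asarray(ic50, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return cls(list(ids), ic50, np.log10(ic50))

    @classmethod
    def from_log10(cls, ids: list[str], log10_ic50) -> "ActivitySet":
        log10_ic50 = np.asarray(log10_ic50, dtype=float)
        return cls(list(ids), np.power(10.0, log10_ic50), log10_ic50)

    def subset(self, row_idx: np.ndarray) -> "ActivitySet":
        return ActivitySet(
            [self.compound_ids[i] for i in row_idx],
            self.ic50[row_idx],
            self.log10_ic50[row_idx],
        )


@dataclass
class SubsetPartition:
    """Train/val/test label per compound, exhaustive and disjoint."""

    compound_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.compound_ids) != len(self.labels):
            raise DataError("partition length mismatch")
        bad = set(self.labels) - set(SUBSETS)
        if bad:
            raise DataError(f"unknown subset labels: {sorted(bad)}")
        for s in SUBSETS:
            if s not in self.labels:
                raise DataError(f"subset {s!r} is empty")
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise DataError("duplicate compound ids in partition")

    def indices(self, subset: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.labels) if s == subset], dtype=int)

    def sizes(self) -> dict[str, int]:
        return {s: int(sum(1 for x in self.labels if x == s)) for s in SUBSETS}


@dataclass
class LinearModel:
    """A fitted MLR model: d named descriptors, coefficients, intercept."""

    descriptor_names: list[str]
    coefficients: np.ndarray
    intercept: float
    train_stats: tuple[float, float] | None = None  # (R2_train, S_train)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.size != len(self.descriptor_names):
            raise DataError("coefficient count does not match descriptor names")

    @property
    def d(self) -> int:
        return len(self.descriptor_names)

    def equation(self, digits: int = 3) -> str:
        terms = [
            f"{c:+.{digits}f}*{name}"
            for name, c in zip(self.descriptor_names, self.coefficients)
        ]
        return "log10IC50 = " + " ".join(terms) + f" {self.intercept:+.{digits}f}"


def _sniff_delimiter(header: str) -> str:
    counts = {d: header.count(d) for d in _DELIMITERS}
    best = max(counts, key=lambda d: counts[d])
    if counts[best] == 0:
        raise DataError("could not detect delimiter (no comma/tab/semicolon in header)")
    return best


def read_descriptor_table(path, delimiter: str | None = None) -> DescriptorMatrix:
    """Read a delimited descriptor table: header row of descriptor names,
    first column compound id. Non-numeric or empty cells become missing-mask
    entries rather than errors; ragged rows are rejected with the row number.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise DataError(f"{path}: empty file")
        delim = delimiter or _sniff_delimiter(header)
        names = [c.strip() for c in header.rstrip("\n").split(delim)][1:]
        if not names:
            raise DataError(f"{path}: no descriptor columns")
        ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split(delim)
            if len(cells) != len(names) + 1:
                raise DataError(
                    f"{path}: row {lineno} has {len(cells)} cells, expected {len(names) + 1}"
                )
            ids.append(cells[0].strip())
            row = []
            for cell in cells[1:]:
                try:
                    row.append(float(cell.strip()))
                except ValueError:
                    row.append(math.nan)  # empty or non-numeric -> missing
            rows.append(row)
    if not rows:
        raise DataError(f"{path}: no data rows")
    return DescriptorMatrix(ids, names, np.array(rows, dtype=float))


def write_descriptor_table(dm: DescriptorMatrix, path, delimiter: str = ",") -> None:
    dm.to_frame().to_csv(path, sep=delimiter, na_rep="")


def read_activity_table(path, ic50_given: bool = True, delimiter: str | None = None) -> ActivitySet:
    """Read a two-column (id, value) activity table.

    ``ic50_given`` selects the units: IC50 in nM (default, the measured
    quantity) or log10 IC50 directly.
    """
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    delim = delimiter or _sniff_delimiter(first)
    df = pd.read_csv(path, sep=delim, dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected two columns (id, value)")
    ids = df.iloc[:, 0].astype(str).str.strip().tolist()
    vals = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(dtype=float)
    if ic50_given:
        return ActivitySet.from_ic50(ids, vals)
    return ActivitySet.from_log10(ids, vals)


def write_activity_table(act: ActivitySet, path, delimiter: str = ",") -> None:
    pd.DataFrame({"compound_id": act.compound_ids, "ic50_nM": act.ic50}).to_csv(
        path, sep=delimiter, index=False
    )


def read_partition(path, delimiter: str | None = None) -> SubsetPartition:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    delim = delimiter or _sniff_delimiter(first)
    df = pd.read_csv(path, sep=delim, dtype=str)
    return SubsetPartition(
        df.iloc[:, 0].str.strip().tolist(), df.iloc[:, 1].str.strip().tolist()
    )


def write_partition(part: SubsetPartition, path, delimiter: str = ",") -> None:
    pd.DataFrame({"compound_id": part.compound_ids, "subset": part.labels}).to_csv(
        path, sep=delimiter, index=False
    )


def align(dm: DescriptorMatrix, act: ActivitySet) -> tuple[DescriptorMatrix, ActivitySet]:
    """Restrict both tables to their id intersection, in descriptor-table order."""
    act_pos = {cid: i for i, cid in enumerate(act.compound_ids)}
    keep_dm = [i for i, cid in enumerate(dm.compound_ids) if cid in act_pos]
    if not keep_dm:
        raise DataError("no shared compound ids between descriptors and activities")
    dropped = (dm.n_compounds - len(keep_dm)) + (len(act.compound_ids) - len(keep_dm))
    if dropped:
        logger.info("align: dropped %d unmatched compounds", dropped)
    dm2 = dm.select_rows(np.array(keep_dm, dtype=int))
    act2 = act.subset(np.array([act_pos[cid] for cid in dm2.compound_ids], dtype=int))
    return dm2, act2
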