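"""Watson/Crick count matrices, strand state frequency, and library QC.

Strand-seq retains a single template strand per chromosome per cell, so the
orientation of read alignments (Watson = reference forward, Crick = reverse)
carries the inherited strand state. The raw signal here is a pair of
unitig x library matrices of first-mate alignment counts, one built from all
reads and one restricted to haplotype-informative reads (single-SMEM
alignments, filtered upstream).

The strand state frequency (SSF) for Watson count w and Crick count c is

    SSF = (w - c) / (w + c)

which is 0 for balanced counts (unmatched WC/CW state expected), and +1/-1
when all alignments are Watson/Crick (matched WW/CC state expected).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SSFMatrix",
    "StrandState",
    "StrandStateCalls",
    "CountTableError",
    "read_count_table",
    "write_count_table",
    "strand_state_frequency",
    "call_strand_states",
    "library_qc",
]


class CountTableError(ValueError):
    """Raised for malformed count-table input."""


@dataclass
class CountMatrix:
    """Dense unitig x library Watson and Crick alignment-count matrices.

    ``W`` and ``C`` share shape ``(len(unitigs), len(libraries))`` and hold
    non-negative integers.
    """

    unitigs: list[str]
    libraries: list[str]
    W: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W)
        self.C = np.asarray(self.C)
        if self.W.shape != self.C.shape:
            raise ValueError("W and C must have the same shape")
        if self.W.shape != (len(self.unitigs), len(self.libraries)):
            raise ValueError("matrix shape does not match index lengths")
        if (self.W < 0).any() or (self.C < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.unitigs)) != len(self.unitigs):
            raise ValueError("duplicate unitig ids")
        if len(set(self.libraries)) != len(self.libraries):
            raise ValueError("duplicate library ids")
        self._urow = {u: i for i, u in enumerate(self.unitigs)}
        self._lcol = {l: j for j, l in enumerate(self.libraries)}

    @property
    def total(self) -> np.ndarray:
        return self.W + self.C

    def row(self, unitig: str) -> int:
        return self._urow[unitig]

    def subset(self, unitigs=None, libraries=None) -> "CountMatrix":
        """Restrict to the given unitigs/libraries (order preserved)."""
        uids = list(unitigs) if unitigs is not None else self.unitigs
        lids = list(libraries) if libraries is not None else self.libraries
        ri = [self._urow[u] for u in uids]
        cj = [self._lcol[l] for l in lids]
        return CountMatrix(uids, lids, self.W[np.ix_(ri, cj)], self.C[np.ix_(ri, cj)])

    def flip_unitigs(self, ids) -> "CountMatrix":
        """Swap W and C for the given unitigs (orientation flip)."""
        W, C = self.W.copy(), self.C.copy()
        rows = [self._urow[u] for u in ids if u in self._urow]
        W[rows], C[rows] = self.C[rows], self.W[rows]
        return CountMatrix(list(self.unitigs), list(self.libraries), W, C)


@dataclass
class SSFMatrix:
    """Strand state frequencies with a defined-mask.

    ``values[i, j]`` is (w - c)/(w + c) where w + c > 0, else 0 with
    ``defined[i, j] = False``. Masked cells contribute 0 to similarity
    vectors, keeping the vector algebra total.
    """

    unitigs: list[str]
    libraries: list[str]
    values: np.ndarray
    defined: np.ndarray
    source: str = "all_reads"
    _urow: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._urow = {u: i for i, u in enumerate(self.unitigs)}

    def vector(self, unitig: str) -> np.ndarray:
        return self.values[self._urow[unitig]]

    def vectors(self, unitig_ids) -> np.ndarray:
        return self.values[[self._urow[u] for u in unitig_ids]]


class StrandState(str, Enum):
    MATCHED = "MATCHED"
    UNMATCHED = "UNMATCHED"
    LOW_COVERAGE = "LOW_COVERAGE"

    def __str__(self) -> str:  # keeps numpy object-array comparisons sane
        return self.value


@dataclass
class StrandStateCalls:
    unitigs: list[str]
    libraries: list[str]
    calls: np.ndarray  # dtype object of StrandState


def read_count_table(path) -> CountMatrix:
    """Read a long-format TSV ``unitig  library  w  c`` into a CountMatrix.

    Absent (unitig, library) pairs become zero cells; duplicate rows are
    summed. Row/column order follows first appearance in the file.
    """
    df = pd.read_csv(path, sep="\t", dtype={"unitig": str, "library": str})
    expected = ["unitig", "library", "w", "c"]
    if list(df.columns[:4]) != expected:
        raise CountTableError(
            f"{path}: expected header {expected}, got {list(df.columns[:4])}"
        )
    if df.empty:
        return CountMatrix([], [], np.zeros((0, 0), dtype=np.int64), np.zeros((0, 0), dtype=np.int64))
    for col in ("w", "c"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[~df[col].astype(str).str.fullmatch(r"-?\d+")].index
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise CountTableError(f"{path}: non-integer count at line {line}")
        if (df[col] < 0).any():
            line = int(df.index[df[col] < 0][0]) + 2
            raise CountTableError(f"{path}: negative count at line {line}")
    unitigs = list(dict.fromkeys(df["unitig"]))
    libraries = list(dict.fromkeys(df["library"]))
    urow = {u: i for i, u in enumerate(unitigs)}
    lcol = {l: j for j, l in enumerate(libraries)}
    W = np.zeros((len(unitigs), len(libraries)), dtype=np.int64)
    C = np.zeros_like(W)
    ri = df["unitig"].map(urow).to_numpy()
    cj = df["library"].map(lcol).to_numpy()
    np.add.at(W, (ri, cj), df["w"].to_numpy(dtype=np.int64))
    np.add.at(C, (ri, cj), df["c"].to_numpy(dtype=np.int64))
    return CountMatrix(unitigs, libraries, W, C)


def write_count_table(counts: CountMatrix, path) -> None:
    """Write the long-format TSV (non-zero cells only)."""
    rows = []
    total = counts.total
    for i, u in enumerate(counts.unitigs):
        for j, l in enumerate(counts.libraries):
            if total[i, j] > 0:
                rows.append((u, l, int(counts.W[i, j]), int(counts.C[i, j])))
    pd.DataFrame(rows, columns=["unitig", "library", "w", "c"]).to_csv(
        path, sep="\t", index=False
    )


def strand_state_frequency(counts: CountMatrix, source: str = "all_reads") -> SSFMatrix:
    """Compute SSF = (w - c)/(w + c) per cell, masking zero-coverage cells."""
    total = counts.total.astype(float)
    defined = total > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(defined, (counts.W - counts.C) / np.where(defined, total, 1.0), 0.0)
    return SSFMatrix(
        list(counts.unitigs), list(counts.libraries), values, defined, source=source
    )


def call_strand_states(
    ssf: SSFMatrix,
    counts: CountMatrix,
    matched_abs_ssf: float = 0.6,
    min_reads: int = 10,
) -> StrandStateCalls:
    """Discretize the SSF into MATCHED / UNMATCHED / LOW_COVERAGE calls.

    A cell with fewer than ``min_reads`` total alignments is LOW_COVERAGE;
    otherwise |SSF| >= ``matched_abs_ssf`` calls MATCHED (WW/CC inherited),
    else UNMATCHED (WC/CW).
    """
    total = counts.total
    calls = np.empty(total.shape, dtype=object)
    calls.fill(StrandState.UNMATCHED)
    calls[np.abs(ssf.values) >= matched_abs_ssf] = StrandState.MATCHED
    calls[total < min_reads] = StrandState.LOW_COVERAGE
    return StrandStateCalls(list(counts.unitigs), list(counts.libraries), calls)


def library_qc(
    calls: StrandStateCalls,
    max_unmatched_frac: float = 0.8,
    min_informative_unitigs: int = 20,
) -> tuple[list[str], pd.DataFrame]:
    """Drop libraries that look like failed Strand-seq chemistry.

    Each unitig inherits matched and unmatched strand states in an expected
    50/50 ratio across libraries; a library where the unmatched fraction
    exceeds ``max_unmatched_frac`` (template-strand retention failed, both
    strands present everywhere) is discarded, as is a library with fewer than
    ``min_informative_unitigs`` callable (non-LOW_COVERAGE) unitigs.

    Returns surviving library ids and a per-library QC report.
    """
    rows = []
    retained = []
    for j, lib in enumerate(calls.libraries):
        col = calls.calls[:, j]
        n_matched = int(np.sum(col == StrandState.MATCHED))
        n_unmatched = int(np.sum(col == StrandState.UNMATCHED))
        n_low = int(np.sum(col == StrandState.LOW_COVERAGE))
        callable_ = n_matched + n_unmatched
        unmatched_frac = n_unmatched / callable_ if callable_ else 1.0
        ok = unmatched_frac <= max_unmatched_frac and callable_ >= min_informative_unitigs
        if ok:
            retained.append(lib)
        rows.append((lib, n_matched, n_unmatched, n_low, ok))
    report = pd.DataFrame(
        rows, columns=["library", "n_matched", "n_unmatched", "n_low", "retained"]
    )
    if not retained:
        raise RuntimeError(
            "library QC discarded every library:\n" + report.to_string(index=False)
        )
    return retained, report
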