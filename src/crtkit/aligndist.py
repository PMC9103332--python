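"""Pairwise alignment, percent identity, and Poisson-corrected distances.

Multiple alignments are consumed (aligned FASTA or Clustal), never computed;
pairwise global alignment is provided for identity reporting between
unaligned homologs.  Distances are amino-acid p-distances corrected for
multiple hits with the Poisson model, d = -ln(1 - p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from Bio import AlignIO, Align
from Bio.Align import substitution_matrices


class SaturationError(ValueError):
    """Raised when a p-distance of 1 makes the Poisson correction infinite."""


@dataclass
class Msa:
    """An aligned set of amino-acid sequences with gap symbol '-'."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        n = len(self.rows[0])
        if any(len(r) != n for r in self.rows):
            raise ValueError("aligned rows must have equal length")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def columns(self) -> list[str]:
        return ["".join(row[j] for row in self.rows) for j in range(self.n_columns)]

    def subsample_columns(self, indices) -> "Msa":
        rows = ["".join(row[j] for j in indices) for row in self.rows]
        return Msa(list(self.taxa), rows)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")

    def to_phylip(self) -> str:
        lines = [f"{len(self.taxa)}"]
        for name, row in zip(self.taxa, self.d):
            lines.append(name.ljust(12) + " ".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"

    def to_tsv(self) -> str:
        header = "\t" + "\t".join(self.taxa)
        lines = [header]
        for name, row in zip(self.taxa, self.d):
            lines.append(name + "\t" + "\t".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


def read_msa(path, fmt: Optional[str] = None) -> Msa:
    """Read an aligned FASTA or Clustal file (format sniffed by default)."""
    if fmt is None:
        with open(path) as fh:
            first = fh.readline()
        fmt = "clustal" if first.upper().startswith("CLUSTAL") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return Msa([r.id for r in aln], [str(r.seq) for r in aln])


# ---------------------------------------------------------------------------
# Pairwise alignment


def make_aligner(matrix: str = "BLOSUM62", gap_open: float = 10.0,
                 gap_extend: float = 0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    a: str, b: str, aligner: Optional[Align.PairwiseAligner] = None
) -> tuple[str, str, float]:
    """Optimal global (Needleman–Wunsch, affine-gap) alignment of two proteins.

    Returns the two gapped rows and the optimal score; among co-optimal
    alignments the aligner's first traceback is taken, which is deterministic
    for fixed inputs.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = aligner or make_aligner()
    try:
        alignment = aligner.align(a.upper(), b.upper())[0]
    except ValueError as exc:
        raise ValueError(f"unscorable residue in input: {exc}") from exc
    return str(alignment[0]), str(alignment[1]), float(alignment.score)


def percent_identity(row_a: str, row_b: str, denominator: str = "ungapped") -> float:
    """Percent identity of one aligned pair.

    ``denominator`` selects the convention: ``"ungapped"`` (default) counts
    only columns where neither row is gapped — published identity values are
    sensitive to this choice; ``"alignment"`` uses all columns;
    ``"shorter"`` uses the shorter ungapped sequence length.
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows differ in length")
    pairs = [(x, y) for x, y in zip(row_a, row_b)]
    ungapped = [(x, y) for x, y in pairs if x != "-" and y != "-"]
    matches = sum(1 for x, y in ungapped if x == y)
    if denominator == "ungapped":
        denom = len(ungapped)
    elif denominator == "alignment":
        denom = len(pairs)
    elif denominator == "shorter":
        denom = min(len(row_a.replace("-", "")), len(row_b.replace("-", "")))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError("no columns available for identity computation")
    return 100.0 * matches / denom


# ---------------------------------------------------------------------------
# Distances


def poisson_distance(p: float, cap: Optional[float] = None) -> float:
    """Poisson multiple-hit correction d = -ln(1 - p) of a p-distance.

    ``p`` is the proportion of differing sites.  ``p >= 1`` means saturation;
    by default that raises :class:`SaturationError`, or returns ``cap`` when
    one is supplied.
    """
    if p < 0:
        raise ValueError(f"p-distance must be >= 0, got {p}")
    if p >= 1:
        if cap is not None:
            return cap
        raise SaturationError(f"p-distance {p} >= 1: Poisson correction diverges")
    return -math.log(1.0 - p)


def p_distance_pair(row_a: str, row_b: str, gap_mode: str = "pairwise") -> float:
    """Proportion of differing sites over retained (ungapped) columns."""
    cols = [(x, y) for x, y in zip(row_a, row_b) if x != "-" and y != "-"]
    if not cols:
        raise ValueError("no retained columns for this pair")
    return sum(1 for x, y in cols if x != y) / len(cols)


def msa_to_distances(
    msa: Msa, gap_mode: str = "complete", cap: Optional[float] = None
) -> DistanceMatrix:
    """Poisson-corrected pairwise distance matrix from a multiple alignment.

    ``gap_mode="complete"`` (default) drops every column containing a gap in
    any row before counting differences; ``"pairwise"`` retains, per pair,
    the columns where neither member is gapped.
    """
    if gap_mode not in ("complete", "pairwise"):
        raise ValueError(f"gap_mode must be 'complete' or 'pairwise', got {gap_mode!r}")
    rows = msa.rows
    if gap_mode == "complete":
        keep = [j for j in range(msa.n_columns)
                if all(row[j] != "-" for row in rows)]
        if not keep:
            raise ValueError("complete deletion retained no columns")
        rows = ["".join(row[j] for j in keep) for row in rows]
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance_pair(rows[i], rows[j])
            d[i, j] = d[j, i] = poisson_distance(p, cap=cap)
    return DistanceMatrix(list(msa.taxa), d)
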