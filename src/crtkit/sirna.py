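"""Rule-based siRNA design against a target mRNA.

Every 19-nt window of the target is a candidate duplex core.  Candidates
are filtered on GC content, homopolymer tracts, contiguous off-target
homology against a transcript background, and miRNA seed collisions, then
rendered as sense/antisense duplexes with 3' dTdT overhangs.  A seeded,
composition-preserving scrambled control is generated and re-screened
against the whole background (target included).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")

CORE_LEN = 19
OVERHANG_DISPLAY = "[dT][dT]"
OVERHANG_PLAIN = "TT"


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


@dataclass
class TranscriptDb:
    """Off-target background: labeled transcripts with one designated target."""

    transcripts: dict[str, str]
    target_id: str

    def __post_init__(self) -> None:
        if self.target_id not in self.transcripts:
            raise ValueError(f"target {self.target_id!r} absent from database")
        self.transcripts = {k: to_dna(v) for k, v in self.transcripts.items()}

    @property
    def target(self) -> str:
        return self.transcripts[self.target_id]

    def decoys(self) -> dict[str, str]:
        return {k: v for k, v in self.transcripts.items() if k != self.target_id}


@dataclass
class MirnaSeedDb:
    """Mature miRNA sequences (RNA alphabet) for seed-collision screening."""

    mirnas: dict[str, str]

    def __post_init__(self) -> None:
        self.mirnas = {k: to_rna(v) for k, v in self.mirnas.items()}

    @classmethod
    def from_tsv(cls, path) -> "MirnaSeedDb":
        mirnas = {}
        with open(path) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                mirnas[row[0]] = row[1]
        return cls(mirnas)


@dataclass
class FilterOutcome:
    name: str
    passed: bool
    detail: dict = field(default_factory=dict)


@dataclass
class SirnaCandidate:
    """One 19-nt duplex core at a given 1-based position on the target mRNA."""

    target_start: int
    core_sense: str  # RNA, 5'->3'
    core_antisense: str = ""
    filter_results: dict[str, FilterOutcome] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.core_sense = to_rna(self.core_sense)
        if len(self.core_sense) != CORE_LEN:
            raise ValueError(f"core must be {CORE_LEN} nt")
        self.core_antisense = revcomp_rna(self.core_sense)

    @property
    def duplex_sense(self) -> str:
        return self.core_sense + OVERHANG_DISPLAY

    @property
    def duplex_antisense(self) -> str:
        return self.core_antisense + OVERHANG_DISPLAY

    @property
    def seed(self) -> str:
        """Guide (antisense) strand nucleotides 2-8."""
        return self.core_antisense[1:8]

    @property
    def passed_all(self) -> bool:
        return all(o.passed for o in self.filter_results.values())

    def gc_percent(self) -> float:
        gc = sum(1 for b in self.core_sense if b in "GC")
        return 100.0 * gc / CORE_LEN


def enumerate_candidates(target_mrna: str) -> list[SirnaCandidate]:
    """All 19-nt windows of the target, 5'->3'."""
    rna = to_rna(target_mrna)
    if len(rna) < CORE_LEN:
        raise ValueError(f"target shorter than {CORE_LEN} nt")
    return [SirnaCandidate(i + 1, rna[i : i + CORE_LEN])
            for i in range(len(rna) - CORE_LEN + 1)]


# ---------------------------------------------------------------------------
# Filters


def gc_filter(c: SirnaCandidate, max_gc: float = 38.0,
              window: str = "core") -> FilterOutcome:
    """Pass iff GC% of the chosen window (core or dTdT-extended duplex) is
    <= ``max_gc`` (boundary inclusive)."""
    if window == "core":
        seq, n = c.core_sense, CORE_LEN
    elif window == "duplex":
        seq, n = c.core_sense + OVERHANG_PLAIN, CORE_LEN + 2
    else:
        raise ValueError(f"window must be 'core' or 'duplex', got {window!r}")
    gc = 100.0 * sum(1 for b in seq if b in "GC") / n
    out = FilterOutcome("gc", gc <= max_gc,
                        {"gc_percent": round(gc, 1), "window": window})
    c.filter_results["gc"] = out
    return out


def longest_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0


def homopolymer_filter(c: SirnaCandidate, max_run: int = 4) -> FilterOutcome:
    """Pass iff the longest single-nucleotide tract in the core is <= max_run."""
    run = longest_run(c.core_sense)
    out = FilterOutcome("homopolymer", run <= max_run, {"max_run": run})
    c.filter_results["homopolymer"] = out
    return out


def longest_shared_block(query: str, subject: str) -> int:
    """Length of the longest exact contiguous match of ``query`` (either
    strand) within ``subject``; both sequences in DNA alphabet."""
    q = to_dna(query)
    s = to_dna(subject)
    for k in range(len(q), 0, -1):
        for i in range(len(q) - k + 1):
            block = q[i : i + k]
            if block in s or revcomp_dna(block) in s:
                return k
    return 0


def offtarget_screen(c: SirnaCandidate, db: TranscriptDb,
                     min_block: int = 15) -> FilterOutcome:
    """Fail iff any non-target transcript shares a contiguous exact block of
    >= ``min_block`` nt with the candidate core (either strand)."""
    decoys = db.decoys()
    best_len, best_tx = 0, None
    core_dna = to_dna(c.core_sense)
    for label, seq in decoys.items():
        k = longest_shared_block(core_dna, seq)
        if k > best_len:
            best_len, best_tx = k, label
    out = FilterOutcome(
        "offtarget", best_len < min_block,
        {"max_match_len": best_len, "transcript": best_tx},
    )
    c.filter_results["offtarget"] = out
    return out


def seed_screen(c: SirnaCandidate, mirnas: MirnaSeedDb) -> FilterOutcome:
    """Fail iff the guide seed (positions 2-8) equals positions 2-8 of any
    listed mature miRNA."""
    collisions = [name for name, seq in mirnas.mirnas.items()
                  if len(seq) >= 8 and seq[1:8] == c.seed]
    out = FilterOutcome("seed", not collisions, {"collisions": collisions})
    c.filter_results["seed"] = out
    return out


# ---------------------------------------------------------------------------
# Design cascade


@dataclass
class DesignParams:
    max_gc: float = 38.0
    gc_window: str = "core"
    max_run: int = 4
    min_block: int = 15


@dataclass
class DesignReport:
    candidates: list[SirnaCandidate]
    survivors: list[SirnaCandidate]
    attrition: dict[str, int]

    def to_tsv(self) -> str:
        lines = ["start\tcore_sense\tcore_antisense\tgc_percent\tpassed\t"
                 "failed_filters"]
        for c in self.candidates:
            failed = ",".join(n for n, o in c.filter_results.items()
                              if not o.passed)
            lines.append(
                f"{c.target_start}\t{c.core_sense}\t{c.core_antisense}\t"
                f"{c.gc_percent():.1f}\t{c.passed_all}\t{failed or '.'}"
            )
        return "\n".join(lines) + "\n"


FILTER_ORDER = ("gc", "homopolymer", "seed", "offtarget")


def design(
    db: TranscriptDb,
    mirnas: Optional[MirnaSeedDb] = None,
    params: Optional[DesignParams] = None,
    top_k: Optional[int] = None,
) -> DesignReport:
    """Run the full filter cascade over every candidate on the target.

    All filters are evaluated for every candidate (their conjunction is
    order-independent); attrition attributes each failure to the first
    failing filter in cheap-to-expensive order (GC, homopolymer, seed,
    off-target).  Survivors are ranked by ascending GC% then 5' position.
    """
    params = params or DesignParams()
    mirnas = mirnas or MirnaSeedDb({})
    candidates = enumerate_candidates(db.target)
    attrition = {name: 0 for name in FILTER_ORDER}
    attrition["survivors"] = 0
    for c in candidates:
        gc_filter(c, max_gc=params.max_gc, window=params.gc_window)
        homopolymer_filter(c, max_run=params.max_run)
        seed_screen(c, mirnas)
        offtarget_screen(c, db, min_block=params.min_block)
        for name in FILTER_ORDER:
            if not c.filter_results[name].passed:
                attrition[name] += 1
                break
        else:
            attrition["survivors"] += 1
    survivors = sorted(
        (c for c in candidates if c.passed_all),
        key=lambda c: (c.gc_percent(), c.target_start),
    )
    if top_k is not None:
        survivors = survivors[:top_k]
    return DesignReport(candidates, survivors, attrition)


def scramble_control(
    c: SirnaCandidate,
    seed: int,
    db: TranscriptDb,
    max_attempts: int = 1000,
    min_block: int = 15,
) -> SirnaCandidate:
    """Seeded composition-preserving scramble of the core, re-screened so it
    shares no contiguous block of >= ``min_block`` nt with ANY transcript in
    the database (target included).  Deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    letters = list(c.core_sense)
    for _ in range(max_attempts):
        perm = rng.permutation(len(letters))
        scrambled = "".join(letters[i] for i in perm)
        if scrambled == c.core_sense:
            continue
        sdna = to_dna(scrambled)
        worst = max(
            (longest_shared_block(sdna, seq) for seq in db.transcripts.values()),
            default=0,
        )
        if worst < min_block:
            control = SirnaCandidate(c.target_start, scrambled)
            control.filter_results["scramble_screen"] = FilterOutcome(
                "scramble_screen", True, {"max_match_len": worst}
            )
            return control
    raise RuntimeError(
        f"no acceptable scramble found in {max_attempts} attempts"
    )
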