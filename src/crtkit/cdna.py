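"""cDNA anatomy: ORF finding, UTR segmentation, poly(A) signal and tail mapping.

Coordinates are 1-based inclusive throughout the public API, the convention
used in sequence-feature reports (GenBank/GFF3 style).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
POLYA_HEXAMER = "AATAAA"

_DNA_RE = re.compile(r"^[ACGT]+$")


class NoOrfError(ValueError):
    """Raised when a sequence contains no complete ATG-initiated ORF."""


@dataclass(frozen=True)
class Interval:
    """1-based inclusive interval on a sequence."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def slice(self, sequence: str) -> str:
        return sequence[self.start - 1 : self.end]


@dataclass(frozen=True)
class CdnaRecord:
    """A single cDNA/mRNA sequence; U is normalized to T on construction."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        if not seq:
            raise ValueError(f"{self.id}: empty sequence")
        if not _DNA_RE.match(seq):
            bad = sorted(set(seq) - set("ACGT"))
            raise ValueError(f"{self.id}: non-ACGT characters {bad}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CdnaAnnotation:
    """5'UTR / ORF / 3'UTR / poly(A) decomposition of one cDNA."""

    record_id: str
    utr5: Optional[Interval]
    orf: Interval
    utr3: Optional[Interval]
    polya_tail: Optional[Interval] = None
    polya_signal: Optional[Interval] = None
    signal_to_tail_bp: Optional[int] = None
    length: int = 0
    notes: list[str] = field(default_factory=list)


def find_orf(cdna: CdnaRecord) -> Interval:
    """Longest ATG-initiated ORF closed by an in-frame stop, stop included.

    Ties on length are broken toward the most 5' start.  Raises
    :class:`NoOrfError` when no start codon is closed by a stop.
    """
    seq = cdna.sequence
    if len(seq) < 6:
        raise NoOrfError(f"{cdna.id}: sequence shorter than one codon pair")
    best: Optional[Interval] = None
    for m in re.finditer("ATG", seq):
        start = m.start()
        for pos in range(start + 3, len(seq) - 2, 3):
            if seq[pos : pos + 3] in STOP_CODONS:
                candidate = Interval(start + 1, pos + 3)
                if best is None or len(candidate) > len(best):
                    best = candidate
                break
    if best is None:
        raise NoOrfError(f"{cdna.id}: no ATG-initiated complete ORF found")
    return best


def _terminal_a_run(seq: str) -> int:
    n = 0
    for ch in reversed(seq):
        if ch != "A":
            break
        n += 1
    return n


def segment_cdna(cdna: CdnaRecord, tail_min: int = 10) -> CdnaAnnotation:
    """Tile the cDNA into 5'UTR + ORF + 3'UTR (+ optional poly(A) tail).

    The poly(A) tail is the maximal terminal run of A when it reaches
    ``tail_min`` nucleotides; the 3'UTR excludes it.  The poly(A) signal is
    mapped afterwards by :func:`map_polya_signal`.
    """
    orf = find_orf(cdna)
    seq = cdna.sequence
    run = _terminal_a_run(seq)
    tail = Interval(len(seq) - run + 1, len(seq)) if run >= tail_min else None
    utr3_end = (tail.start - 1) if tail else len(seq)
    ann = CdnaAnnotation(
        record_id=cdna.id,
        utr5=Interval(1, orf.start - 1) if orf.start > 1 else None,
        orf=orf,
        utr3=Interval(orf.end + 1, utr3_end) if utr3_end > orf.end else None,
        polya_tail=tail,
        length=len(seq),
    )
    map_polya_signal(ann, cdna)
    return ann


def map_polya_signal(
    annotation: CdnaAnnotation, cdna: CdnaRecord, anchor: str = "end"
) -> tuple[Optional[Interval], Optional[int]]:
    """Locate the 3'-most AATAAA in the 3'UTR and its distance to the tail.

    ``anchor`` selects the offset convention: ``"end"`` (default) counts the
    nucleotides strictly between the hexamer's last base and the tail's first
    base; ``"start"`` counts from the hexamer's first base.  Absence of the
    hexamer (or of a 3'UTR) is a valid result, not an error.
    """
    if anchor not in ("end", "start"):
        raise ValueError(f"anchor must be 'end' or 'start', got {anchor!r}")
    annotation.polya_signal = None
    annotation.signal_to_tail_bp = None
    utr3 = annotation.utr3
    if utr3 is None:
        return None, None
    region = utr3.slice(cdna.sequence)
    hit = region.rfind(POLYA_HEXAMER)
    if hit < 0:
        return None, None
    signal = Interval(utr3.start + hit, utr3.start + hit + len(POLYA_HEXAMER) - 1)
    offset = None
    if annotation.polya_tail is not None:
        ref = signal.end if anchor == "end" else signal.start
        offset = annotation.polya_tail.start - ref - 1
    annotation.polya_signal = signal
    annotation.signal_to_tail_bp = offset
    return signal, offset


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path) -> list[CdnaRecord]:
    records = [CdnaRecord(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def _fmt(iv: Optional[Interval]) -> str:
    return f"{iv.start}\t{iv.end}" if iv else ".\t."


def annotation_to_tsv_rows(ann: CdnaAnnotation) -> str:
    """One TSV line per annotated feature (1-based inclusive coordinates)."""
    lines = []
    for name, iv in [
        ("five_prime_UTR", ann.utr5),
        ("ORF", ann.orf),
        ("three_prime_UTR", ann.utr3),
        ("polyA_signal", ann.polya_signal),
        ("polyA_tail", ann.polya_tail),
    ]:
        lines.append(f"{ann.record_id}\t{name}\t{_fmt(iv)}")
    off = ann.signal_to_tail_bp if ann.signal_to_tail_bp is not None else "."
    lines.append(f"{ann.record_id}\tsignal_to_tail_bp\t{off}\t.")
    return "\n".join(lines)


def annotation_to_gff3(ann: CdnaAnnotation) -> str:
    """GFF3-style feature rows for one annotation."""
    rows = []
    for ftype, iv in [
        ("five_prime_UTR", ann.utr5),
        ("CDS", ann.orf),
        ("three_prime_UTR", ann.utr3),
        ("polyA_signal_sequence", ann.polya_signal),
        ("polyA_site", ann.polya_tail),
    ]:
        if iv is None:
            continue
        rows.append(
            f"{ann.record_id}\tcrtkit\t{ftype}\t{iv.start}\t{iv.end}\t.\t+\t.\t"
            f"ID={ann.record_id}.{ftype}"
        )
    return "\n".join(rows)


def annotate_fasta(path, tail_min: int = 10) -> Iterable[CdnaAnnotation]:
    for rec in read_fasta(path):
        yield segment_cdna(rec, tail_min=tail_min)
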