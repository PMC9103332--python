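"""Protein-level annotation of calreticulin-diagnostic features.

Covers in-silico translation, average molecular mass, isoelectric point
(Henderson–Hasselbalch with the Bjellqvist pKa set, as used by ExPASy's
Compute pI/Mw), N-glycosylation sequons, the degenerate proline-rich M1/M2
repeats of the CRT P-domain, the C-terminal HDEL ER-retention signal,
cysteine positions, and per-domain acidic-residue fractions.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import yaml
from Bio.Seq import Seq

from .cdna import Interval

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# ExPASy average residue masses (Da); a peptide adds one water.
WATER_DA = 18.0153
RESIDUE_MASS_DA = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

# Bjellqvist pKa values (the ExPASy Compute pI/Mw set), including the
# residue-specific terminal corrections.
BJELLQVIST = {
    "positive": {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98},
    "negative": {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
    "nterm_by_residue": {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36,
                         "T": 6.82, "V": 7.44, "E": 7.7},
    "cterm_by_residue": {"D": 4.55, "E": 4.75},
}

# EMBOSS iep defaults, selectable via pka_set="emboss".
EMBOSS = {
    "positive": {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5},
    "negative": {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
    "nterm_by_residue": {},
    "cterm_by_residue": {},
}

PKA_SETS = {"bjellqvist": BJELLQVIST, "emboss": EMBOSS}


class TranslationError(ValueError):
    """Raised for ORFs that violate the single-ORF translation contract."""


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"{self.id}: empty protein sequence")
        bad = sorted(set(seq) - set(AMINO_ACIDS))
        if bad:
            raise ValueError(f"{self.id}: non-standard residues {bad}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    interval: Interval
    matched_text: str


@dataclass(frozen=True)
class DomainPartition:
    """Contiguous N / P / C domain decomposition of the mature sequence."""

    n_domain: Interval
    p_domain: Interval
    c_domain: Interval

    def __post_init__(self) -> None:
        if not (self.n_domain.end + 1 == self.p_domain.start
                and self.p_domain.end + 1 == self.c_domain.start):
            raise ValueError("domains must be contiguous and ordered N, P, C")


@dataclass
class FeatureReport:
    record_id: str
    length: int
    mass_da: float
    pi: float
    sequons: list[MotifHit]
    m1_hits: list[MotifHit]
    m2_hits: list[MotifHit]
    hdel_present: bool
    c_terminal_tetrapeptide: str
    cysteine_positions: list[int]
    acidic_fraction_p: Optional[float] = None
    acidic_fraction_c: Optional[float] = None
    domains: Optional[DomainPartition] = None
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        def hit(h: MotifHit) -> dict:
            return {"motif": h.motif_name, "start": h.interval.start,
                    "end": h.interval.end, "match": h.matched_text}

        payload = {
            "id": self.record_id,
            "length_aa": self.length,
            "mass_da": round(self.mass_da, 2),
            "mass_kda": round(self.mass_da / 1000.0, 1),
            "pi": round(self.pi, 2),
            "sequons": [hit(h) for h in self.sequons],
            "m1_hits": [hit(h) for h in self.m1_hits],
            "m2_hits": [hit(h) for h in self.m2_hits],
            "hdel_present": self.hdel_present,
            "c_terminal_tetrapeptide": self.c_terminal_tetrapeptide,
            "cysteine_positions": self.cysteine_positions,
            "acidic_fraction_p": self.acidic_fraction_p,
            "acidic_fraction_c": self.acidic_fraction_c,
            "domains": None if self.domains is None else {
                "N": [self.domains.n_domain.start, self.domains.n_domain.end],
                "P": [self.domains.p_domain.start, self.domains.p_domain.end],
                "C": [self.domains.c_domain.start, self.domains.c_domain.end],
            },
            "notes": self.notes,
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# Translation


def translate(orf_nt: str, record_id: str = "orf") -> ProteinRecord:
    """Translate a complete ORF (ATG .. stop) with the standard genetic code.

    The terminal stop is required and excluded from the product; an internal
    stop raises :class:`TranslationError` naming the offending codon.
    """
    seq = orf_nt.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise TranslationError(f"{record_id}: length {len(seq)} not divisible by 3")
    if not seq.startswith("ATG"):
        raise TranslationError(f"{record_id}: ORF must start with ATG")
    aa = str(Seq(seq).translate())
    if not aa.endswith("*"):
        raise TranslationError(f"{record_id}: ORF lacks a terminal stop codon")
    body = aa[:-1]
    if "*" in body:
        codon_idx = body.index("*") + 1  # 1-based codon number
        raise TranslationError(
            f"{record_id}: internal stop codon at codon {codon_idx} "
            f"(nt {3 * codon_idx - 2}-{3 * codon_idx})"
        )
    return ProteinRecord(record_id, body)


# ---------------------------------------------------------------------------
# Physicochemistry


def compute_mass(p: ProteinRecord) -> float:
    """Average molecular mass in Da (sum of residue masses plus one water)."""
    return sum(RESIDUE_MASS_DA[r] for r in p.sequence) + WATER_DA


def net_charge(sequence: str, ph: float, pka_set: str = "bjellqvist") -> float:
    """Henderson–Hasselbalch net charge of a peptide at the given pH."""
    pk = PKA_SETS[pka_set]
    counts: dict[str, int] = {}
    for r in sequence:
        counts[r] = counts.get(r, 0) + 1

    def pos(pka: float, n: float = 1.0) -> float:
        return n / (1.0 + 10.0 ** (ph - pka))

    def neg(pka: float, n: float = 1.0) -> float:
        return -n / (1.0 + 10.0 ** (pka - ph))

    nterm_pka = pk["nterm_by_residue"].get(sequence[0], pk["positive"]["Nterm"])
    cterm_pka = pk["cterm_by_residue"].get(sequence[-1], pk["negative"]["Cterm"])
    charge = pos(nterm_pka) + neg(cterm_pka)
    for res, pka in pk["positive"].items():
        if res != "Nterm" and res in counts:
            charge += pos(pka, counts[res])
    for res, pka in pk["negative"].items():
        if res != "Cterm" and res in counts:
            charge += neg(pka, counts[res])
    return charge


def compute_pi(p: ProteinRecord, pka_set: str = "bjellqvist",
               tol: float = 1e-4) -> float:
    """Isoelectric point: the pH where the net charge crosses zero.

    The charge is strictly decreasing in pH, so bisection on [0, 14] finds
    the unique root; iteration stops at ``|charge| < tol``.
    """
    lo, hi = 0.0, 14.0
    ph = 7.0
    for _ in range(200):
        ph = (lo + hi) / 2.0
        q = net_charge(p.sequence, ph, pka_set)
        if abs(q) < tol:
            return ph
        if q > 0:
            lo = ph
        else:
            hi = ph
    return ph


# ---------------------------------------------------------------------------
# Motif scanning

_GROUP_RE = re.compile(r"\(([A-Z](?:/[A-Z])+)\)|([A-Z])")


def parse_pattern(pattern: str) -> list[Optional[frozenset[str]]]:
    """Parse a degenerate pattern into per-position residue sets.

    A literal matches itself, ``X`` matches anything (``None`` entry),
    ``(A/B)`` matches either listed residue.
    """
    tokens: list[Optional[frozenset[str]]] = []
    pos = 0
    for m in _GROUP_RE.finditer(pattern):
        if m.start() != pos:
            raise ValueError(f"unparseable pattern at {pattern[pos:]!r}")
        pos = m.end()
        if m.group(1):
            tokens.append(frozenset(m.group(1).split("/")))
        else:
            ch = m.group(2)
            tokens.append(None if ch == "X" else frozenset(ch))
    if pos != len(pattern):
        raise ValueError(f"unparseable pattern at {pattern[pos:]!r}")
    return tokens


def scan_motif(p: ProteinRecord, name: str, pattern: str) -> list[MotifHit]:
    """All (possibly overlapping) matches of a degenerate pattern, in order."""
    tokens = parse_pattern(pattern)
    k = len(tokens)
    seq = p.sequence
    hits = []
    for i in range(len(seq) - k + 1):
        if all(t is None or seq[i + j] in t for j, t in enumerate(tokens)):
            hits.append(MotifHit(name, Interval(i + 1, i + k), seq[i : i + k]))
    return hits


def load_motif_patterns(path=None) -> dict[str, str]:
    """Motif name → pattern, from the packaged YAML or a user file."""
    if path is None:
        text = (resources.files("crtkit") / "data" / "motifs.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    return {name: spec["pattern"] for name, spec in cfg["motifs"].items()}


def scan_crt_repeats(
    p: ProteinRecord, patterns: Optional[dict[str, str]] = None
) -> tuple[list[MotifHit], list[MotifHit]]:
    """M1 and M2 proline-rich repeat hits (position-wise degenerate match)."""
    patterns = patterns or load_motif_patterns()
    return scan_motif(p, "M1", patterns["M1"]), scan_motif(p, "M2", patterns["M2"])


def scan_sequons(p: ProteinRecord) -> list[MotifHit]:
    """N-glycosylation sequons N-X-[S/T] with X != P.

    The hit interval spans the 3-residue sequon; ``matched_text`` carries a
    fourth context residue when one exists (the NKTL-style 4-mer convention).
    """
    seq = p.sequence
    hits = []
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST":
            context = seq[i : i + 4] if i + 3 < len(seq) else seq[i : i + 3]
            hits.append(MotifHit("sequon", Interval(i + 1, i + 3), context))
    return hits


def check_er_retention(p: ProteinRecord) -> tuple[bool, str]:
    """True iff the final four residues are exactly HDEL.

    Returns the terminal tetrapeptide alongside the flag so a KDEL terminus
    (the animal-type signal) can be reported informationally.
    """
    if len(p) < 4:
        return False, p.sequence
    tail = p.sequence[-4:]
    return tail == "HDEL", tail


def cysteine_positions(p: ProteinRecord) -> list[int]:
    return [i + 1 for i, r in enumerate(p.sequence) if r == "C"]


def acidic_fraction(p: ProteinRecord, domain: Interval) -> float:
    """Percent of D+E residues within a domain interval (1-based inclusive)."""
    if domain.end > len(p):
        raise ValueError(f"domain {domain.start}-{domain.end} outside sequence")
    segment = domain.slice(p.sequence)
    if not segment:
        raise ValueError("empty domain interval")
    return 100.0 * sum(1 for r in segment if r in "DE") / len(segment)


def infer_domains(
    p: ProteinRecord,
    m1_hits: Sequence[MotifHit],
    m2_hits: Sequence[MotifHit],
) -> DomainPartition:
    """Heuristic N/P/C partition: P spans the M1/M2 repeat region.

    P runs from the first M1 hit start to the last M2 hit end; N precedes it
    and C follows.  Calreticulin domain boundaries are commonly reported from
    annotated figures, so an explicit :class:`DomainPartition` should be
    supplied when exact bounds are known.
    """
    if not m1_hits or not m2_hits:
        raise ValueError("cannot infer domains without both M1 and M2 hits")
    p_start = min(h.interval.start for h in m1_hits)
    p_end = max(h.interval.end for h in m2_hits)
    if p_start < 2 or p_end >= len(p):
        raise ValueError("repeat region leaves no room for N or C domain")
    return DomainPartition(
        Interval(1, p_start - 1), Interval(p_start, p_end), Interval(p_end + 1, len(p))
    )


def build_feature_report(
    p: ProteinRecord,
    domains: Optional[DomainPartition] = None,
    patterns: Optional[dict[str, str]] = None,
    pka_set: str = "bjellqvist",
) -> FeatureReport:
    """Full calreticulin feature annotation of one protein."""
    m1, m2 = scan_crt_repeats(p, patterns)
    hdel, tail = check_er_retention(p)
    notes = []
    if not hdel and tail == "KDEL":
        notes.append("terminal KDEL (animal-type ER-retention signal), not HDEL")
    if domains is None and m1 and m2:
        try:
            domains = infer_domains(p, m1, m2)
            notes.append("N/P/C domains inferred from M1/M2 repeat span")
        except ValueError:
            domains = None
    report = FeatureReport(
        record_id=p.id,
        length=len(p),
        mass_da=compute_mass(p),
        pi=compute_pi(p, pka_set=pka_set),
        sequons=scan_sequons(p),
        m1_hits=m1,
        m2_hits=m2,
        hdel_present=hdel,
        c_terminal_tetrapeptide=tail,
        cysteine_positions=cysteine_positions(p),
        domains=domains,
        notes=notes,
    )
    if domains is not None:
        report.acidic_fraction_p = round(acidic_fraction(p, domains.p_domain), 1)
        report.acidic_fraction_c = round(acidic_fraction(p, domains.c_domain), 1)
    return report
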