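"""Seeded synthetic-data generators with attached ground truth.

Each generator is a pure function of its parameters and seed and returns,
alongside the dataset, a ground-truth object sufficient to score the
corresponding pipeline stage without human input:

* :func:`make_cdna` — a cDNA with planted 5'UTR/ORF/3'UTR geometry, AATAAA
  signal, poly(A) tail, and planted protein motifs (sequon, M1/M2 repeats,
  HDEL).  Defaults reproduce the anatomy of the full-length PhCRT3a cDNA
  (19 nt 5'UTR, 431-codon ORF ending in TGA, 320 nt 3'UTR, AATAAA 24 nt
  upstream of the tail, 1652 bp total).
* :func:`evolve_family` — a gap-free homolog family evolved along a known
  tree by a Poisson substitution process (uniform 20-state exchange).
* :func:`make_transcriptome` — decoy transcripts with exact-copy off-target
  blocks of the target planted at recorded positions.
* :func:`make_intensity_table` — two-group intensity tables with a known
  knockdown effect and log-normal multiplicative noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cdna import CdnaRecord, Interval, segment_cdna
from .phylo import Node, Tree, to_newick
from .protein import (
    AMINO_ACIDS,
    check_er_retention,
    load_motif_patterns,
    parse_pattern,
    scan_crt_repeats,
    scan_sequons,
    translate,
)
from .aligndist import Msa

_STOPS = ("TAA", "TAG", "TGA")

# Codons per residue (standard code), for seeded reverse translation.
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"], "D": ["GAT", "GAC"], "C": ["TGT", "TGC"],
    "E": ["GAA", "GAG"], "Q": ["CAA", "CAG"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "K": ["AAA", "AAG"], "M": ["ATG"], "F": ["TTT", "TTC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "W": ["TGG"],
    "Y": ["TAT", "TAC"], "V": ["GTT", "GTC", "GTA", "GTG"],
}

# Background residues exclude N so the only N-X-[S/T] sequon is the planted
# one; motif X-positions draw from the same restricted alphabet.
_BACKGROUND_AA = AMINO_ACIDS.replace("N", "")


@dataclass
class CdnaGroundTruth:
    """Planted coordinates and protein-level features of one synthetic cDNA."""

    utr5: Optional[Interval]
    orf: Interval
    utr3: Optional[Interval]
    polya_tail: Optional[Interval]
    polya_signal: Optional[Interval]
    signal_to_tail_bp: Optional[int]
    protein: str
    m1_starts: list[int]
    m2_starts: list[int]
    sequon_start: Optional[int]
    hdel: bool
    seed: int

    def to_json(self) -> str:
        def iv(x):
            return None if x is None else [x.start, x.end]

        return json.dumps({
            "utr5": iv(self.utr5), "orf": iv(self.orf), "utr3": iv(self.utr3),
            "polya_tail": iv(self.polya_tail),
            "polya_signal": iv(self.polya_signal),
            "signal_to_tail_bp": self.signal_to_tail_bp,
            "protein": self.protein,
            "m1_starts": self.m1_starts, "m2_starts": self.m2_starts,
            "sequon_start": self.sequon_start, "hdel": self.hdel,
            "seed": self.seed,
        }, indent=2)


def _instantiate_motif(pattern_tokens, rng: np.random.Generator) -> str:
    out = []
    for tok in pattern_tokens:
        if tok is None:
            out.append(_BACKGROUND_AA[rng.integers(0, len(_BACKGROUND_AA))])
        else:
            choices = sorted(tok)
            out.append(choices[rng.integers(0, len(choices))])
    return "".join(out)


def _random_protein(length: int, rng: np.random.Generator) -> list[str]:
    idx = rng.integers(0, len(_BACKGROUND_AA), size=length)
    return [_BACKGROUND_AA[i] for i in idx]


def _build_protein(
    orf_aa: int, n_m1: int, n_m2: int, plant_sequon: bool, sequon_pos: int,
    plant_hdel: bool, rng: np.random.Generator,
) -> tuple[str, list[int], list[int], Optional[int]]:
    patterns = load_motif_patterns()
    m1_tokens = parse_pattern(patterns["M1"])
    m2_tokens = parse_pattern(patterns["M2"])
    residues = _random_protein(orf_aa, rng)
    residues[0] = "M"
    reserved: set[int] = {1}
    sequon_start = None
    if plant_sequon:
        if sequon_pos < 2 or sequon_pos + 3 > orf_aa - (4 if plant_hdel else 0):
            raise ValueError("sequon does not fit in the ORF")
        for off, res in enumerate("NKTL"):
            residues[sequon_pos - 1 + off] = res
        reserved.update(range(sequon_pos, sequon_pos + 4))
        sequon_start = sequon_pos
    if plant_hdel:
        for off, res in enumerate("HDEL"):
            residues[orf_aa - 4 + off] = res
        reserved.update(range(orf_aa - 3, orf_aa + 1))

    # Lay the repeats out sequentially (all M1, then all M2) after the
    # sequon, mirroring the N -> P(-repeat) -> C domain order.
    blocks = [("M1", m1_tokens)] * n_m1 + [("M2", m2_tokens)] * n_m2
    cursor = (sequon_pos + 5) if plant_sequon else max(2, orf_aa // 4)
    last_ok = orf_aa - (4 if plant_hdel else 0)
    m1_starts, m2_starts = [], []
    for name, tokens in blocks:
        cursor += int(rng.integers(2, 9))  # spacer between repeats
        end = cursor + len(tokens) - 1
        if end > last_ok:
            raise ValueError(
                f"cannot pack {n_m1} M1 + {n_m2} M2 repeats into {orf_aa} aa"
            )
        text = _instantiate_motif(tokens, rng)
        for off, res in enumerate(text):
            residues[cursor - 1 + off] = res
        (m1_starts if name == "M1" else m2_starts).append(cursor)
        cursor = end + 1
    return "".join(residues), m1_starts, m2_starts, sequon_start


def _reverse_translate(protein: str, stop_codon: str,
                       rng: np.random.Generator) -> str:
    codons = []
    for res in protein:
        options = _CODONS[res]
        codons.append(options[rng.integers(0, len(options))])
    return "".join(codons) + stop_codon


def _random_nt(length: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _draw_utr5(length: int, rng: np.random.Generator) -> str:
    for _ in range(200):
        utr = _random_nt(length, rng)
        if "ATG" not in utr:
            return utr
    raise RuntimeError("could not draw an ATG-free 5'UTR")


def _draw_utr3(length: int, polya_offset: Optional[int], tail_len: int,
               rng: np.random.Generator) -> str:
    plant = polya_offset is not None and tail_len > 0
    if plant and (polya_offset < 1 or length < polya_offset + 6):
        raise ValueError("3'UTR too short for the requested signal offset")
    for _ in range(500):
        utr = list(_random_nt(length, rng))
        if plant:
            start = length - polya_offset - 6  # 0-based within UTR
            utr[start : start + 6] = "AATAAA"
        seq = "".join(utr)
        if tail_len > 0 and seq.endswith("A"):
            continue
        if seq.count("AATAAA") != (1 if plant else 0):
            continue
        return seq
    raise RuntimeError("could not draw a 3'UTR meeting the signal constraints")


def make_cdna(
    utr5_len: int = 19,
    orf_aa: int = 431,
    utr3_len: int = 320,
    tail_len: int = 17,
    n_m1: int = 3,
    n_m2: int = 3,
    plant_sequon: bool = True,
    sequon_pos: int = 107,
    plant_hdel: bool = True,
    polya_offset: Optional[int] = 24,
    stop_codon: str = "TGA",
    seed: int = 0,
) -> tuple[CdnaRecord, CdnaGroundTruth]:
    """Synthetic cDNA whose annotation recovers the planted ground truth.

    ``orf_aa`` counts encoded residues, so the ORF spans ``3 * (orf_aa + 1)``
    nt including the stop codon.  The defaults reproduce the PhCRT3a-style
    geometry (19 + 1296 + 320 + 17 = 1652 bp).  The generated record is
    verified by round-trip annotation before being returned; construction
    raises on infeasible packings.
    """
    if utr5_len < 0 or utr3_len < 0 or orf_aa < 2:
        raise ValueError("invalid lengths")
    if 0 < tail_len < 10:
        raise ValueError("tail_len must be 0 (no tail) or >= 10 (detectable)")
    if stop_codon not in _STOPS:
        raise ValueError(f"stop_codon must be one of {_STOPS}")
    rng = np.random.default_rng(seed)
    for _attempt in range(20):
        protein, m1_starts, m2_starts, sequon_start = _build_protein(
            orf_aa, n_m1, n_m2, plant_sequon, sequon_pos, plant_hdel, rng
        )
        orf_nt = _reverse_translate(protein, stop_codon, rng)
        utr5 = _draw_utr5(utr5_len, rng) if utr5_len else ""
        utr3 = _draw_utr3(utr3_len, polya_offset, tail_len, rng) if utr3_len else ""
        seq = utr5 + orf_nt + utr3 + "A" * tail_len
        record = CdnaRecord(f"synthetic_cdna_seed{seed}", seq)

        orf_iv = Interval(utr5_len + 1, utr5_len + len(orf_nt))
        truth = CdnaGroundTruth(
            utr5=Interval(1, utr5_len) if utr5_len else None,
            orf=orf_iv,
            utr3=Interval(orf_iv.end + 1, orf_iv.end + utr3_len)
            if utr3_len else None,
            polya_tail=Interval(len(seq) - tail_len + 1, len(seq))
            if tail_len else None,
            polya_signal=None,
            signal_to_tail_bp=None,
            protein=protein,
            m1_starts=m1_starts,
            m2_starts=m2_starts,
            sequon_start=sequon_start,
            hdel=plant_hdel,
            seed=seed,
        )
        if polya_offset is not None and utr3_len and truth.utr3 is not None:
            sig_end = truth.utr3.end - polya_offset if tail_len else None
            if sig_end is not None:
                truth.polya_signal = Interval(sig_end - 5, sig_end)
                truth.signal_to_tail_bp = polya_offset

        ann = segment_cdna(record)
        if not (ann.utr5 == truth.utr5 and ann.orf == truth.orf
                and ann.utr3 == truth.utr3
                and ann.polya_tail == truth.polya_tail
                and ann.polya_signal == truth.polya_signal
                and ann.signal_to_tail_bp == truth.signal_to_tail_bp):
            continue
        # protein-level scans must recover exactly the planted features
        prot = translate(truth.orf.slice(record.sequence), record.id)
        if prot.sequence != protein:
            continue
        m1, m2 = scan_crt_repeats(prot)
        hdel, _ = check_er_retention(prot)
        expected_sequons = [sequon_start] if sequon_start else []
        if ([h.interval.start for h in m1] == m1_starts
                and [h.interval.start for h in m2] == m2_starts
                and [h.interval.start for h in scan_sequons(prot)]
                == expected_sequons
                and hdel == plant_hdel):
            return record, truth
    raise RuntimeError("could not generate a self-consistent cDNA in 20 attempts")


# ---------------------------------------------------------------------------
# Homolog families along a tree


@dataclass
class FamilyGroundTruth:
    tree_newick: str
    root_sequence: str
    seed: int


def _evolve_sequence(parent: np.ndarray, branch_length: float,
                     rng: np.random.Generator) -> np.ndarray:
    child = parent.copy()
    n_subs = rng.poisson(branch_length, size=child.size)
    for site in np.nonzero(n_subs)[0]:
        state = child[site]
        for _ in range(n_subs[site]):
            # uniform over the 19 alternative residues
            step = rng.integers(1, 20)
            state = (state + step) % 20
        child[site] = state
    return child


def evolve_family(
    tree: Tree, root_protein_len: int = 2000, seed: int = 0
) -> tuple[Msa, FamilyGroundTruth]:
    """Gap-free protein family evolved along ``tree``.

    Per branch, each site receives a Poisson(branch length) number of
    substitutions, each uniform over the 19 alternative residues; branch
    lengths are therefore in expected substitutions per site.
    """
    rng = np.random.default_rng(seed)
    root_states = rng.integers(0, 20, size=root_protein_len)
    leaves: dict[str, np.ndarray] = {}

    def descend(node: Node, states: np.ndarray) -> None:
        if node.is_leaf:
            leaves[node.name] = states
            return
        for child in node.children:
            descend(child, _evolve_sequence(states, child.length, rng))

    descend(tree.root, root_states)
    taxa = sorted(leaves)
    rows = ["".join(AMINO_ACIDS[i] for i in leaves[t]) for t in taxa]
    truth = FamilyGroundTruth(
        tree_newick=to_newick(tree, supports=False),
        root_sequence="".join(AMINO_ACIDS[i] for i in root_states),
        seed=seed,
    )
    return Msa(taxa, rows), truth


def evolve_pair(
    distance: float, length: int, seed: int = 0
) -> tuple[str, str]:
    """Two sequences separated by an expected ``distance`` substitutions/site
    (evolution applied along a single branch)."""
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 20, size=length)
    b = _evolve_sequence(a, distance, rng)
    return ("".join(AMINO_ACIDS[i] for i in a),
            "".join(AMINO_ACIDS[i] for i in b))


# ---------------------------------------------------------------------------
# Decoy transcriptomes


@dataclass
class PlantedBlock:
    decoy: str
    target_start: int  # 1-based on the target
    length: int
    strand: str
    decoy_start: int  # 1-based on the decoy


@dataclass
class TranscriptomeGroundTruth:
    blocks: list[PlantedBlock]
    seed: int


def make_transcriptome(
    target: str,
    n_decoys: int = 5,
    decoy_len: int = 1000,
    planted_blocks: Optional[list[dict]] = None,
    seed: int = 0,
    screen_len: int = 15,
):
    """Random decoy transcripts with exact-copy target blocks planted.

    ``planted_blocks`` entries are dicts with keys ``decoy`` (0-based decoy
    index), ``target_start`` (1-based), ``length``, and optional ``strand``
    ('+' default).  Decoys without planted blocks are redrawn until their
    longest chance match to the target is shorter than ``screen_len``, so
    the planted blocks are the only screening-relevant homology.
    """
    from .sirna import TranscriptDb, revcomp_dna, to_dna

    target = to_dna(target)
    planted_blocks = planted_blocks or []
    rng = np.random.default_rng(seed)
    by_decoy: dict[int, list[dict]] = {}
    for spec in planted_blocks:
        if spec["length"] > decoy_len:
            raise ValueError("planted block longer than the decoy")
        if spec["target_start"] + spec["length"] - 1 > len(target):
            raise ValueError("planted block outside the target")
        by_decoy.setdefault(spec["decoy"], []).append(spec)

    # k-mer set of the target (both strands) for chance-match screening
    kmers = {target[i : i + screen_len]
             for i in range(len(target) - screen_len + 1)}
    rc = revcomp_dna(target)
    kmers |= {rc[i : i + screen_len] for i in range(len(rc) - screen_len + 1)}

    def clean_background() -> str:
        for _ in range(100):
            cand = _random_nt(decoy_len, rng)
            if not any(cand[i : i + screen_len] in kmers
                       for i in range(decoy_len - screen_len + 1)):
                return cand
        raise RuntimeError("could not draw a decoy free of chance matches")

    transcripts = {"target": target}
    blocks: list[PlantedBlock] = []
    for d in range(n_decoys):
        label = f"decoy{d + 1}"
        background = clean_background()
        seq = list(background)
        specs = by_decoy.get(d, [])
        cursor = 0
        for spec in specs:
            length = spec["length"]
            strand = spec.get("strand", "+")
            piece = target[spec["target_start"] - 1 :
                           spec["target_start"] - 1 + length]
            if strand == "-":
                piece = revcomp_dna(piece)
            max_start = decoy_len - length
            if cursor > max_start:
                raise ValueError(f"cannot pack blocks into {label}")
            pos = int(rng.integers(cursor, max_start + 1))
            seq[pos : pos + length] = piece
            blocks.append(PlantedBlock(label, spec["target_start"], length,
                                       strand, pos + 1))
            cursor = pos + length
        transcripts[label] = "".join(seq)
    db = TranscriptDb(transcripts, target_id="target")
    return db, TranscriptomeGroundTruth(blocks, seed)


# ---------------------------------------------------------------------------
# Intensity tables


@dataclass
class IntensityGroundTruth:
    effect: float
    expected_percent_reduction: float
    cv: float
    seed: int


def make_intensity_table(
    n_control: int = 7,
    n_treated: int = 7,
    effect: float = 0.25,
    cv: float = 0.10,
    seed: int = 0,
    reference_base: float = 1000.0,
) -> tuple[pd.DataFrame, IntensityGroundTruth]:
    """Two-group long-format intensity table with a known knockdown effect.

    Reference-normalized target levels are ``1`` (control) and ``effect``
    (treated), each multiplied by unit-mean log-normal noise with
    coefficient of variation ``cv``; reference intensities get independent
    noise of the same magnitude around ``reference_base``.  ``cv = 0``
    reproduces the means exactly.
    """
    if not (0 < effect <= 1):
        raise ValueError("effect must be in (0, 1]")
    if cv < 0 or min(n_control, n_treated) < 1:
        raise ValueError("invalid sample sizes or cv")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(cv**2)))

    def lognoise(size: int) -> np.ndarray:
        if sigma == 0:
            return np.ones(size)
        return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)

    rows = []
    for group, n, level in (("control", n_control, 1.0),
                            ("treated", n_treated, effect)):
        ref = reference_base * lognoise(n)
        ratio = level * lognoise(n)
        for i in range(n):
            rep = f"{group}_{i + 1}"
            rows.append({"replicate": rep, "group": group, "gene": "reference",
                         "intensity": ref[i]})
            rows.append({"replicate": rep, "group": group, "gene": "target",
                         "intensity": ratio[i] * ref[i]})
    table = pd.DataFrame(rows)
    truth = IntensityGroundTruth(effect, 100.0 * (1.0 - effect), cv, seed)
    return table, truth
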