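"""siRNA candidate enumeration, filtering cascade, and scrambled control."""

from collections import Counter

import numpy as np
import pytest

from crtkit.sirna import (
    CORE_LEN,
    DesignParams,
    MirnaSeedDb,
    SirnaCandidate,
    TranscriptDb,
    design,
    enumerate_candidates,
    gc_filter,
    homopolymer_filter,
    longest_run,
    longest_shared_block,
    offtarget_screen,
    revcomp_dna,
    scramble_control,
    seed_screen,
    to_dna,
)
from crtkit import simulate

# The published duplex pair used in the silencing experiments (19-nt cores).
SI_CORE = "GCAGGAUCAUUUAAGCACA"
SCR_CORE = "GCUACAGAUUGCGUAACAA"


def _random_rna(n, rng):
    return "".join("ACGU"[i] for i in rng.integers(0, 4, size=n))


def lcs_length_oracle(a: str, b: str) -> int:
    """Quadratic DP longest-common-substring oracle (single strand)."""
    best = 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


def both_strand_lcs(query: str, subject: str) -> int:
    q = to_dna(query)
    s = to_dna(subject)
    return max(lcs_length_oracle(q, s), lcs_length_oracle(revcomp_dna(q), s))


class TestEnumeration:
    def test_minimal_target_single_candidate(self):
        assert len(enumerate_candidates("A" * 19)) == 1

    def test_21mer_gives_three(self):
        assert len(enumerate_candidates("ACGU" * 5 + "A")) == 3

    def test_count_formula(self, rng):
        for n in (19, 25, 60, 113):
            target = _random_rna(n, rng)
            assert len(enumerate_candidates(target)) == n - 18

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            enumerate_candidates("ACGU")

    def test_strand_geometry(self):
        c = SirnaCandidate(1, SI_CORE)
        assert c.core_antisense == "UGUGCUUAAAUGAUCCUGC"
        assert c.duplex_sense.endswith("[dT][dT]")
        assert len(c.core_sense) == CORE_LEN
        assert c.seed == c.core_antisense[1:8]


class TestGcFilter:
    def test_all_a_passes_at_zero(self):
        c = SirnaCandidate(1, "A" * 19)
        out = gc_filter(c)
        assert out.passed and out.detail["gc_percent"] == 0.0

    def test_published_core_gc_by_window(self):
        # 8 G/C in the 19-mer: 42.1% on the core, 38.1% with the dT overhang
        c = SirnaCandidate(1, SI_CORE)
        core = gc_filter(c, window="core")
        assert core.detail["gc_percent"] == 42.1
        assert not core.passed
        duplex = gc_filter(c, window="duplex")
        assert duplex.detail["gc_percent"] == 38.1
        assert not duplex.passed

    def test_boundary_is_inclusive(self):
        c = SirnaCandidate(1, "GGGGGGGA" + "A" * 11)  # 7/19 G
        exact = 100.0 * 7 / 19
        assert gc_filter(c, max_gc=exact).passed
        assert not gc_filter(c, max_gc=exact - 1e-9).passed


class TestHomopolymerFilter:
    def test_five_run_fails(self):
        c = SirnaCandidate(1, "AAAAA" + "GCGU" * 3 + "GC")
        assert not homopolymer_filter(c).passed

    def test_published_core_passes(self):
        c = SirnaCandidate(1, SI_CORE)  # longest tract is UUU
        out = homopolymer_filter(c)
        assert out.passed and out.detail["max_run"] == 3

    def test_longest_run_matches_oracle(self, rng):
        for _ in range(200):
            s = _random_rna(int(rng.integers(1, 40)), rng)
            oracle = max(
                sum(1 for _ in g)
                for _, g in __import__("itertools").groupby(s)
            )
            assert longest_run(s) == oracle


class TestOfftargetScreen:
    def test_planted_verbatim_core_fails_at_19(self, rng):
        target = _random_rna(120, rng)
        db, _ = simulate.make_transcriptome(
            target, n_decoys=2, decoy_len=400,
            planted_blocks=[{"decoy": 0, "target_start": 40, "length": 19}],
            seed=1)
        c = SirnaCandidate(40, to_dna(target)[39:58])
        out = offtarget_screen(c, db)
        assert not out.passed
        assert out.detail["max_match_len"] == 19
        assert out.detail["transcript"] == "decoy1"

    def test_14_block_background_passes(self, rng):
        target = _random_rna(120, rng)
        db, _ = simulate.make_transcriptome(
            target, n_decoys=2, decoy_len=400,
            planted_blocks=[{"decoy": 0, "target_start": 40, "length": 14},
                            {"decoy": 1, "target_start": 44, "length": 14}],
            seed=2)
        for c in enumerate_candidates(target):
            out = offtarget_screen(c, db)
            assert out.passed
            assert out.detail["max_match_len"] <= 14

    def test_matches_quadratic_dp_oracle(self, rng):
        for _ in range(30):
            core = _random_rna(19, rng)
            subject = _random_rna(60, rng)
            assert longest_shared_block(to_dna(core), to_dna(subject)) == \
                both_strand_lcs(core, subject)

    def test_antisense_strand_hit_detected(self, rng):
        target = _random_rna(60, rng)
        core = to_dna(target[10:29])
        decoy_seq = to_dna(_random_rna(50, rng)) + revcomp_dna(core) \
            + to_dna(_random_rna(50, rng))
        db = TranscriptDb({"target": to_dna(target), "d": decoy_seq}, "target")
        c = SirnaCandidate(11, target[10:29])
        assert not offtarget_screen(c, db).passed


class TestSeedScreen:
    def test_empty_database_passes(self):
        assert seed_screen(SirnaCandidate(1, SI_CORE), MirnaSeedDb({})).passed

    def test_seed_collision_fails(self):
        c = SirnaCandidate(1, SI_CORE)
        mirna = "A" + c.seed + "CCCCCCCCCCCCC"
        out = seed_screen(c, MirnaSeedDb({"mir-x": mirna}))
        assert not out.passed and out.detail["collisions"] == ["mir-x"]

    def test_fuzz_against_exhaustive_comparison(self, rng):
        for _ in range(50):
            c = SirnaCandidate(1, _random_rna(19, rng))
            db = MirnaSeedDb(
                {f"m{i}": _random_rna(21, rng) for i in range(20)})
            expected = [n for n, s in db.mirnas.items() if s[1:8] == c.seed]
            out = seed_screen(c, db)
            assert out.passed == (not expected)
            assert out.detail["collisions"] == expected


def brute_force_survivors(db, mirnas, params):
    """Independent cascade: re-apply every rule with plain string code."""
    target = db.target.replace("T", "U")
    survivors = []
    for i in range(len(target) - 18):
        core = target[i : i + 19]
        gc = 100.0 * sum(1 for b in core if b in "GC") / 19
        if params.gc_window == "duplex":
            gc = 100.0 * (sum(1 for b in core if b in "GC")) / 21
        if gc > params.max_gc:
            continue
        if any(run > params.max_run for run in _runs(core)):
            continue
        anti = core.translate(str.maketrans("ACGU", "UGCA"))[::-1]
        if any(len(s) >= 8 and s[1:8] == anti[1:8]
               for s in mirnas.mirnas.values()):
            continue
        if any(both_strand_lcs(core, seq) >= params.min_block
               for label, seq in db.decoys().items()):
            continue
        survivors.append(i + 1)
    return survivors


def _runs(s):
    import itertools

    return [sum(1 for _ in g) for _, g in itertools.groupby(s)]


class TestDesignCascade:
    @pytest.fixture()
    def planted_db(self, rng):
        target = _random_rna(150, rng)
        db, _ = simulate.make_transcriptome(
            target, n_decoys=3, decoy_len=300,
            planted_blocks=[{"decoy": 0, "target_start": 20, "length": 19},
                            {"decoy": 1, "target_start": 70, "length": 16},
                            {"decoy": 2, "target_start": 120, "length": 14}],
            seed=8)
        return db

    def test_attrition_conserves_candidates(self, planted_db):
        report = design(planted_db)
        assert sum(report.attrition.values()) == len(report.candidates)

    def test_survivors_match_brute_force_cascade(self, planted_db, rng):
        mirnas = MirnaSeedDb({f"m{i}": _random_rna(21, rng) for i in range(10)})
        params = DesignParams(max_gc=55.0)
        report = design(planted_db, mirnas, params)
        got = [c.target_start for c in sorted(report.survivors,
                                              key=lambda c: c.target_start)]
        assert got == brute_force_survivors(planted_db, mirnas, params)

    def test_relaxing_gc_grows_survivor_set(self, planted_db):
        sets = []
        for max_gc in (30.0, 45.0, 60.0, 100.0):
            report = design(planted_db, params=DesignParams(max_gc=max_gc))
            sets.append({c.target_start for c in report.survivors})
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger

    def test_filter_conjunction_order_independent(self, planted_db, rng):
        mirnas = MirnaSeedDb({f"m{i}": _random_rna(21, rng) for i in range(5)})
        params = DesignParams(max_gc=50.0)
        report = design(planted_db, mirnas, params)
        # reapply each filter independently, in reverse order
        db, p = planted_db, params
        manual = set()
        for c in enumerate_candidates(db.target):
            checks = [
                offtarget_screen(c, db, min_block=p.min_block).passed,
                seed_screen(c, mirnas).passed,
                homopolymer_filter(c, max_run=p.max_run).passed,
                gc_filter(c, max_gc=p.max_gc, window=p.gc_window).passed,
            ]
            if all(checks):
                manual.add(c.target_start)
        assert manual == {c.target_start for c in report.survivors}

    def test_empty_background_and_open_gc_keeps_everything(self, rng):
        # target constructed without homopolymer tracts longer than 4
        target = ("ACGU" * 30)[:100]
        db = TranscriptDb({"t": to_dna(target)}, "t")
        report = design(db, params=DesignParams(max_gc=100.0))
        assert len(report.survivors) == 100 - 18

    def test_ranking_by_gc_then_position(self, planted_db):
        report = design(planted_db, params=DesignParams(max_gc=60.0))
        keys = [(c.gc_percent(), c.target_start) for c in report.survivors]
        assert keys == sorted(keys)


class TestScrambleControl:
    @pytest.fixture()
    def db(self, rng):
        target = _random_rna(80, rng)
        db, _ = simulate.make_transcriptome(target, n_decoys=2,
                                            decoy_len=200, seed=4)
        return db

    def test_scramble_is_anagram(self, db):
        c = enumerate_candidates(db.target)[5]
        ctl = scramble_control(c, seed=7, db=db)
        assert Counter(ctl.core_sense) == Counter(c.core_sense)
        assert ctl.core_sense != c.core_sense

    def test_deterministic_given_seed(self, db):
        c = enumerate_candidates(db.target)[5]
        a = scramble_control(c, seed=7, db=db)
        b = scramble_control(c, seed=7, db=db)
        assert a.core_sense == b.core_sense
        other = scramble_control(c, seed=8, db=db)
        assert Counter(other.core_sense) == Counter(c.core_sense)

    def test_screened_against_target_itself(self, db):
        c = enumerate_candidates(db.target)[0]
        ctl = scramble_control(c, seed=1, db=db)
        worst = max(longest_shared_block(to_dna(ctl.core_sense), seq)
                    for seq in db.transcripts.values())
        assert worst < 15

    def test_unscramblable_core_raises(self, db):
        c = SirnaCandidate(1, "A" * 19)  # every permutation is itself
        with pytest.raises(RuntimeError, match="no acceptable scramble"):
            scramble_control(c, seed=1, db=db, max_attempts=50)

    def test_published_control_is_an_anagram_of_its_sirna(self):
        # direct letter count: both cores are 7A/4C/4G/4U, so the deposited
        # control is composition-preserving, matching scramble_control's
        # contract
        assert Counter(SCR_CORE) == Counter(SI_CORE)
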