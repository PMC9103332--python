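# Methods

This note documents the models, conventions, and numerical choices behind
crtkit, and what the synthetic-data generators do and do not emulate.

## cDNA anatomy

A cDNA is decomposed as 5′UTR + ORF + 3′UTR + poly(A) tail, with 1-based
inclusive coordinates in all reports. The ORF is the longest ATG-initiated
open reading frame closed by an in-frame stop (stop codon included in the
interval); ties on length go to the most 5′ start. Longest-ORF is the
standard single-ORF convention for full-length mRNA clones; the package
deliberately does not model multi-ORF or spliced gene structures.

The poly(A) tail is the maximal terminal run of A when it reaches
`tail_min` (default 10 nt — long enough that a chance terminal A-run is
vanishingly unlikely at 4^-10, short enough to catch partially captured
tails). The 3′UTR excludes the tail. The polyadenylation signal is the
3′-most AATAAA within the 3′UTR; its distance to the tail is reported, by
default, as the number of nucleotides strictly between the hexamer's last
base and the tail's first base. Published "N bp upstream" statements do not
always fix that anchor, so the alternative convention (counting from the
hexamer's first base) is available via `anchor="start"`. U is normalized to
T on input so mRNA and cDNA FASTA both work.

## Protein features

Translation uses the standard genetic code; an internal stop is an error
that names the offending codon. Mass is the sum of ExPASy average residue
masses plus one water (18.0153 Da) — average, not monoisotopic, matching
what gel-scale "calculated molecular mass" values mean in practice.

The isoelectric point is the root of the Henderson–Hasselbalch net charge
over the N-terminus, C-terminus and the D/E/C/Y/H/K/R side chains. The
default pKa set is Bjellqvist's (the Compute pI/Mw defaults, including the
residue-specific terminal corrections); the EMBOSS set is available behind
`pka_set="emboss"`. Published pI values for plant proteins are almost
always ExPASy values, hence the default. The charge is strictly decreasing
in pH, so bisection on [0, 14] converges to the unique root; iteration
stops at |Z| < 1e-4, well below the 0.01 pH unit reporting precision.

Motif scanning is position-wise degenerate matching: literals match
themselves, X matches anything, (A/B) matches either. All match starts are
reported and overlaps are allowed — scanners never suppress a hit a
sliding-window enumeration would find, which is also how the test oracles
check them. Patterns ship in `data/motifs.yaml` (M1, 17 aa; M2, 14 aa) so
additional family signatures can be added without code changes. Sequons are
N-X-[S/T] with X ≠ P, reported with a fourth context residue (the "NKTL"
style) when one exists. ER retention requires the final four residues to be
exactly HDEL; a terminal KDEL (the animal-type signal) is noted but does
not pass.

Calreticulin N/P/C domain boundaries are usually published only as figure
annotations, so the partition is user-suppliable. When absent, a heuristic
places the P-domain from the first M1 hit to the last M2 hit (N before, C
after) — adequate for repeat-bearing calreticulins, and reported in the
output notes whenever it is used. Acidic fractions are 100·(D+E)/length
over a domain interval, reported to 0.1.

Signal-peptide prediction is intentionally not implemented; the mature
sequence start is user-supplied and defaults to residue 1.

## Distances and trees

Multiple alignments are consumed (aligned FASTA or Clustal), never
computed. The default distance treatment is complete deletion (drop every
column with a gap in any row), the convention of the common desktop
phylogenetics tools; pairwise deletion is selectable. p-distances are
corrected with the Poisson model d = −ln(1 − p); p ≥ 1 raises a saturation
error unless a cap is requested. Percent identity defaults to
identical/mutually-ungapped columns — published identity values are highly
sensitive to this denominator, so the convention is stated in the API and
alternatives ("alignment", "shorter") are explicit options. Pairwise global
alignment is Needleman–Wunsch with affine gaps (BLOSUM62, open 10, extend
0.5, the conventional protein defaults), provided for identity reporting;
among co-optimal alignments the first deterministic traceback is returned,
and only the optimal score is contract-tested.

Neighbor joining follows Saitou–Nei: at each step the pair minimizing
Q(i,j) = (n−2)·d(i,j) − R_i − R_j is joined, with ties broken by the
smallest (row, column) index pair so results are deterministic. Negative
branch-length estimates (possible on non-additive matrices) are clamped to
zero with the deficit moved to the sibling edge, preserving the joined
pair's path length; the raw estimate is kept in `Node.raw_length` for
diagnostics. The final three lineages attach to an unresolved root — the
tree is unrooted until `root_by_outgroup` places the root at the midpoint
of the outgroup's pendant edge. On additive matrices NJ is exact in both
topology and branch lengths; the tests exploit this with random-tree
round-trips at 1e-9 tolerance.

Bootstrap supports resample alignment columns with replacement; replicate r
uses an RNG stream derived deterministically from (seed, r), so runs are
reproducible and trivially parallelizable. Supports are mapped onto the
original tree's internal edges as the percentage of replicates containing
the same bipartition (the presentation used in the common NJ tools);
a majority-rule consensus is available separately (`majority_consensus`).
A replicate whose resample retains no columns under complete deletion is
redrawn, up to 100 attempts. `collapse_low_support` contracts edges below a
cutoff (e.g. 70%) into polytomies — both "collapse" and "display-only"
readings of a support cutoff are therefore available, since published
figures rarely say which was applied. Newick output writes supports as
internal-node labels and branch lengths with 6 decimals.

## siRNA design

Candidates are all 19-nt windows of the target mRNA. Filters:

* **GC** ≤ 38.0% by default, boundary inclusive. The window is the 19-nt
  core by default; the 21-nt dTdT-extended duplex is selectable, because
  published GC bounds do not always state their denominator. Notably, a
  known published duplex core computes to 42.1% (core) / 38.1% (duplex)
  against its own stated 38.0% bound — the threshold is configurable
  precisely because such accounting is often irrecoverable.
* **Homopolymer**: longest single-nucleotide tract ≤ 4.
* **Off-target**: fail at ≥ 15 nt ("more than 14") of exact contiguous
  identity between the core (either strand) and any non-target transcript.
  This is a deliberate simplification of a BLAST-style homology screen to
  exact matching: auditable, deterministic, and oracle-testable against a
  longest-common-substring dynamic program.
* **Seed**: guide-strand positions 2–8 (the standard miRNA seed) must not
  exactly match positions 2–8 of any listed mature miRNA. Exact matching is
  the implemented reading of "seed similarity"; alignment-scored variants
  are out of scope.

All filters are evaluated for every candidate (their conjunction is
order-independent); attrition is attributed to the first failing filter in
cheap-to-expensive order. Survivors are ranked by ascending GC then 5′
position. The scrambled control is a seeded composition-preserving
permutation of a chosen core, re-screened so its longest contiguous match
to ANY transcript (target included) stays below the off-target threshold —
consistent with the published control duplex, which is a pure anagram of
its siRNA. dTdT overhangs render as `[dT][dT]` in reports and plain `TT`
in machine-readable output.

## Knockdown quantification

Long-format tables (replicate, group, gene, intensity) are validated so
every replicate carries exactly one target and one positive reference
measurement. Relative levels are per-replicate target/reference ratios
(invariant to common rescaling); group SDs are computed over per-replicate
ratios. Percent reduction is 100·(1 − mean_treated/mean_control).

The Mann–Whitney U test is two-sided. For tie-free samples with
n₁·n₂ ≤ 400 the exact null distribution of U is computed with the classical
counting recurrence c(u; n, m) = c(u−m; n−1, m) + c(u; n, m−1) — identical
to enumerating all C(n+m, n) group assignments but feasible at n = 15 vs
15, which literal enumeration is not. With ties, or for larger samples, the
normal approximation with tie correction and a 0.5 continuity correction is
used; the method is always reported. Two identical constant groups are
degenerate and yield p = 1 with a note.

## Synthetic data

Every generator is a pure function of its parameters and seed, and returns
ground truth sufficient to score its downstream stage.

* `make_cdna` defaults encode the geometry of the characterized
  calreticulin-3 cDNA: 19 nt 5′UTR, 431-codon ORF ending in TGA, 320 nt
  3′UTR, AATAAA 24 nt upstream of the tail, sequon at residue 107, three
  M1 + three M2 repeats, terminal HDEL, and a 17 nt tail — the tail length
  closes the documented 1652 bp total (19 + 1296 + 320 = 1635), though the
  annotator itself never assumes it. Background residues exclude N so the
  planted sequon is provably unique; the 5′UTR is ATG-free so the planted
  ORF is unambiguous; the 3′UTR carries exactly one AATAAA and does not end
  in A. Each record is verified by round-trip annotation (segmentation,
  translation, all motif scans) before being returned. What this does NOT
  emulate: realistic codon usage, compositional bias, indels, or sequencing
  error — passing round-trip tests demonstrates coordinate bookkeeping and
  scanner correctness, not robustness to messy real reads.
* `evolve_family` evolves a gap-free family along a given tree: per branch,
  each site receives Poisson(branch length) substitutions, each uniform
  over the 19 alternative residues — the 20-state uniform-exchange model,
  the simplest process whose pairwise distances the Poisson correction
  estimates. Expected proportion of differing sites after d substitutions
  is (19/20)(1 − e^(−20d/19)), which the tests check in closed form.
  Real amino-acid exchange is not uniform; empirical matrices are out of
  scope, so recovery results say nothing about model misspecification.
* `make_transcriptome` plants exact copies of target segments (either
  strand) into otherwise random decoys, and redraws decoy background until
  it contains no chance 15-mer of the target, so planted blocks are the
  only screening-relevant homology.
* `make_intensity_table` draws reference-normalized target levels around 1
  (control) and `effect` (treated) with unit-mean log-normal noise of
  coefficient of variation `cv`, on top of a reference baseline with
  independent noise. Defaults (effect 0.25, cv 0.10, n = 7 per group)
  mirror the reported ~73–77% knockdowns and small replicate counts of
  band-densitometry experiments; cv = 0 reproduces the means exactly.

## Problem sizes used in the automated runs

Topology-recovery checks use 100 families on random 8-leaf trees with
2,000-column alignments (recovery ≥ 95% expected); Poisson recovery uses
10,000-site pairs at d ∈ {0.05, 0.1, 0.3, 0.5} with a 5% relative + 3
binomial-SE tolerance (slight downward bias from back-substitution is
expected and tolerated); bootstrap determinism uses 100–200 replicates;
type-I error of the exact test uses 10,000 null simulations at n = 7 vs 7,
compared against the largest attainable level of the discrete null rather
than the nominal 0.05. These sizes were chosen as the smallest at which the
statistical properties under test are comfortably resolvable.

## Known limitations

* Real-sequence anchors: composition-dependent reference values (mass, pI,
  acidic fractions of the deposited cDNA's product) require the actual
  GenBank record, which is not redistributable here; the corresponding test
  states exactly how to supply it.
* Identity values between real homolog sets depend on the aligner's
  internals and the identity denominator; the package documents its
  conventions but does not promise to reproduce any particular published
  percentage.
* Off-target screening is exact-match only; a BLAST-grade mismatch-tolerant
  screen would be strictly more conservative.
* The domain-partition heuristic requires both M1 and M2 hits and assumes
  the canonical N–P–C order.
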