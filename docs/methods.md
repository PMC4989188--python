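# Methods

## Data model and coordinates

A genome is a list of replicons, each an annotated DNA molecule with CDS
gene records sorted by start. Internally all intervals are **0-based
half-open**; GenBank and GFF3 (both 1-based inclusive) are converted on
input and output, so the round trip external → internal → external is the
identity. CDS features without a `translation` qualifier are translated
with the bacterial genetic code (NCBI table 11); alternative start codons
are rendered as Met, and partial features are retained but flagged (and
excluded from candidacy by default, configurable).

The signed intergenic distance of two position-ordered genes *a*, *b* is
`b.start − a.end`: positive gap, zero abutting, negative overlap. It is
defined on genomic coordinates irrespective of strand (the pairing stage
handles orientation separately) and is undefined for nested genes, which
are excluded from pairing — a ±small-window rule has no meaning for
containment. The definition makes two properties exact: mirror symmetry
under reverse complement, and additivity
`gap(a,b) + len(b) + gap(b,c) = c.start − a.end`.

## Homolog identification

The homology stage is pluggable:

* **External profile search.** HMMER3 per-domain tabular output
  (`--domtblout`, hmmsearch orientation) is parsed directly; the
  **per-domain independent e-value** governs filtering, matching the
  domain-level semantics of a conserved-domain search, at an **inclusive**
  cutoff (default ≤ 0.01). A test cross-checks the parser against
  Bio.SearchIO's `hmmsearch3-domtab` reader.
* **Built-in PSSM fallback.** From a seed alignment (≥ 2 sequences;
  columns > 50 % gaps dropped) a position-specific scoring matrix is built
  with scores `ln(((count + κ/20)/(n + κ)) / background)` (pseudocount
  κ = 1, uniform background by default). Proteins are scored by the best
  ungapped window; significance is a shuffle-based empirical p-value with
  add-one correction, `(1 + #shuffles ≥ observed)/(n_shuffles + 1)`,
  seed-reproducible. This trades the power of a full profile HMM for a
  small, exactly testable surface; it is the hermetic stand-in for an
  arbitrary user profile collection, since no canonical TA profile set is
  redistributable.

Role assignment: each protein takes the role (toxin/antitoxin) of its
lowest-e-value hit; exact cross-role ties are marked `ambiguous` and
excluded from pairing by default — conservative and auditable. The size
filter keeps 30–500 aa inclusive at both bounds. Filtering is monotone:
relaxing any threshold can only add candidates.

## Operon pairing

Candidates are scanned in genomic order. A pair qualifies when it is
adjacent (no intervening candidate; by default also no intervening
annotated gene, since "flanking" is read as direct neighborhood — a flag
relaxes this), co-oriented (default on, as an operon implies
co-transcription; a flag relaxes it), of opposite roles, and within the
closed distance window (default −20..30 bp). Gene order
(antitoxin-first/toxin-first) is derived from the strand: the 5′ gene in
transcription direction is "first".

Each candidate joins at most one locus. Conflicts (e.g. an antitoxin
flanked by two toxins) are resolved deterministically: smallest |distance|,
then lowest combined e-value, then leftmost pair. Three-gene tandem loci
are therefore not called as such; the better-scoring two-gene pair wins.
Widening the window, the size band, or the e-value cutoff never removes a
locus (monotonicity), and locus calls are invariant under
reverse-complementing the replicon with mirrored coordinates.

Circularity: the default generator and the bundled analyses use linear
replicons; for circular inputs the origin-spanning adjacency is not
currently evaluated, a documented limitation rather than a modular-
arithmetic special case.

## RelB consensus motif and residue analyses

The RelB-family C-terminal motif is modeled as nine positions `ZXnnZnnRZ`
with residue classes Z = {V, I, L, A} (small hydrophobic) and
X = {A, V, I, L, M, F, W, C} (hydrophobic). The literature does not fix the
hydrophobic set exactly — in particular whether aromatics belong — so X is
configurable and every report echoes the classes used. Tyr is excluded from
the default X because its hydroxyl makes it borderline; Gly is excluded
from Z as it has no side chain. The scanner evaluates every window
(optionally restricted to a C-terminal fraction, default 40 % when enabled,
since the motif sits at the C-terminus of the antitoxin's α3 helix but the
scanner has no structural input — a stated heuristic) and returns
per-position verdicts; position 8 must be exactly Arg. Anchor arithmetic is
fixed by the motif: X is position 2 and the last Z position 9, so an X at
residue 61 pairs with a last Z at 68.

Point mutations use compact `N61V,M68L` notation, 1-based, with the
reference residue checked against the sequence (an off-by-one guard);
application is an involution when ref/alt are swapped back.

Catalytic-residue mapping and percent identity use Biopython's
`PairwiseAligner` with BLOSUM62, gap open 11 / extend 1 (the familiar
protein-BLAST parameterization), deterministic first-traceback. Identity is
identical columns over all alignment columns (gap columns counted), to
0.1 %. Protein mass sums average-isotopic residue masses plus one water,
in kDa.

## Codon usage

RSCU(c) = count(c) / mean count over c's synonym family (bacterial code,
stops excluded); families with zero observations are flagged undefined.
Relative adaptiveness w(c) = RSCU(c)/max synonymous RSCU; unobserved codons
get a floor of 0.01 (configurable, flagged) to avoid zero geometric means.
CAI is the geometric mean of w over a gene's codons **excluding the start
codon, the terminal stop, and the single-codon families Met and Trp** — the
canonical construction; with it, Σ RSCU over a family equals the family
size, max w = 1 per family, a gene written purely in modal codons scores
exactly 1.0, and recoding any codon to a higher-w synonym never lowers CAI.
Reference genes are selected by case-insensitive product-text keywords
(default "ribosomal protein", "elongation factor"), and the selected list
is always emitted with the result for auditability.

## qPCR expression

For target *t* and internal reference *r* (16S rRNA by default):
ΔCt = mean Ct(t) − mean Ct(r) per condition, ΔΔCt = ΔCt(treated) −
ΔCt(control), fold = 2^−ΔΔCt. Replicates are averaged within each
(condition, gene) cell before differencing; the reported SD is the
root-sum-square of the four cell-mean standard errors. Significance is
**fold > 2 or fold < 0.5, strict** — the down threshold is read as a fold
of 0.5 (a fold change cannot be negative), and boundary folds are not
significant. The estimator is antisymmetric (swapping conditions inverts
the fold) and invariant to adding a constant to all Ct values of one
condition.

## Synthetic data

The generator emulates a two-replicon genome (chromosome-scale +
plasmid-scale, default 60 kb + 25 kb — scaled down from Mb-scale real
replicons to keep runs fast while preserving every geometric feature):
five antitoxin–toxin pairs planted at exact signed intergenic distances
drawn from the −20..30 window (the bundled analyses fix them to −8, −1, 0,
10, 30 so the canonical overlap geometry is always present), ~40 %
minus-strand, 50 decoy genes, 10 % size outliers (< 30 or > 500 aa), and
five reference genes with ribosomal/elongation-factor products. Planted
proteins embed fixed synthetic role signatures — not real RelBE sequences,
so nothing external is ever fetched; the antitoxin signature contains a
ZXnnZnnRZ-compatible window. Matching seed alignments and a
domtblout-format hit table (planted e-values log-uniform in [1e-8, 1e-3];
optional spurious decoy hits at a stated rate) derive from the same truth
table.

Overlap feasibility is a real biological constraint the generator honors:
a same-strand overlap contains the upstream stop codon, so overlaps of
k ≥ 3 with k ≡ 0 (mod 3) would put that stop in-frame inside the
downstream CDS, and k ∈ {2, 3, 5} admit no stop codon across the shared
bases; feasible overlaps are {1, 4} ∪ {k ≥ 6 : k ≢ 0 (mod 3)}. Overlapping
junctions are realized by rewriting both genes' junction codons against a
shared bridge segment and re-translating, so annotation and sequence agree
exactly in both emitted dialects (GenBank and GFF3+FASTA load to identical
structures).

Ct tables place control targets at 22 cycles, the reference at 12, shift
treated targets by −log₂(fold), and add Gaussian noise (default SD 0.3
cycles, 3 replicates — typical technical-replicate scatter). All
randomness flows through one seeded generator; a fixed seed yields
byte-identical files (the GenBank date field is pinned for this reason).

What the generator does **not** model: GC skew and realistic codon bias in
decoys, pseudo-genes, nested or antisense gene arrangements, circular
replicons, amplification-efficiency variation in qPCR, and biological (as
opposed to technical) replicate structure. Passing tests therefore
demonstrate the correctness of the measurement and pairing machinery under
controlled geometry, not discovery performance on real genomes, which is
bounded by the quality of the supplied profile set.

## Problem sizes and reproducibility

The test suite and `scripts/acceptance.py` run on genomes of 30–60 kb with
2–5 planted loci, 20 seeded genomes for the recovery property, 100–200
random sequences for oracle-equivalence checks, and 200 simulated Ct tables
for estimator recovery — sizes chosen so the full suite completes in
seconds while every property is exercised at meaningful multiplicity. The
acceptance script derives every stream from `--seed` and writes one JSON
object of measured quantities; reruns with the same seed are identical.

## Known limitations

* The built-in PSSM scorer is ungapped and not a substitute for a profile
  HMM's sensitivity; it exists so the pipeline is testable and usable
  without an external search.
* Three-gene TA operons are resolved to their best two-gene pair.
* Percent identity from a global BLOSUM62 alignment approximates, but does
  not reproduce, BLASTp's local identity on divergent pairs (±~2 points is
  typical).
* Reference-set composition moves CAI by a few hundredths; CAI comparisons
  should hold the reference set fixed.
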