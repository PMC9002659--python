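# Methods

## Problem and model

Local gene duplication leaves two distinct footprints inside a chromosome.
A segmental duplication copies a run of genes, producing a *collinear
block*: a chain of homologous gene pairs whose order is preserved along the
chromosome. A tandem duplication places a single copy near its source,
producing a close homologous pair without extended collinearity. Both kinds
of young duplicates are identified by low synonymous divergence (Ks), which
accumulates approximately clock-like because synonymous changes are largely
unconstrained. The pipeline classifies every gene as segmental, tandem,
both, or neither, and intersects the classification with resistance-gene
families, whose expansion in plants is strongly driven by local duplication.

## Ks estimator

Nei–Gojobori (1986) counting with Jukes–Cantor correction:

- Every codon position contributes a fractional synonymous-site count equal
  to the fraction of its possible single-nucleotide changes that preserve
  the amino acid; changes creating stop codons are excluded from the
  possible set, so each position still contributes exactly one site and
  S + N = 3 × codons. Sites are averaged between the two sequences.
- Codons differing at d positions are resolved by averaging
  synonymous/nonsynonymous step counts over all d! mutational pathways;
  pathways through stop codons are excluded, and a codon pair whose every
  pathway is blocked is skipped entirely (it then contributes neither sites
  nor differences).
- Ks = −(3/4)·ln(1 − 4·ps/3) with ps = Sd/S; ps ≥ 3/4 is reported as
  SATURATED and excluded from all downstream Ks filters and histograms.
  The degenerate 0/0 case (no synonymous sites, no differences — e.g. a
  single ATG codon) is defined as ps = 0.
- Ka is computed symmetrically and reported, but no classification uses it.

NG86 was chosen over maximum-likelihood estimators because the thresholds
involved (Ks < 0.2) sit in the regime where counting methods are accurate,
and because NG86 admits an exact brute-force oracle: the test suite checks
site and pathway counts against naive enumeration on all 61 × 61
sense-codon pairs.

Gene pairs are aligned at the protein level (global affine-gap alignment,
BLOSUM62, gap open 11 / extend 1, so a length-1 gap costs 12) and the
alignment is back-translated to codons; columns with a gap or an ambiguous
base are dropped before counting.

## Homology and RBH

All-vs-all alignment is restricted to pairs sharing at least one exact
protein 6-mer, and hits scoring below 50 are discarded. The score floor
removes the rare chance 6-mer collisions between unrelated proteins, which
would otherwise let two singleton genes elect each other as reciprocal best
hits; genuinely homologous pairs score far above it (an identical 150-aa
pair scores ≈ 750). Reciprocal best hits use alignment score with ties
broken toward the lexicographically smaller partner, making the pairing
deterministic. Tandem arrays of more than two near-identical members tie on
score, so array members beyond the first are not RBH-paired — this is why
tandem classification consumes *all* scored homologous pairs, not only RBH
pairs, while the Ks age distribution is built on the RBH subset.

## Collinear blocks

Anchors (same-chromosome pairs, canonicalised to rank_a < rank_b) are
chained by dynamic programming with unit scores: rank_a strictly
increasing, rank_b strictly monotone (ascending and descending evaluated
separately), consecutive gaps ≤ max_gap = 25 ranks on both axes. Blocks
need ≥ 5 anchors. Greedy extraction (best chain, remove anchors, repeat)
assigns each anchor to at most one block; ties are resolved by leftmost
rank_a, then ascending before descending, so output order is deterministic.
Unit scores (no distance penalty) keep the objective simple enough for an
exhaustive oracle, which the tests run on random instances of ≤ 8 anchors.

A block passes the age filter when its **median** anchor Ks is < 0.2
(strict). The median is robust to a single saturated or outlying anchor;
`ks_mode=all_anchors` switches to requiring every anchor to pass.

## Duplication classes

Gene distance is rank difference: adjacent genes are 1 apart. The tandem
threshold is inclusive (distance ≤ 10). Tandem pairs need their own
defined Ks < 0.2; segmental membership needs only the block-level filter.
Percentages are rounded half-up to one decimal; the overlap percentage is
reported relative to the tandem set.

## Synthetic genomes and what they do (not) show

Background genes are independent random coding sequences (ATG + uniform
sense codons + fixed stop), mutually non-homologous at the default length
of 150 codons. Planted events copy real gene runs (segmental, same
chromosome, order preserved) or single genes (tandem, adjacent insertion),
then re-lay coordinates left to right with 1 kb intergenic spacing, so
100-kb windows contain ~65 genes-worth of sequence.

Divergence is planted only at synonymous positions: each codon position
mutates with probability p·f, where f is that position's synonymous-change
fraction and p = (3/4)(1 − exp(−4·Ks_target/3)) inverts the Jukes–Cantor
correction, drawing uniformly among synonymous non-stop alternatives.
Consequently the expected observed ps equals p and the corrected Ks is
centred on the target, while proteins stay identical — so homology
detection is exact by construction and Ks recovery is tested in isolation.
Two caveats follow. First, codon-degeneracy drift (a synonymous walk does
not preserve site counts exactly) and double hits within a codon leave a
small residual bias, < 5% relative at Ks ≤ 0.5 — inside the ±0.02
recovery tolerance at the benchmark's 300-codon, 200-pair setting. Second,
an individual 150-codon pair planted at Ks 0.1 has a sampling standard
deviation near 0.03, so a pair occasionally estimates above the 0.2
threshold; the canonical fixture is evaluated at a fixed seed where all
planted pairs classify correctly, and threshold-adjacent behaviour on other
seeds is the estimator's honest sampling noise, not a defect.

Real genomes differ in ways the simulator deliberately omits: genes differ
in length and composition, duplicates diverge nonsynonymously and acquire
indels, blocks erode by gene loss, and domain architectures come from
imperfect annotation. Passing the planted-truth tests therefore
demonstrates correctness of the algorithms, not robustness to annotation
noise.

The canonical study genome (3 chromosomes × 60 genes × 150 codons) plants
one 6-gene segmental block inserted far from its source (purely segmental),
one inserted 7 ranks away (its genes meet both definitions — the mechanism
by which the "both" class arises in real genomes too), one 3-copy tandem
array at Ks 0.05, and 12 R genes covering all 11 families.

## R-gene rules

Families are assigned from domain presence, order-independent. With NBS:
TIR+CC → OTHER (the RGAugury catch-all, checked first), TIR+LRR → TNL,
TIR → TN, CC+LRR → CNL, CC → CN, LRR → NL, bare → NBS. Without NBS:
TIR → TX, TM+kinase+LRR → RLK, TM+LRR → RLP, TM+CC → TM-CC, else no call.
Domain architectures are an input table, not inferred from sequence: the
classification logic is what the downstream statistics use, and decoupling
it from HMM scanning keeps the pipeline self-contained. Window counts
assign a gene to the 100-kb window containing its start coordinate.

## Numerical and reporting conventions

Coordinates are 1-based inclusive (GFF3); gene rank is 0-based per
chromosome ordered by start with lexicographic gene-id tie-break. All
tabular outputs are TSV, sorted by their first column, stamped with the
tool version, a hash of the analysis parameters (file paths excluded, so
re-runs into different directories are byte-identical) and the seed. The
output validator re-derives every invariant — rank permutations, block
monotonicity, label conservation, percentage arithmetic — from the emitted
files alone.

## Problem sizes

Defaults used by the tests, the analysis scripts and the acceptance script:
the canonical genome is 195 genes after insertions; the Ks recovery
benchmark uses 200 pairs × 300 codons per target (binomial sampling error
of the mean ≈ 0.002, far inside the ±0.02 band); the chaining oracle runs
200 random instances of ≤ 8 anchors; the NG86 oracle covers all 3721
sense-codon pairs.

## Known limitations

- NG86 ignores transition/transversion bias and codon-usage bias; Ks is
  slightly underestimated for real sequences with strong bias. The
  estimator interface accepts alternative methods.
- The chaining objective has no gap penalty, so a sparse chain within the
  gap bound scores as well as a dense one of equal length.
- Only intra-chromosomal blocks are detected (by design); inter-chromosomal
  segmental duplications are out of scope.
- Whether a published block count refers to blocks or to anchor pairs can
  be ambiguous; the report emits both (`n_blocks_kept`,
  `n_anchor_pairs_kept`).
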