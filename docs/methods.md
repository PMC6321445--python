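# Methods

## Scope and units of analysis

The package quantifies synonymous codon usage bias in bacterial coding
sequences and the forces shaping it: directional mutation pressure
(nucleotide composition, summarized by GC3 and positional entropies)
versus translational selection (preferred-codon enrichment, summarized
by ENC depression below the neutral curve and by CAI). The unit of
analysis is the individual gene; genome-level summaries are either
pooled codon counts (RSCU vectors, family-adaptation indices) or
per-gene means ± sd (composition tables). Distribution-level contrasts
(e.g. overall vs third-position entropy, leading vs lagging strand)
are per-gene values compared by one-way ANOVA.

## Validation of coding sequences

A CDS is kept when its length is a multiple of three, it contains no
internal stop codon, and at least `min_codons` (default 30) sense
codons remain after dropping codons with ambiguous bases. The default
floor exists because RSCU and ENC are unstable on very short genes;
it is a parameter, not a constant, so toy inputs can be validated
explicitly. The terminal TAA/TAG/TGA is stored separately and never
enters sense-codon statistics; stop usage is analyzed on those records
alone. Coordinates are 0-based half-open internally; GenBank 1-based
closed locations are converted on read. Ambiguity handling drops the
affected codon, not the gene, preserving genes with isolated Ns.

## Entropy measures

H = −Σ fᵢ log₂ fᵢ with 0·log₂0 := 0 (delegated to `scipy.stats.entropy`).
Nucleotide entropies (overall and third-position) are reported in raw
bits with maximum 2; only the amino-acid entropy is normalized, by
log₂ 20, to [0, 1]. A `normalize_entropy` option divides nucleotide
entropies by log₂ 4 for cross-alphabet comparison. The asymmetric
convention is deliberate: the amino-acid measure is conventionally
reported on a normalized scale, whereas nucleotide entropy in bits is
directly interpretable against its ceiling of 2.

## RSCU and representation classes

RSCU is computed over the 59 sense codons of the 18 degenerate
families (Met/ATG, Trp/TGG and stops excluded); within an observed
k-fold family the values sum to k. Unobserved families carry 0 and an
explicit `family_observed` flag. Representation classes use strict
inequalities: over-represented iff RSCU > 1.6, under-represented iff
RSCU < 0.6, boundary values unbiased.

## ENC and the null curve

Wright's estimator is applied per gene: for each family with n ≥ 2
counted codons, F̂ = (n Σp̂² − 1)/(n − 1); families with F̂ ≤ 0 are
dropped; ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ over degeneracy-class
means (9 two-fold, 1 three-fold, 5 four-fold, 3 six-fold families).
An empty three-fold class is imputed as (F̄₂ + F̄₄)/2; any other empty
class takes the grand mean F̂ of computable families. Values are
clamped to [20, 61]; a gene with no computable family yields a missing
value. The implementation is verified against an independent
brute-force second implementation to 1e-9 on 200 random genes. The
expected curve under pure mutation pressure, 2 + s + 29/(s² + (1−s)²)
capped at 61, is exposed separately for the ENC–GC3 plot.

## CAI

Relative adaptiveness w is computed from the pooled codon counts of a
reference gene set: within each family a pseudocount of 0.5 is added
to every codon's count before dividing by the family maximum, so all
weights are strictly positive and the most-used codon of each family
has w = 1. (The pseudocount makes weights only asymptotically invariant
to duplicating the reference; for realistic reference sizes the effect
is below 1%.) CAI is the geometric mean of w over a gene's codons,
excluding the single-codon families ATG and TGG. The reference policy
is configurable: genes annotated as ribosomal proteins when available,
otherwise the lowest-ENC 5% of genes. Because absolute CAI depends on
the reference choice, cross-study comparisons should rely on ranks and
correlations rather than absolute values.

## R(A,B)/D(A,B)

R(A,B) is the cosine of the angle between two 59-dimensional RSCU
vectors; for non-negative vectors it lies in [0, 1], so the distance
D = (1 − R)/2 lies in [0, 0.5] (0 iff the vectors are parallel,
0.5 iff orthogonal). Family vectors are built from pooled counts of
the tagged genes rather than means of per-gene RSCU, which is robust
to short genes. D < 0.1 is used as the adaptation criterion.

## Strand inference

No annotation of replication origin is assumed. Per-window GC skew
(G−C)/(G+C) with window = max(genome/500, 1000) nt is cumulated; the
global minimum marks ori, the maximum ter. A plus-strand gene starting
on the ori→ter arc (increasing coordinates with circular wrap) is
leading; minus-strand genes invert. When the normalized amplitude
(max − min of the cumulative curve per window) is below 0.01 the
labels are kept but flagged low-confidence: a constructed skew of
amplitude 0.1 yields ~0.05 on this scale while a skew-free random
walk stays near 0.002, so the threshold separates the two regimes by
more than an order of magnitude. Genomes shorter than 10 windows get
no labels.

## PCA, correlation, ANOVA

PCA mean-centres columns without variance scaling (RSCU columns share
a scale; scaling is configurable in principle via pre-transforming the
matrix) and decomposes by SVD; explained fractions are λₖ/Σλ; each
component's sign is fixed by making its largest-magnitude loading
positive, so runs are reproducible. Genome-level PCA rows are pooled
RSCU vectors (one point per strain); gene-level rows (for strand
analyses) are per-gene RSCU vectors. Spearman uses average ranks for
ties and the two-sided t approximation; ANOVA is the standard
between/within decomposition with significance stars at
0.05/0.01/0.001. No multiple-testing correction is applied.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not any particular genome. Each gene starts with ATG, draws its length
from a normal distribution (default mean 330 codons, sd 150, truncated
to [30, 1000] — i.e. roughly 0.1–3 kb, typical of bacterial CDS), and
samples each codon from a mixture: with probability ω uniformly from
one designated optimal codon per family (T-ending preferred, then
A-ending — an AT-consistent fixed choice), otherwise three independent
nucleotides from positional background distributions. Stop triplets in
sense positions are excluded by renormalising over the 61 sense codons,
which is exactly equivalent to rejection-resampling and leaves
within-family conditional distributions untouched. Terminal stops are
drawn from (TAA, TAG, TGA) = (0.6, 0.3, 0.1), the TAA-biased,
TGA-poorest pattern of AT-rich intracellular bacteria. Defaults are
900 genes per genome and GC3 0.345.

Two calibration details matter. First, because the excluded stop
triplets all end in A or G, a naive background would realize third-
position frequencies ~1–2 points away from the requested targets; the
generator therefore solves for the background by a deterministic
fixed-point iteration so that the *realized* marginals (including the
ATG start's contribution at weight 1/mean-length) hit the targets to
<1e-10. This applies to the gc3 knob and to the composition presets;
an explicitly supplied background matrix is used literally. Second,
positions 1–2 default to uniform: under that null the within-family
third-position conditionals match the assumption behind Wright's
expected curve, so ω = 0 genes sit on the curve (observed agreement
within ~0.4 ENC units at 300-codon genes) without any curve-specific
tuning.

Skewed genomes place half the genes on each replichore with random
orientation; a gene transcribed co-directionally with the replication
fork (the true leading class) is generated G-rich in coding
orientation at the requested amplitude, so the published strand shows
the canonical leading-strand G excess on either replichore. Ori is at
position 0 and ter at the concatenation midpoint; both are recorded
with per-gene true labels.

What the generator does *not* emulate: amino-acid composition of real
proteomes (family usage follows the positional backgrounds),
codon-pair and dinucleotide effects, gene-expression-correlated
selection strength, operon structure, intergenic DNA, or evolution
along a phylogeny. Passing tests therefore demonstrate correctness of
the estimators and the qualitative force-separation diagnostics, not
that any biological conclusion about real genomes is reproduced.

## Problem sizes and determinism

Simulation-based checks use 200 genes × 300 codons per condition
(estimator-vs-oracle, null-curve, correlation-sign and family-
adaptation checks) and 400 genes for strand recovery; these sizes put
sampling error well inside the asserted tolerances while keeping the
whole suite fast. All randomness flows through a single integer seed
per generated genome (`numpy.random.default_rng`); identical seeds
produce byte-identical FASTA output. Pipeline outputs are sorted by
gene identifier, making every table invariant to input record order,
and the run manifest records package versions, the config hash and the
seed needed to reproduce a run.

## Known limitations

- ENC uses Wright's imputation conventions; other tools differ in rare
  edge cases (missing families, tiny genes), so cross-tool ENC values
  can differ by a few units on short genes.
- Absolute CAI values depend on the reference-set policy and are not
  comparable across policies.
- The strand heuristic assumes a single circular replicon with
  canonical G-excess-on-leading skew; plasmids, linear chromosomes or
  inverted-skew taxa will mislabel.
- The D(A,B) distance is bounded by 0.5, not 1: cosine similarity of
  non-negative RSCU vectors cannot be negative.
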