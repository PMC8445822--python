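# Methods

`paleosyn` implements the comparative-genomics inference chain used to read
whole-genome duplication (WGD) history and ancient chromosomal
rearrangements off genome comparisons anchored by an unduplicated reference
genome, together with the gene-tree and co-expression analyses that
accompany such studies. This note records the models, the parameters that
matter, the numerical choices, and what the bundled simulator does and does
not emulate.

## Synteny blocks

Homolog hits (BLAST tabular style) are reduced to candidate anchors per
query gene: hits with e-value > 1e-5 or bitscore < 100 are dropped and at
most the top 10 per query survive, ranked by descending bitscore with
deterministic tie-breaking (ascending e-value, then subject id). Chaining
operates on gene ranks, not base pairs: rank gaps are what the anchor-gap
parameter of the MCScanX tool family means, and rank arithmetic is
invariant to intergenic-length variation. Within each chromosome pair a
dynamic program finds the maximum-cardinality collinear chain (query ranks
strictly increasing, subject ranks strictly monotone in either direction so
inversions form descending blocks, consecutive anchors ≤ `max_gap` = 25
ranks apart on both genomes); the best chain is extracted, its anchors
removed, and the search repeated until no chain reaches `min_block_genes` =
11 anchors ("more than ten genes"). Iterated greedy extraction rather than
a simultaneous multi-chain optimum keeps the procedure deterministic and
mirrors standard practice; the DP itself is certified against exhaustive
chain enumeration in the test suite. Each anchor belongs to at most one
block so that depth counting cannot double-count a block's own anchors.

Tandem arrays — consecutive same-family genes within `max_gap` ranks — are
collapsed to their lowest-rank representative before chaining (on by
default, configurable). Without this, local duplications masquerade as
elevated syntenic depth. In a self-comparison the identity diagonal is
excluded; paralogous self-synteny remains visible.

## Syntenic depth and WGD rounds

The depth of a reference gene is the number of *distinct* regions of the
other genome covering it. Coverage is by block rank span, not anchor
membership: post-WGD fractionation thins anchors inside genuinely duplicated
regions, and span coverage matches how dotplot depth is read by eye. Two
blocks covering the same reference gene count as one copy when their spans
on the other genome overlap reciprocally by ≥ 50% — split blocks from one
copy must not inflate depth; truly distinct copies sit on different
chromosomes or well-separated spans and are unaffected.

A profile is summarized by the mode of its nonzero depths (robust to
unaligned and over-retained segments), and the reciprocal pair of modes
forms the depth ratio, printed with the unduplicated side first: 1:2 after
one WGD, 1:4 after two, 1:8 after three. `infer_wgd_rounds` takes log2 of
each side; a mode that is not a power of two is reported with its two
nearest power-of-two candidates and a warning rather than silently rounded.
The supporting fraction of genes at the modal depth is always reported;
thresholds on it are left to the caller.

## Ks estimation and peak fitting

Synonymous divergence is estimated by the Nei–Gojobori (1986) method under
the standard genetic code: per-codon synonymous site fractions (changes to
stop codons count nonsynonymous), observed differences apportioned by
equal-weight averaging over all minimal mutational pathways (pathways
through stop codons excluded; if all are blocked they are readmitted with
stop transitions counted nonsynonymous), sites averaged over the two
sequences, and the Jukes–Cantor correction dS = −(3/4)·ln(1 − (4/3)·pS).
Estimates with pS ≥ 3/4 are saturated and flagged invalid instead of
raising. Gap or ambiguity codon columns are dropped pairwise; a shared
terminal stop codon is trimmed. The implementation agrees with Biopython's
NG86 routine to machine precision on simulated pairs (the library serves
only as an independent cross-check in tests).

Cohort Ks distributions are smoothed by a fixed-bandwidth Gaussian kernel
(default 0.05, the width used to read WGD peaks in practice) on a 512-point
grid over [0, `ks_max` = 3.0]; beyond Ks ≈ 3 the Jukes–Cantor correction is
saturation-dominated and peaks are not interpretable. The density is
boundary-reflected at 0 and `ks_max` so its integral equals the retained
sample fraction. Peaks are then located by fitting
f(x) = Σ aⱼ·exp(−(x−μⱼ)²/(2σⱼ²)) to the *curve* by bounded nonlinear least
squares — the manual curve-fitting workflow this models — adding one
component at a time and stopping at the first m whose R² exceeds 0.95.
Initialization uses the m highest local maxima of the density with σ
initialized at twice the bandwidth, plus a fixed number of seeded jittered
restarts, so reported models are deterministic. EM on the raw samples is
deliberately not the estimator (it answers a different question); it is an
oracle in tests.

A known consequence of the smallest-adequate-m rule: two overlapping
cohorts (separation below roughly two component widths) can be absorbed by
a single broad Gaussian whose fit already clears R² = 0.95, in which case
the rule honestly selects the smaller model and the older peak locations
merge (the second worked example shows exactly this on a three-cohort
mixture whose two older cohorts overlap). Resolving such cohorts requires
external evidence (e.g. depth ratios), narrower true peaks, or a stricter
adequacy threshold — the threshold is a parameter, but 0.95 is the
documented default.

Unequal substitution rates shift Ks peaks between lineages. `rate_correct`
rescales each lineage i by cᵢ = target / modeᵢ, where modeᵢ is the
lineage's modal Ks against a common reference species and the target is the
geometric mean of the observed modes — the geometric mean makes the
correction symmetric under exchanging fast and slow lineages and preserves
peak ordering. The choice of target is a convention of this package; any
common target yields the same *relative* alignment.

## Region adjacencies and ancestral reconstruction

Labelled chromosomal regions are curated intervals on a reference genome
(as such regions are defined by inspection of dotplots); automatic
breakpoint discovery is out of scope. A region projects into another genome
through each synteny block whose reference-side span covers ≥ 50% of the
region's gene span; the projected occurrence sits at the subject-side
anchor ranks, inherits the block's orientation, and nearby fragments (≤ 25
ranks) are merged. Unprojected regions are reported missing, never dropped
silently.

Consecutive occurrences on a chromosome yield an adjacency between their
facing ends (tail of a forward occurrence, head of a reversed one, etc.).
Each observed adjacency is an independent binary presence/absence character
on the rooted species tree — independence is the simplest defensible model;
reconstructed node states that jointly violate linearity (an end used
twice) are flagged, not repaired. Ancestral states are computed by
unit-cost Sankoff with an outside-cost down pass, which yields the *exact*
set of states attained in at least one most-parsimonious reconstruction:
nodes where both states are optimal are reported ambiguous rather than
resolved, because scenario arguments (shared fusion vs parallel fusion)
hinge on honest ambiguity. The change count equals the Fitch minimum and is
property-tested against brute-force enumeration. Synapomorphies of a clade
are the adjacencies present at its ancestor and absent — not ambiguous — at
the parent node; polarity therefore requires outgroup sampling, and a
character private to a two-taxon study design is correctly reported
ambiguous rather than synapomorphic.

Nested regions (a region embedded in another) are flattened to linear order
by start coordinate when building occurrence lists; containment is a
presentational annotation, not a separate character.

## Quartet support and the polytomy test

Gene-tree leaves are assigned to four groups (magnoliid-like G1,
monocot-like G2, eudicot-like G3, outgroup). Edges with bootstrap support
below a threshold (absent supports count as 100, so collapsing is opt-in
per edge) are contracted to polytomies first. Every quartet with one leaf
per group is resolved by the four-point condition on edge-count distances —
a tree metric with unit branch lengths, under which a polytomy-separated
quartet produces a three-way tie and votes unresolved. A tree votes once,
by strict majority over its quartets (matching per-gene-tree histograms);
ties vote unresolved. The polytomy test is a 2-df chi-square of the three
resolved counts against equal expectation — a transparent approximation to
coalescent-based polytomy tests, adequate because under the null every
resolved gene tree is an independent fair three-sided draw.

## Mutual-rank co-expression

Genes with TPM ≥ 1 in at least one sample (boundary inclusive) enter the
analysis. Pearson correlations are computed for all pairs across samples
(≥ 3 samples required; zero-variance genes excluded with a warning); for
gene a, rank_a(b) is b's 1-based position in a's partner list by descending
signed correlation (average ranks on ties, self excluded), and
MR(a,b) = √(rank_a(b)·rank_b(a)). Pairs with MR ≤ 300 are co-expressed.
Ranking by signed correlation places strong anti-correlations last;
anti-correlation networks are out of scope. The MR ≤ 300 cutoff is only
selective when the gene universe is much larger than 300 — on small
matrices every pair passes, which is a property of the statistic, not a
bug. Correlations are computed on a 64-byte-aligned copy of the matrix so
that repeated runs produce byte-identical edge tables.

## The simulator

The generator provides every pipeline input with known ground truth. Its
defaults are the package's reference study conditions:

* **Genomes.** An ancestral genome (4 chromosomes × 150 single-copy
  families by default) propagates down a rooted species tree with branch
  lengths in Ks units. WGD duplicates every chromosome and retains each
  duplicated gene independently with probability ρ (fractionation as
  i.i.d. Bernoulli; biased fractionation/subgenome dominance is a stated
  non-goal). Fusions, fissions, reciprocal translocations and inversions
  edit chromosome gene lists in event order. Gene i of a chromosome
  occupies [1000·i, 1000·i+500).
* **Divergence.** Each gene copy carries its lineage history; the true Ks
  of a pair is the rate-scaled branch length accumulated since their
  histories diverged (speciation, or WGD at a configurable position along
  its branch, default mid-branch). Homolog bitscores are a deterministic
  decreasing function of true Ks plus truncated-Gaussian Ks noise (sd 0.03
  by default), giving anchor filtering realistic top-hit structure.
* **Coding sequences.** Per pair, an ancestral sequence of 4-fold
  degenerate codons (families whose first/second-position single changes
  are all nonsynonymous, so each codon has exactly one synonymous site)
  diverges at third positions with Jukes–Cantor difference probability
  (3/4)(1 − e^(−4k/3)), making the expected Nei–Gojobori dS equal the
  requested k. Pairs with expected pS ≥ 0.7 are flagged as saturation
  risks. Sequences are emitted per pair, not per gene, since the estimator
  consumes pairs.
* **Gene trees.** Topologies drawn with concordance probability
  1 − (2/3)e^(−t) for one internal branch of t coalescent units, the two
  discordant resolutions at (1/3)e^(−t) each; support labels from a
  caller-supplied distribution.
* **Expression.** Module genes share a latent per-sample profile plus
  log-scale Gaussian noise (default sd 0.3), exponentiated to TPM-like
  values; background genes are pure noise. Defaults (3000 genes, 14
  samples, three 30-gene modules) represent a small multi-tissue RNA-seq
  panel at a scale where MR ≤ 300 is selective.

What the simulator does *not* emulate: nucleotide-level selection mixtures,
transposable-element dynamics, biased fractionation, segmental (non-whole-
genome) duplication, gene conversion between paralogs, and expression
compositionality artifacts. Passing tests therefore demonstrate that the
inference chain recovers the processes it models at realistic sizes and
noise levels — not that real genomes contain no further complications.

## Problem sizes and determinism

Reference experiment sizes (package choices, used by the benchmark script
and tests): depth-ratio runs use 600-gene ancestors (4 × 150) with
retention 0.8 per WGD and divergence Ks 1.5; Ks peak fitting uses 6000
draws; quartet tallies use 3000 trees. All randomness flows through
`numpy.random.default_rng` seeds carried by scenario objects or function
arguments; every emitted artifact is a pure function of (parameters, seed).

## Known limitations

* Depth profiles assume blocks from a single query species; multi-species
  joint profiling is out of scope.
* The greedy chain extraction is order-optimal per step, not globally
  optimal across chains; the gap to a simultaneous optimum is negligible at
  the block sizes of interest but unquantified in general.
* Adjacency characters are treated independently; correlated events (one
  translocation creating two adjacencies) are counted as separate changes.
* The polytomy test inherits chi-square small-count caveats below ~5
  expected trees per topology.
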