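# Methods

## Differential-expression filter

The substrate is a processed genes × samples matrix of non-negative
linear-scale signals with Affymetrix-style detection calls (P/A/M) and one
group label per sample. For a contrast A → B each gene gets

* a signed mean fold change: FC = mean_B/mean_A when ≥ 1, otherwise
  −mean_A/mean_B, so down-regulation prints as a negative magnitude and the
  magnitude is always ≥ 1;
* an unpaired two-sided Welch t-test p-value (unequal variances; the original
  analysis names only an "unpaired two-sided t-test", and Welch is the safer
  default for group sizes of 4–10 with tumor-inflated variances);
* a change-call concordance: the fraction of all n_A × n_B cross-group sample
  pairings whose sign agrees with the gene's overall direction. This stands in
  for the proprietary comparative-ranking change calls of the original
  vendor software; 100 % means every pairing moves the same way.

A gene is a DEG when |FC| ≥ FC₀ ∧ p ≤ p₀ ∧ concordance ≥ c₀. Two profiles are
shipped: tumor (3, 0.05, 1.0) and transgenic non-tumor (2.5, 0.05, 0.875).
Benjamini–Hochberg q-values are computed over all testable genes and reported,
but the filter itself uses raw p, matching the profile definitions. Genes with
a zero group mean or zero variance in both groups are skipped with a warning
(ratio or p undefined). The filter is monotone: tightening any threshold never
adds genes.

Percentages in report tables round half-up — one decimal for the
target-category breakdown (62.5 %, 41.4 %), nearest integer for module
coverage (15/24 → 63 %).

## Promoter scanning

Promoters are −1000..+100 bp around the annotated TSS (1100 bp), 0-based
half-open coordinates, minus-strand genes reverse-complemented, contig
overruns N-padded. The annotation supplies the TSS coordinate; the package
does not locate start codons itself.

Matrices load from JASPAR-style count text; a pseudocount (default 0.01 per
cell) precedes per-position normalization so that raw counts with zeros keep
the min–max normalization non-degenerate. Scoring uses the information vector
I(i) = Σ_b f(i,b) ln(4 f(i,b)) (0·ln 0 := 0, so I ∈ [0, ln 4]):

    Current(w) = Σ_i I(i) · f(i, w_i)
    mss = (Current − Min) / (Max − Min)

with Min/Max the extreme achievable Current; when Max = Min (an uninformative
matrix) the score is defined as 1. The core similarity applies the same
formula to the five consecutive most informative positions (leftmost window on
ties). N bases contribute the position's minimum frequency — the conservative
choice — and windows with more than 20 % N are skipped. A hit requires
css ≥ core cutoff and mss ≥ matrix cutoff; both strands are scanned and
minus-strand hits are reported at their plus-strand start offset. The scanner
is vectorized; tests hold it window-for-window equal to a naive per-position
reference implementation.

Default cutoffs are (core 0.75, matrix 0.80) and are configurable per matrix.
Because a fixed mss cutoff is far more permissive for short matrices than long
ones (a 6-bp E-box matrix exceeds 0.8 somewhere in almost every 1100-bp
window), `calibrate_matrix_cutoff` estimates the null mss distribution on
i.i.d. background and sets the cutoff at a target per-window false-positive
rate (default 1e-4, echoing the stringent per-matrix profiles distributed with
commercial matrix libraries). The end-to-end pipeline calibrates every matrix
this way, with the configured cutoffs as floors.

YES/NO sets: the YES set is the experimentally filtered DEG list; the NO
(background) set removes from the gene universe all DEGs under a relaxed
background filter (|log2 FC| > 0.5 and −log10 p > 3) and every gene carrying
at least one Myc-matrix hit, and is required to be non-empty. Per-matrix
enrichment is a one-sided Fisher exact test on the gene-level 2×2 presence
table (≥ 1 hit vs none, YES vs NO) with BH adjustment.

## Composite-module discovery

A composite module is a set of (matrix, score-cutoff) components — three by
default, matching the Myc + two-partner modules the method was built to find —
plus one shared pairwise distance bound D. A promoter fits the module when
every component has a hit with mss at or above its cutoff and one hit per
component can be chosen with every pairwise start distance ≤ D; because all
pairwise distances are bounded iff the selection's span is, the implementation
slides a span-D window anchored at each candidate start and takes each
component's best site inside it (vectorized with `searchsorted` +
`maximum.reduceat`; tests pin it to exhaustive enumeration). The module score
is the best achievable Σ of component mss, 0 for non-fitting promoters.

The fitness the GA maximizes is a documented reconstruction (the original
platform's multi-component function is unpublished):

    fitness = (mean_YES − mean_NO) / pooled_sd  −  penalty_rate · complexity

where the means and pooled standard deviation are over module scores on the
YES and NO promoter sets, and complexity is the mean normalized cutoff slack
plus the normalized distance slack (each in [0, 1]). The pooled sd is floored
at 0.1 so that perfectly separating modules are compared by their mean
separation and parsimony rather than by numerical noise; identical YES and NO
collections give separation 0 and hence fitness ≤ 0. The penalty rate (0.3
default) is interpreted as a complexity weight.

GA mechanics: size-3 tournament selection; elitism (elite carried unchanged,
making the best-fitness history non-decreasing); per-gene mutation of matrix
identity, cutoff and distance independently at the mutation rate; cutoffs
live on a 0.05 grid in [0.5, 1.0] and mutate by ±0.05, distances on
{25, 50, …, 500} bp. The finite chromosome space lets fitness evaluations be
memoized, which is what keeps the discovery runs fast. Ties in fitness break
toward smaller complexity, then lexicographic matrix ids, so runs are fully
reproducible for a fixed seed. Default full-scale configuration: 800
iterations, population 1000, non-change limit 800, elite 50, mutation 0.25,
penalty 0.3 (a 0.1-mutation variant is one constructor argument away); the
`fast` preset (100 iterations, population 200, elite 20) is used throughout
the test suite and recovers planted modules reliably at the 30 YES / 100 NO /
12-matrix scale.

An optional anchor constraint forces a designated Myc matrix into every
chromosome. Module coverage reports how many genes of a set fit the module,
with the integer half-up percentage.

## Master-regulator search

Over a directed interaction graph (activation / inhibition / plain regulation;
self-loops dropped, parallel edges collapsed keeping the more specific
annotation), a candidate's downstream cone is the set of nodes reachable along
edge direction within the radius (default 4). With d(v) the BFS distance and
decay γ (default 0.1):

    score = [ Σ_{inputs} γ^(d−1) − penalty · Σ_{non-inputs} γ^(d−1) ]
            / max(1, Σ_{all reached} γ^(d−1))

This reconstruction keeps the published parameter set meaningful on
desk-scale graphs: a candidate whose only reached node is one direct input
scores exactly 1, score ∈ [−penalty, 1], and as γ → 0 the ranking reduces to
counting direct input targets. Edge signs are carried through for reporting
but do not alter traversal. Significance comes from permuting the input set
uniformly over the network's nodes (sizes preserved): since reachability is
fixed, each candidate's null score is an affine function of the decay mass
falling on the permuted set, and the whole null is one weight-matrix ×
indicator-matrix product. Z-scores use the permutation mean/sd (degenerate
nulls get z = 0 with a warning), empirical p-values use +1 smoothing, and BH
gives q-values. A candidate passes at score ≥ 0.2, Z ≥ 1 and q ≤ 0.05.

The smallest empirical p with B permutations is 1/(B+1), so for a lone true
positive to clear BH at FDR α among N candidates one needs B ≳ N/α;
`recommended_permutations` applies this rule (with a 2× margin) and the
pipeline uses it automatically — around 12 000 permutations for a 300-node
graph, which the matrix formulation evaluates in under a second.

## Synthetic data

The generators are pure functions of (parameters, seed) and write the exact
formats the analysis stages read.

* **Expression**: per-gene baseline log2 levels ~ Normal(8, 1) across genes
  (microarray-typical dynamic range); replicates scatter around the baseline
  with log2 sd 0.25 (biological-replicate scale). Planted genes shift by the
  requested log2 effect in the case group; detection calls are P with flips to
  A at a configurable error rate. Only the filter logic, not probe chemistry,
  is modelled.
* **Promoters**: i.i.d. background at a chosen GC (default 0.45; a
  first-order-Markov background is not modelled — planted-recovery results
  therefore speak to filter logic, not to repeat-rich real promoters). Planted
  sites are sampled from the matrix conditioned on mss ≥ a floor (rejection
  sampling), placed non-overlapping, optionally confined to a span so that
  composite-distance constraints hold by construction; every placement is
  recorded in the truth object. Each gene gets its own contig with the TSS
  placed so both strand conventions are exercised.
* **Matrix library**: Dirichlet-sharpened random matrices of length 6–12 in
  JASPAR layout, led by a canonical CACGTG E-box matrix with mild central
  degeneracy (the E-box-like variants Myc tolerates).
* **Network**: Poisson out-degree background with uniform targets and edge
  types; a planted hub is wired to a chosen fraction of the input genes via
  paths of exactly the requested length. The hub gets no background out-edges,
  so its radius-1 reach is exactly the planted wiring.

Passing planted-recovery suites show that each stage recovers what its own
generative model plants; they do not certify performance on real microarray
noise, real promoter composition, or literature-mined network topologies.

## Problem sizes and numerical choices

The shipped benchmark sizes are 30 YES / 100 NO promoters with a 12-matrix
library for module discovery (10 seeds), 300-node networks with a hub wired to
18 of 27 inputs (20 seeds), 400-gene expression panels at n = 10 per group
(5 seeds), and 200 promoters for scanner/reference agreement — small enough to
run in minutes on one CPU while leaving every planted object comfortably
recoverable. Rounding of report percentages is decimal half-up. Decimal output
uses periods even where the original tables print comma decimals.

Known limitations: the GA fitness and master-regulator score are
reconstructions of unpublished commercial functions and reproduce their
parameter semantics, not their exact values; concordance is computed from
signals rather than vendor change calls; per-matrix cutoff calibration is
sampling-based (deterministic per seed) rather than exact tail enumeration;
and sign information in networks is reported but not propagated.
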