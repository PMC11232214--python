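# Methods

## The statistical problem

Noncanonical ORFs sit orders of magnitude below canonical genes in
expression and are detected (count ≥ 5) in only a fraction of samples.
Treating their undetected entries as zeros poisons correlation estimates;
discarding sparsely detected ORFs removes the objects of study. The
pipeline therefore works pairwise-complete: an entry is either detected
(count ≥ 5) or missing, and every pairwise statistic uses only the samples
where both ORFs are detected, subject to a minimum shared-sample gate.

## Expression model and transforms

**clr.** For sample *j* with detected counts *x*, clr(x)ᵢ = ln xᵢ − mean of
ln x over the detected ORFs of that sample. Natural log is used throughout
(ρ is invariant to the base; a convention is needed for printed values).
Detected clr entries sum to zero per sample and are invariant to rescaling
the sample's detected counts.

**TPM.** TPMᵢ = 10⁶·(cᵢ/Lᵢ)/Σⱼ(cⱼ/Lⱼ) per sample; ORF summaries are
medians across all samples.

**Detection gates.** Default min_count = 5 with the boundary at ≥ 5 (the
spelled-out rule "count ≥ min_count"), and min_samples = 400 detected
samples per ORF / min_shared = 400 shared samples per pair for the
full-compendium setting. On the 500-sample synthetic study these gates are
scaled to min_samples = 100 and min_shared = 80: noncanonical ORFs are on
in ~45% of samples, so two independent noncanonical ORFs share ~100
detected samples, and a 400-sample gate would simply delete the class the
pipeline exists to keep.

## Proportionality and normalization

ρ = 2·cov/(var+var) is computed for all pairs via masked cross-products
(five matrix multiplications give shared counts, sums, squares and
cross-products), with sample (n−1) variances; the denominator choice
cancels in ρ. Pairs with fewer than min_shared shared samples or zero
variance are missing, never zero.

**SpQN.** ORFs are ranked by mean clr and cut into `n_groups` equal-size
strata; for each unordered stratum pair the non-missing ρ values are
quantile-mapped (linear interpolation between 1000 empirical quantiles)
onto the highest-expression × highest-expression bin. The map is monotone,
so within-bin rank order and the missingness pattern are preserved
exactly; symmetry holds because a pair's bin is unordered. This is a
simplification of the published estimator, which uses overlapping inner
and outer windows; with non-overlapping bins the method is exactly
specified and testable, at the cost of hard bin boundaries.

*Stratum count at small scale.* The default of 10 strata presumes enough
ORFs that every bin-pair holds thousands of values. With ~300 ORFs a
10-strata reference bin holds only ~435 pairs and its empirical quantile
function is dominated by sampling noise — depending on the draw it either
lacks a high tail (compressing genuinely coexpressed pairs) or overweights
one (inflating background pairs). `run_all` therefore caps the stratum
count so each stratum holds at least ~60 ORFs; 10 strata engage from ~600
ORFs upward. This is a bin-size floor, not a change to the method.

## Thresholds and network

Two rules are provided: the top-fraction rule (default 0.2% of non-missing
pairs, strict ">", matching the convention that an edge *exceeds* the
threshold) and the coverage rule (smallest threshold whose "≥" rule keeps
the best-partner ρ of ≥ 90% of canonical ORFs — the selected order
statistic is attainable, hence "≥"). Nodes without a passing pair are
excluded from the network.

**Null model.** Degree-preserving double-edge swaps restricted to edges
with at least one noncanonical endpoint: proposals creating self-loops,
duplicate edges, or canonical–canonical edges are rejected, so the
canonical subnetwork is conserved byte-identically and every node keeps
its degree (no node can be disconnected; components may still split, which
is a graph-level, not node-level, event). At least 10·|E| proposals are
attempted per replicate. Diameter on a disconnected graph is the maximum
over components; transitivity is the global 3·triangles/triples ratio.
Empirical two-sided rank p-values use the add-one rule.

## Modules

Adjacency a = max(ρ, 0)^β with β = 12 (negatives clipped: the network is
unsigned, and the handling of negative normalized ρ is otherwise
undefined), TOM similarity

TOMᵢⱼ = (Σᵤ aᵢᵤaᵤⱼ + aᵢⱼ)/(min(kᵢ, kⱼ) + 1 − aᵢⱼ),

Ward linkage on 1 − TOM, and a branch cut at a fixed fraction of the
merge-height range; branches with ≥ min_cluster_size (20) members become
clusters, the rest are unassigned (label 0). The cut fraction defaults to
0.5: the familiar 0.99 convention comes from average-linkage trees whose
heights are bounded by the dissimilarity scale, whereas Ward merge heights
grow with cluster mass, so the top few merges dominate the range and a
0.99 cut keeps only the final one or two splits. On planted-module data
any fraction in 0.3–0.7 recovers the modules exactly; 0.5 is the center of
that plateau.

Cluster GO enrichment is a one-sided Fisher test of each cluster's
canonical members against the canonical background, BH-corrected across
all (cluster, term) tests; clusters with < 5 canonical members are
skipped. Each cluster's noncanonical fraction is reported alongside.

## Function-level analyses

**Preranked GSEA.** For a query ORF, annotated ORFs are ranked by ρ to the
query (ties broken by ORF id; the query excluded). The running sum adds
|ρ|/Σ|ρ| at hits and subtracts 1/(N−n) at misses; ES is the extreme
deviation. Significance comes from gene-label permutations — random sets
of the same size drawn from the ranked list — with the p-value conditional
on the ES sign and floored at 1/(n_perm+1); BH across terms per query;
"enriched" means FDR < 0.01. The permutation scheme replaces the adaptive
multilevel estimator used by fgsea: it is exactly defined, and the sample
sizes here make the floor (≈ 1/1000 at the 2000-permutation default)
sufficient for the FDR-0.01 call.

**Prevalence.** Per term, a Fisher test on enriched/not × class, BH
correction, and a proportion ratio (noncanonical proportion over canonical
proportion — reported under that name; a sample odds ratio is emitted
alongside). Flagging uses FDR < 0.001 and ratio > 2 (or < 0.5).

**Neighbor voting.** Terms of 20–1000 genes; 3-fold cross-validation;
a hidden gene's score is Σw·y/Σw over training neighbors; AUROC separates
hidden positives from hidden negatives; the mean over folds is reported.

**GO similarity.** Schlicker Relevance: sim(t₁,t₂) = max over common
ancestors a of [2·IC(a)/(IC(t₁)+IC(t₂))]·(1−p(a)), with p(t) the fraction
of annotated genes at or below t and IC = −ln p. Term sets (each ORF's
FDR < 0.01 GSEA terms) are compared by best-match averaging: the mean of
row maxima and column maxima.

## Genomic context

Coordinates are 0-based half-open; GFF3 converts at the boundary. The gap
between ORFs is start₂ − end₁; "within 500 bp" means gap ≤ 500 (gap 501 is
out of range). Orientation is judged in the conserved neighbor's
transcription direction, so up_opposite is divergent and down_opposite
convergent; conflicting in-range neighbors yield "ambiguous", none yield
"independent". Conservation labels come from reading-frame-conservation
and homology tables: conserved if mean RFC > 0.8 or an outside-genus
tblastn/blastp hit at e < 1e-4; de novo if translated, without such hits,
without a self-blastp hit to a canonical ORF, not same-strand overlapping
a canonical ORF, and with both most-distant-branch RFCs < 0.6.

TSS = median (lower-middle on even counts, keeping it integer) of the
start positions of same-strand isoforms fully covering the ORF; TF binding
requires a site overlapping [TSS−200, TSS) ('+') or (TSS, TSS+200] ('−').
Promoter sharing: down/up-same pairs share iff one isoform covers both
ORFs; up-opposite pairs share iff both are covered and no isoform covering
one contains the TSS of an isoform covering the other (one concrete
reading of "non-overlapping TSSs"). A conserved ORF absent from the
isoform data makes the call missing; an absent de novo ORF means "not
shared". The shared-transcript fraction is covering-both / covering-de
novo. Terminator interruption requires a Pcf11/Nrd1-type site strictly
inside the intergenic gap.

Piggybacking contrasts (Cliff's delta + Mann-Whitney, exact for small
groups) compare expression (piggybacking-capable vs independent de novo
ORFs), neighbor-ρ and GO similarity (capable vs incapable orientations),
neighbor-ρ (sharing vs non-sharing within each capable orientation) and
shared-transcript fraction (terminator-present vs absent down-same
pairs). Only single-orientation de novo ORFs enter the table.

## The synthetic generator

What it emulates: log relative expression = class baseline + module
loading × per-sample latent factor + N(0, noise_sd); Poisson counts at
depth × relative abundance (gamma-Poisson when dispersion > 0);
noncanonical ORFs carry an on/off indicator per sample (off entries draw
from a near-zero rate 0.1), giving the two-strata detection pattern;
sharing down-same pairs receive an additive λ-fraction of the conserved
neighbor's expected count (readthrough on the expected-count scale, the
way a shared transcript contributes reads to both ORFs).

Defaults and why: 150 + 150 ORFs × 500 samples (large enough for stable
pairwise-complete ρ at the scaled gates, small enough for second-scale
runs); baselines ln-TPM 3.0 vs 0.5 (sd 0.7) separate the class strata by
roughly an order of magnitude; detection fraction 0.45 puts most
noncanonical ORFs below 50% detection while keeping ~100-sample pair
overlaps; module loading 1.5 vs noise 0.3 makes within-module ρ ≈ 0.95;
five modules of 20–30 members with canonical fractions cycling
0.9/0.1/0.9/0.1/0.5 plant both canonical- and noncanonical-majority
modules; λ = 0.5 readthrough; 20 down-same pairs with terminator fraction
0.5 give ~10 sharing vs ~10 interrupted pairs, enough for an exact
Mann-Whitney far below p = 1e-3 when the groups separate; 8 + 8 + 6 + 6
pairs in the other orientations and 10 independent ORFs. One global seed
spawns child generators per stage, so outputs are byte-identical per
configuration.

What it does **not** emulate: batch effects beyond depth variation,
isoform-level read assignment, length biases, overdispersion by default,
correlated on/off states, or expression coupling for up-same/up-opposite
sharing pairs (only down-same readthrough is planted). Passing tests
therefore certify the machinery — transform identities, oracle
equivalence, exact recovery of planted structure — not performance on real
compendia, where signal fractions, library artifacts and annotation errors
are harsher.

## Numerical choices and degenerate inputs

Zero-variance pairs and short-overlap pairs are missing, not 0; p-values
are floored at the smallest positive double (permutation tests at
1/(n_perm+1)); two-sided Fisher uses the probability-mass rule; the odds
ratio CI is Woolf-logit with a 0.5 cell correction when a cell is empty;
Mann-Whitney is exact (scipy's distribution, or full enumeration under
ties when C(n+m, n) ≤ 2·10⁵) for n_x·n_y ≤ 400 and
tie/continuity-corrected asymptotic otherwise; Cliff's delta is derived
from U, which equals the pairwise win–loss count exactly. All-identical
dissimilarities collapse to a single cluster; an all-undetected sample
becomes all-missing with a warning; empty contrast groups are reported
missing rather than raising errors.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run the default 300-ORF ×
500-sample study (scaled gates 100/80, SpQN strata capped at 5, GSEA 2000
permutations, 200 null networks); oracle tests use 20 × 500 dense matrices
(ρ), 30-node matrices (TOM), graphs up to 50 nodes (topology), a 500-node
graph (randomization contract), and 20 seeds of an 160-ORF × 300-sample
study for the λ = 0 null contrast.

## Known limitations

- SpQN with hard equal-size bins distorts values near bin boundaries; at
  the 300-ORF scale occasional seeds show compressed or inflated pair
  values at bin tails (the module-recovery and contrast results quoted in
  the README are seed-reproducible; across random seeds the sharing
  contrast occasionally lands at p ≈ 1e-3–5e-3 instead of < 1e-3).
- The branch cut is a static height cut, not the adaptive hybrid variant;
  very unbalanced module sizes may need a different cut fraction.
- The GSEA null is gene-label permutation, which ignores inter-gene
  correlation; on strongly modular data its p-values are conservative for
  terms overlapping a module.
- Conservation classification consumes precomputed RFC/homology tables;
  it does not run alignments.
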