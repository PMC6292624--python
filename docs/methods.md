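# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `mitocline`. Everything quantitative here is computed by the
test suite or by `scripts/acceptance.py`; nothing is asserted that the code
does not reproduce.

## The synthetic cohort model

The generator exists because the registry genotypes behind large neonatal
mtDNA surveys cannot be deposited. It emulates exactly the statistical
structure the downstream analysis consumes, in three seeded layers.

**Frequencies.** A `FrequencyModel` holds per-region haplogroup proportions
at a base year plus additive per-year trends, applied uniformly across
regions; realized vectors are clipped at zero and renormalized, so every
region-year stratum is a proper probability vector. The default
(`denmark_model()`) is calibrated to the published five-region distribution
of a 24,216-sample Danish birth cohort and to its period comparison
(1981–1986 vs 2000–2005):

* trends for the aggregate L clades, macro-haplogroup M and haplogroup U are
  the printed period endpoints divided by the 19 years between period
  midpoints (L ≈ +0.00054/yr, M ≈ +0.00074/yr, U ≈ +0.00084/yr);
* the published regional values are whole-period means, 12 years of trend
  past the 1981 base year, so trended rows are anchored by scaling each
  regional value by the national base/mean ratio `1 − 12·τ/p̄`. The
  multiplicative form preserves regional enrichment ratios and avoids
  clipping small regional frequencies (an additive offset would push
  several regional L frequencies below zero and bias the early-period level
  upward);
* published rows that mix reporting levels are resolved to concrete tree
  nodes: H, U, J, K and T are split into their sub-haplogroups and the L and
  M rows into their constituent clades, proportional to the published
  within-clade distributions, with the trend distributed by within-row
  share. This makes simulated cohorts exercise all three classification
  levels.

Regional sampling weights default to the published per-region sample counts
(6,818 / 3,550 / 5,660 / 4,957 / 2,632). Within-region metropolitan
fractions are not published; the defaults (Capital 0.75, Central 0.35,
South 0.25, North 0.30, Zealand 0.10) reflect which regions contain the four
major cities and are a free configuration parameter. Haplogroup frequencies
do not differ between metropolitan and rural strata in the model — the
published metropolitan enrichment of L/M is driven by the Capital region's
weight, which the model does capture only partially.

**Genotypes.** Each sample carries the derived allele at every defining
variant on its root→true-haplogroup path and the ancestral allele elsewhere;
haplotypes are tree-path constructs, not sequence evolution (no coalescent,
no mutation clock). Private mutations flip non-path loci independently at a
configurable rate — never the sample's own defining positions, which keeps
classification identifiable; homoplasy stress-testing would need a separate
flag. Missingness masks calls independently.

**Intensities.** The intensity layer inverts the caller: REF calls draw
Norm Theta from a clipped Gaussian around 0.05 and ALT around 0.95; a
configurable fraction of records is relocated into the AB band (theta in
0.40–0.60) or below the 0.08 Norm R floor. Missing input calls always emit
low-intensity records so that noise-free simulation → calling round-trips
exactly. What this does *not* emulate: per-locus cluster geometry differences,
correlated (sample-wide) intensity failures, and genuine heteroplasmy
gradients. Passing round-trip tests therefore validate the threshold logic,
not robustness to array artifacts beyond these noise modes.

## Genotype calling

Calls are haploid over {REF, ALT, MISSING}: records with Norm R < 0.08 are
rejected; otherwise theta ≤ 0.25 → REF, theta ≥ 0.75 → ALT, and the open AB
band between them → MISSING. The published pipeline adjusted theta clusters
manually per locus; the fixed symmetric band is the reproducible surrogate,
with per-locus `(ref_max, alt_min)` overrides available. Sample QC keeps a
sample iff its call rate is ≥ 0.97 (strict inequality rejected at exactly
the threshold is *not* used — the comparison is ≥). The threshold type
requires a strictly positive call-rate floor; loci with zero non-missing
calls are retained as uninformative columns so PCA dimensionality never
changes silently.

## Hierarchical classification

Classification descends the haplogroup tree greedily from the root. At each
step, each *callable* child (≥ 1 panel-typed defining variant; the panel
binding marks nodes uncallable when their defining variants are absent, as
with arrays that cannot separate HV from R) is scored on its own defining
set: observed = non-missing calls, matched = calls equal to the derived
allele. A child is accepted when observed ≥ 1 and matched/observed meets the
level floor — 1.0 at the macro level, 0.5 below. Strict-at-root/lenient-below
is this package's surrogate for the survey's manual "unequivocal" matching,
whose exact criterion was never stated; the resulting few-percent unassigned
rates at the deeper levels are qualitatively, not numerically, comparable to
the published ones. Ties break on higher matched count, then
lexicographically smaller name — deterministic by construction. Back-mutations
at ancestral nodes are not penalized (only the candidate's own defining set
is scored); a `cumulative` mode scores the whole root-to-candidate set
instead.

The greedy descent is verified against an exhaustive oracle (score every
root-to-node path, keep paths qualifying at every step, select by the same
per-step key) on hundreds of random trees. One caveat is documented rather
than asserted: "masking calls can never turn an unassigned level into an
assigned one" holds for genotypes consistent with a tree path, but not
unconditionally — masking a *mismatched* defining call raises the matched
fraction and can newly qualify a node.

Sub-haplogroup output can be reported in the merged bins used by published
tables (H1-H30b-H79a, H5-36, U2-U3, U4-9) via a built-in label map.

## Median-joining networks

Inputs are distinct binary haplotype vectors with multiplicities. The
pipeline mirrors classical practice for mtDNA arrays:

1. *Frequency filter*: drop haplotypes observed fewer than `min_count` times
   (the "frequency > 1" setting keeps multiplicity ≥ 2). The parameter
   string in the source survey is interpreted as exactly this singleton
   filter.
2. *Star contraction* (radius 5 for large clades, 1 for small ones): a
   cluster is a center plus ≥ 2 satellites within the Hamming radius, each
   strictly closer to the center than to any haplotype outside the cluster;
   satellites merge into the center with summed multiplicity. Centers are
   scanned by decreasing multiplicity with restart after each merge, to a
   fixed point.
3. *Median joining*: iterate between the ε-relaxed minimum spanning network
   (an edge (u,v) is included iff d(u,v) ≤ T(u,v) + ε, where T is the
   bottleneck threshold computed from an MST of the complete Hamming graph;
   ε = 0 yields the union of all MSTs) and quasi-median insertion: for every
   connected triplet, the majority-per-position vector is added if new.
   All positions carry weight 1, so ε is in mutation-count units and the
   conventional "epsilon 10" maps directly. Processing order is
   lexicographic on vectors, making output deterministic. After closure,
   median nodes of degree ≤ 2 whose removal leaves the minimum spanning cost
   of the remaining set unchanged are discarded. A safety cap (5,000 nodes)
   aborts pathological median explosions at large ε; pre-processing with the
   filter and star contraction is the intended remedy.
4. *Maximum-parsimony pruning*: keep exactly the median nodes and edges
   participating in at least one minimum-total-length spanning subgraph
   connecting all observed haplotypes. Up to 12 network nodes this is
   exhaustive over median subsets (edges tested with the MST cut criterion);
   above that a greedy heuristic removes medians whose deletion does not
   increase the spanning cost, and the output records
   `params["mp_mode"] = "heuristic"`. Observed haplotypes are never deleted
   and connectivity is an enforced invariant.

Test oracles: brute-force MST on perfect-phylogeny (ancestry-closed) inputs,
brute-force quasi-median closure on small sets, and exhaustive spanning-
subgraph enumeration for the MP step.

## Structure PCA

The genotype matrix is encoded 0/1 with missing calls imputed to the locus
mean (all-missing loci become zero-variance columns); a `drop` policy
removes incomplete loci instead. PCA is a column-centered SVD — no variance
scaling, since scaling binary data would explode the influence of rare
variants (a flag can be added by scaling the input). Signs are fixed by
making each component's largest-magnitude loading positive, so results are
bit-for-bit reproducible and sample-order invariant up to row permutation.
Components beyond numerical rank are flagged. Cluster separation on PC
planes is summarized by per-label centroids, RMS dispersion and pairwise
centroid distances — the quantitative surrogate for visual cluster plots;
no formal "new cluster" test is defined for period comparisons because the
underlying survey defines none.

## Frequency statistics

Crosstabs count samples per group (region, period bin, metropolitan/rural,
or calendar year) × haplogroup at a chosen level; unassigned samples tally
in an "NA" column, and a `paper` level reproduces the merged reporting bins
of the published tables (L and M as whole macro-haplogroups; I, W, X split
out of N; haplogroup labels within R).

The 2×2 test is the two-sided Fisher exact test in the point-probability
(minimum-likelihood) convention: p sums hypergeometric probabilities not
exceeding the observed table's probability, with a 1 + 1e-7 relative
tolerance on the comparison — the convention of standard exact-test
routines, and the one that reproduces the published p-values at printed
precision (L 1.14e-10, M 3.73e-08, H 2.98e-03, J 0.53). For r×c tables a
Monte-Carlo permutation version shuffles column labels across samples, uses
the table point probability as statistic, and reports the add-one estimator
p = (1 + hits)/(n_perm + 1), which cannot return zero; 2×2 inputs delegate
to the exact routine. The published survey's permutation scheme was not
specified beyond a citation; the exact 2×2 computation is used for all 2×2
comparisons and validated against the printed values.

Bonferroni correction compares p ≤ α/m with m defaulting to the number of
comparisons; the published tables use m = 14 (13 haplogroup bins + NA). At
α = 0.05 the L and M period increases are significant and U (p ≈ 0.0195) is
not; H (p ≈ 0.00298) also falls below the 0.05/14 ≈ 0.00357 threshold —
the decision rule is applied mechanically, without narrative exceptions.

Yearly trend series report per-year counts, denominators, proportions and
Wilson 95% intervals, optionally with the denominator restricted to one
macro-haplogroup (e.g. U within R). Slopes are estimated by weighted least
squares with per-year denominators as weights; synthetic-recovery tests
require agreement with the configured trend within 3 standard errors.

## Problem sizes and determinism

All randomness flows through explicit integer seeds into per-operation
`numpy` Generators; identical seeds give bit-identical outputs. The test
suite uses cohorts of 200–50,000 samples; `scripts/acceptance.py` uses 2,000
samples for the full intensity→caller→classifier round trip and a
1,000,000-sample cohort (metadata layer only) for the simulated period
frequencies, sizes at which the binomial noise on a 0.2% frequency is well
below the reported precision. Seeds passed via `--seed` are expanded with
`numpy.random.SeedSequence` spawning.

## Known limitations

* The bundled haplogroup tree is an example: it covers the macro/hg/sub-hg
  label set of Northern European surveys with PhyloTree-style positions,
  kept globally unique; it is not the full PhyloTree and real recurrent
  mutations (homoplasy) are deliberately absent.
* The classifier's acceptance rule is a surrogate for unstated manual
  criteria; unassigned fractions match published ones only qualitatively.
* The MP heuristic above 12 nodes is not guaranteed minimal; the mode is
  recorded in the output for that reason.
* Genomic-ancestry estimation (ADMIXTURE-style) and any use of nuclear
  markers are out of scope.
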