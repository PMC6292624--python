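# mitocline

Spatio-temporal analysis of mitochondrial DNA haplogroups in large birth
cohorts, built for array-based surveys in the style of the Danish neonatal
screening biobank (24,216 newborns, 418 mtDNA SNPs, birth years 1981–2005).

Mitochondrial haplogroups (hgs) are matrilineal clades diagnosed by sets of
*defining SNPs* in rCRS coordinates (PhyloTree nomenclature): the deep
macro-haplogroups L0–L6, M, N and R, their haplogroups (H, U, T, J, K, …) and
sub-haplogroups (H1, U5a, …). Their frequencies carry geographic and
demographic signal: regional clines, metropolitan/rural contrasts, and —
over a 25-year birth window — immigration-driven rises of the otherwise rare
L, M and U clades. Because the raw registry genotypes behind such surveys are
protected, the package pairs every analysis stage with a synthetic-cohort
generator that reproduces the published frequency structure, so the whole
pipeline is testable end to end.

## Pipeline

| stage | module | what it does |
|---|---|---|
| synthetic cohorts | `mitocline.simulate` | region/year/metro metadata, true haplogroups from a trend-aware frequency model, tree-path genotypes, array intensities |
| genotype calling | `mitocline.caller` | haploid calls from (Norm R, Norm Theta): reject R < 0.08, REF/ALT theta clusters at 0.25/0.75, AB band → missing, 97% sample call-rate QC |
| classification | `mitocline.tree`, `mitocline.classify` | greedy root-to-leaf descent over a defining-SNP hierarchy; macro/hg/sub-hg calls with per-level diagnostics |
| haplotype networks | `mitocline.network` | frequency filter, star contraction, Bandelt median-joining (quasi-medians under an ε-relaxed minimum spanning network), maximum-parsimony pruning |
| structure PCA | `mitocline.pca` | centered PCA of the 0/1 SNP matrix with a deterministic sign convention; cluster-separation summaries |
| frequency statistics | `mitocline.stats` | region/period/area crosstabs, two-sided Fisher exact tests (point-probability convention), Monte-Carlo permutation tests for r×c tables, Bonferroni correction (m = 14), yearly trend series with Wilson intervals |

The statistic at the heart of the temporal analysis is the two-sided Fisher
exact test on the focal-haplogroup 2×2 collapse

```
            hg      not hg
period 1     a        b
period 2     c        d
```

with p = Σ { P(T) : P(T) ≤ P(observed) } over tables with the observed
margins, compared against the Bonferroni threshold α/m with m = 14
simultaneously compared groups (13 haplogroup bins + the unassignable
column).

## Worked example

`examples/05_period_comparison.py` rebuilds the published 1981–1986 vs
2000–2005 period table from the printed tallies and tests every haplogroup
bin:

```
haplogroup  p-value     significant after Bonferroni (m=14)
L           1.14e-10      True
M           3.73e-08      True
H           0.00298      True
U           0.0195      False
...
J           0.531      False
```

The L and M increases (0.2%→1.2% and 1.0%→2.4%) survive correction — the
immigration signal — while U (p ≈ 0.02) does not at the corrected threshold
0.05/14 ≈ 0.0036. `examples/01_simulate_cohort.py` shows the synthetic
generator reproducing the same structure from scratch:

```
Period frequencies of the trending clades (%):
haplogroup     L     M      U
1981-1986   0.21  1.10  12.58
2000-2005   1.06  2.24  13.60
```

The other examples demonstrate intensity calling + classification (noise-free
round trips recover 100% of generating haplogroups; realistic noise ≈ 98%),
median-joining networks, and PCA macro-clade separation.

A thin CLI mirrors the stages:

```
mitocline simulate --n 5000 --seed 1 --out-prefix demo
mitocline call --intensities demo.intensities.tsv --out-prefix called
mitocline classify --ped-prefix called --out calls.tsv
mitocline stats --calls calls.tsv --meta demo.cohort.tsv --grouping period --out stats.tsv
mitocline network --ped-prefix called --epsilon 10 --star-radius 5 --out net.graphml
mitocline pca --ped-prefix called --k 10 --out-prefix pca
```

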