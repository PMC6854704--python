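# rimap

eQTL mapping and downstream analysis for recombinant-inbred (RI) mouse
panels: genome-wide miRNA/mRNA expression QTL scans on strain distribution
patterns, permutation-based significance, eQTL hotspot detection, causal
mediation screening, and bootstrap-averaged Gaussian Bayesian networks.

## Who this is for

RI panels (such as the LXS panel of ~59 strains derived from the Inbred Long
Sleep × Inbred Short Sleep cross) isolate genetic variability: every strain
is genetically fixed, perpetually renewable, and measurable in replicate.
`rimap` is for researchers mapping the genetic control of expression traits
on such panels — finding which loci drive which miRNAs or genes, whether a
locus is a *master regulator* of many transcripts, and whether a miRNA
mediates the path from genotype to gene expression (or the reverse).

## The models

**Mapping.**  Genotypes are 0/1 strain distribution patterns (SDPs): SNPs
sharing an allele pattern across strains collapse to one marker anchored at
the median SNP position.  For each trait y (strain means) and SDP g, marker
regression gives

    LOD = (n/2) · log10(RSS₀ / RSS₁)

where RSS₀/RSS₁ are residual sums of squares about the grand mean and the two
genotype-group means.  Each trait keeps its genome-wide peak; significance is
a permutation p-value for the max-LOD statistic with the exact-test
correction p = (b+1)/(B+1) (never zero; 0.0010 at B = 1000), followed by
Benjamini–Hochberg FDR across traits.  Peaks get 95% Bayes credible
intervals (mass ∝ 10^LOD on the peak chromosome) and cis/trans labels (cis =
same chromosome, within 5 Mb of the trait's locus).

**Hotspots.**  Under a uniform scatter of eQTL, counts in 4-SDP bins are
Poisson with mean λ = eQTL/bins; a bin is a hotspot when its count reaches
the smallest k with P(X ≥ k; λ) < 0.05/bins, and adjacent significant bins
merge.

**Mediation.**  For triplets (SDP, miRNA, gene) sharing an SDP, the
Baron–Kenny equations m = α₁+a·g, y = α₂+c·g, y = α₃+c′·g+b·m give the
indirect effect a·b, with a 99.5% percentile bootstrap CI over strains.

**Networks.**  Gaussian Bayesian networks over {SDP, miRNAs, genes} are
learned by BIC hill-climbing with all edges into the SDP forbidden, then
model-averaged over 500 strain bootstraps: edge strength = fraction of
resampled networks containing the edge, kept at ≥ 50%, signed by Spearman
correlation.

See `docs/methods.md` for assumptions, defaults and numerical details.

## Worked example

Simulate an LXS-like panel with one planted cis eQTL whose genetic effect
accounts for half the strain-mean variance, then scan it:

```python
from rimap import (EqtlScan, SimConfig, simulate_genotypes, plant_structures,
                   beta_for_variance_fraction)
from rimap.simulate import PlantedEqtl

cfg = SimConfig(n_strains=59, n_reps=3, n_chromosomes=5,
                snps_per_chromosome=100, ld_persistence=0.9,
                n_mirna=50, n_mrna=1, icc_target=0.3, seed=1)
panel = simulate_genotypes(cfg)
beta = beta_for_variance_fraction(0.5, 0.3, 3)   # genetic share 0.5
cfg = SimConfig(**{**cfg.__dict__, "planted_eqtl":
                   (PlantedEqtl("miR-0000", panel.sdp_ids[42], beta, "cis"),)})
sim = plant_structures(panel, cfg)

res = EqtlScan(sim.mirna, panel).fit(n_perm=1000, seed=1)
print(res.summary())
print(res.to_table().loc[["miR-0000"]].to_string())
```

prints

```
eQTL scan results
=================
traits mapped:        50
strains:              59
SDPs:                 45
permutations:         1000 (seed 1)
significant (q<=0.05): 1
cis/trans among significant: {'cis': 1}

         eqtl_chr  eqtl_pos_mb  ci_lo_mb  ci_hi_mb   lod  genomewide_p   fdr cis_trans
trait
miR-0000        5        102.7      97.1     108.3  9.55         0.001  0.05       cis
```

The planted trait is the single significant hit: its peak sits at the planted
SDP on chromosome 5, LOD 9.55 means the genotype-split model fits ~10⁹·⁵⁵
times better than the flat model, no permutation reached the observed maximum
(p = 1/1001, printed 0.001), and the 5-Mb rule labels it cis.  The other 49
traits are null and stay below the FDR line.

The package also ships the worked-example tables of 38 significant brain
miRNA eQTL with their annotations.  Re-deriving the reference group
contrasts from them:

```python
from rimap import compare_groups, merged_fixture
print(compare_groups(merged_fixture()).to_string())
```

```
                          n_first  n_second           W             p             note
comparison
cis_vs_trans                   30         8  183.000000  2.307651e-02
annotated_vs_novel             30         8   59.000000  2.823856e-02
intronic_vs_nonintronic        14        24  229.000000  6.668107e-02
high_vs_low_conservation       15        20  108.000000  1.686902e-01
spearman_lod_icc               38        38    0.822596  2.366232e-10  rho in W column
```

cis eQTL are significantly stronger than trans (W = 183, p = 0.023), novel
miRNAs stronger than annotated (W = 59), and eQTL strength correlates tightly
with miRNA heritability (ρ = 0.82).

A command-line umbrella is included for shell use:

```bash
rimap simulate --out sim/ --seed 1
rimap map-eqtl --expr sim/mirna_means.tsv --geno sim/genotypes.csv \
               --map sim/map.tsv --perms 1000 --seed 1 --out hits.tsv
rimap hotspots --hits hits.tsv --geno sim/genotypes.csv --map sim/map.tsv \
               --n-traits 881 --out hotspots.tsv
```

plus `collapse`, `characterize`, `mediate`, `network` and `run` (full
pipeline from a YAML config).

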