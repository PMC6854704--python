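# Methods

`rimap` implements a complete eQTL analysis stack for recombinant-inbred (RI)
mouse panels — the setting where ~60 genetically fixed strains, each measured
in 2–3 biological replicates, are genotyped at thousands of biallelic SNPs and
profiled for miRNA and mRNA expression.  This note describes the statistical
models, the defaults and why they were chosen, the synthetic panel the tests
run on, and the numerical decisions that a maintainer would otherwise have to
reverse-engineer.

## Genotypes: strain distribution patterns

An RI panel carries two parental alleles and no heterozygotes, so genotypes
are coded 0/1.  A marker is fully described by its *strain distribution
pattern* (SDP) — the allele vector across strains — and markers with identical
patterns on the same chromosome are statistically indistinguishable for
mapping.  `collapse_to_sdps` therefore groups SNPs by (chromosome, pattern),
drops monomorphic SNPs (uninformative), and anchors each SDP at the median
member-SNP position; for an even member count the median is the mean of the
two middle positions rounded to the nearest bp.  Two deliberate choices:

* **Complementary patterns are not merged.**  A pattern and its complement
  give identical association statistics, but they are distinct allele
  distributions; the SDP is defined by the literal pattern.
* **Identical patterns on different chromosomes stay separate**, so every SDP
  has a single genomic location (needed for cis/trans labels and binning).

Coordinates are 1-based bp throughout; report tables show Mb to one decimal.
Chromosomes order 1–19 then X.

## eQTL mapping

For a strain-mean trait y and an SDP genotype g, the model is marker
regression with no covariates (the panel is all male and environmentally
controlled, and strain means have already absorbed replicate noise):

    LOD = (n/2) * log10(RSS0 / RSS1)

with RSS0 about the grand mean and RSS1 about the two genotype-group means.
Each trait keeps its single genome-wide peak (ties break by genome order).
Implementation notes:

* SDPs leaving fewer than 2 strains in a genotype group are skipped with a
  warning; a perfectly separating SDP (RSS1 = 0) is capped at LOD 50, which
  keeps arithmetic finite and never changes rank order below the cap.
* The raw single-test p of a LOD is obtained through the monotone map
  F = (n−2)(10^(2·LOD/n) − 1) with (1, n−2) df; it is used only where
  permutations cannot resolve the needed resolution (hotspot eligibility at
  ~4e-8).

**Genome-wide significance** uses a permutation null for the max-LOD
statistic: strain labels of y are permuted B times (default 1000) and the
genome-wide maximum recomputed each time, so the null respects LD among SDPs.
The reported p is the exact-test estimate p = (b+1)/(B+1), which can never be
zero; with B = 1000 the smallest achievable value prints as 0.0010.  Each
trait's permutation stream derives from the global seed plus a CRC-32 hash of
the trait id, so results do not depend on trait order and scans parallelize
reproducibly.  Across traits, multiplicity is controlled by Benjamini–
Hochberg at FDR 0.05.  `fdr_adjust` optionally takes the total family size
`m_total`, used when re-deriving q-values for a reported subset of a larger
trait family (valid when the omitted p-values lie above the step-up
boundary).

**Credible intervals.**  Posterior mass at each SDP on the peak chromosome is
proportional to 10^LOD (normalized within the chromosome — the conventional
single-chromosome interval semantics).  SDPs accumulate in decreasing-mass
order, ties broken by genome order, until 95% coverage; the interval is the
[min, max] representative position of the accumulated set.  A single-SDP
(zero-width) interval expands to that SDP's widest member-SNP span.

**cis/trans.**  A peak is *cis* (local) when it lies on the trait's own
chromosome within 5 Mb of the trait's start coordinate, else *trans*
(distal).  For miRNAs annotated at several genomic copies,
`resolve_multilocation` picks one: the copy whose 5-Mb window holds the
strongest SDP found in any copy's window; if the copies share one window, the
copy nearest that SDP; if no SDP falls in any window, the copy nearest the
strongest SDP on a candidate chromosome.

## Heritability and group contrasts

Heritability of a trait is the intraclass correlation from a one-way
random-effects ANOVA on the replicate layer, by method of moments (closed
form, deterministic, robust for unbalanced 2–3 replicate designs):

    ICC = (MSB − MSW) / (MSB + (k0 − 1) MSW),
    k0  = (N − Σ nᵢ²/N) / (a − 1)

truncated to [0, 1].  eQTL strength is contrasted between hit groups with
two-sided Wilcoxon rank-sum tests; the reported W is the Mann–Whitney U of
the *first* group (cis, annotated, intronic, high-conservation — in that
orientation).  P-values are exact by enumeration when tie-free and group
sizes allow, otherwise the tie-corrected normal approximation.  Conservation
scores dichotomize at 0.5 (they cluster near 0 and 1); missing scores are
excluded listwise from that contrast only.  LOD relates to ICC by Spearman
correlation.  Phenotype screens use Spearman correlation on strain means
with BH-FDR at 0.2, and behavioral QTL tests are simple OLS of the phenotype
on the 0/1 SDP.

## Hotspots

If eQTL scattered uniformly over the genome, the count in a bin of the
genome-ordered SDP list would be Poisson with mean λ = (eligible eQTL)/(bins).
Bins are 4 SDPs wide by default; runs restart at chromosome boundaries so a
bin never straddles chromosomes (`cross_chromosomes=True` restores plain
division — both give 354 bins when per-chromosome SDP counts are divisible by
4, as in the packaged simulation of a 1416-SDP panel).  Eligibility of a
trait's peak uses the Bonferroni rule raw p < 0.05/(traits × SDPs) — at
881 × 1416 this is ≈4e-8, far below what 1000 permutations can resolve, hence
the F-based raw p.  A bin is a hotspot when its count reaches the smallest k
with P(X ≥ k; λ) < 0.05/bins; at λ = 0.56 over 354 bins this gives k = 6.
Adjacent significant bins on one chromosome merge into one hotspot, counting
distinct traits.  Sensitivity of detection to widths 3–5 is covered by a
regression test on a planted hotspot.  Eligible eQTL are restricted to
per-trait peaks (one eQTL per trait), the same convention as the scan.

## Mediation screening

Candidate triplets arise wherever a miRNA eQTL and a gene eQTL share an SDP;
each (SDP, miRNA, gene) is screened twice, with the miRNA and the gene as
mediator (causal and reverse mediation).  The Baron–Kenny linear structural
equations m = α₁ + a·g, y = α₂ + c·g, y = α₃ + c′·g + b·m give the indirect
effect a·b (identically c − c′ in OLS — asserted to machine precision in the
tests).  The CI is a non-parametric percentile bootstrap over strains (1000
draws, 99.5% level); the percentile variant was chosen over BCa for
robustness and determinism at n = 59.  Resampling is at strain level,
matching the strain-mean analysis; degenerate resamples (constant genotype
or mediator) are redrawn and counted.  A triplet is flagged when the CI
excludes zero.  This stage is a deliberate filter for network modelling, so
no multiple-testing correction is applied.

## Gaussian Bayesian networks

Each network covers one SDP plus all miRNAs and genes associated with it.
The score is the decomposable Gaussian BIC: each node regressed (with
intercept) on its parents contributes −(n/2)·ln(RSS/n) − (|parents|+2)/2·ln n
(higher is better); RSS is floored at 1e-12·n·Var(child) so near-deterministic
data stay finite, and singular parent designs score −∞.  Structure search is
greedy hill-climbing from the empty graph over single-edge additions,
deletions and reversals, accepting the best move that improves the score by
more than 1e-9 (the tolerance prevents floating-point oscillation between
exactly symmetric fits); ties break lexicographically on (source, target), so
search is deterministic with no random restarts.  Every edge into an SDP node
is blacklisted: genetic variants cause expression, never the reverse.

Edge confidence comes from model averaging over 500 bootstrap resamples of
the strains: *strength* is the fraction of resampled networks containing the
edge in either direction, *direction confidence* the fraction of those
agreeing with the majority direction; edges are retained at strength ≥ 0.5,
oriented by majority, and signed by the Spearman correlation of their
endpoints on the original data.  Rare cycles among retained edges (possible
under ties) are resolved by dropping the weakest edge of each cycle, logged.

## The synthetic panel

The generator emulates the study conditions end to end: 59 strains × 3
replicates; 20 chromosomes × 1,732 SNPs at ~50:50 allele frequency; local LD
modelled as *pattern persistence* — the next SNP copies the previous pattern
with probability 0.96, giving ~71 pattern runs per chromosome and hence
~1,400 SDPs after compression (pattern persistence, not a recombination map,
is enough to exercise SDP compression, and no map densities are prescribed
for the emulated panel); 881 miRNA and 3,000 mRNA features (the mRNA count is
a round figure of the same order as the array-based gene set).  Replicate
expression is Gaussian (emulating post-VST data): x = β·g + u_s + ε with
Var(u_s) = ICC and Var(ε) = 1 − ICC, so the non-genetic intraclass
correlation equals `icc_target` (default 0.5, the middle of the observed ICC
range) and planted effects add genetic variance on top.
`beta_for_variance_fraction` converts a target genetic share of strain-mean
variance into β.  Planted structures — cis/trans eQTL, one hotspot SDP
driving ≥7 miRNAs, mediation chains g → m → y with chosen path coefficients —
are recorded in truth tables.  All randomness flows from one seed through
per-stage substreams, so stages re-run independently and reproduce
bit-for-bit.

What the generator does **not** emulate: sequencing-read noise and
count-level dispersion (expression is already normalized), batch structure,
population structure beyond the two-allele RI design, and realistic
recombination maps.  Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to raw-data
artefacts, which upstream normalization is assumed to have handled.

## Problem sizes in the test-suite and acceptance script

Simulation-based checks run at the panel's sample size (n = 59) but on
reduced marker and trait grids chosen to keep the suite quick while leaving
the statistics well inside their asymptotics: 5 chromosomes × 100 SNPs
(~260 SDPs), 30–200 traits, 200 permutations (the (b+1)/(B+1) correction is
exercised separately at B = 1000), 500–1000 bootstrap draws, and 50–500
Monte-Carlo seeds per property.  The worked-example statistics (cis/trans
counts, rank-sum W values, the LOD~ICC correlation, FDR and hotspot
arithmetic) are computed at full fidelity from the packaged 38-eQTL tables.

## Known limitations

* Interval mapping between markers, covariate adjustment and genetic-map (cM)
  support are out of scope; positions are physical bp only.
* Whether complementary SDPs should merge is a modelling question the package
  answers conservatively (they do not); flag rather than silently merge.
* The permutation null recomputes the genome-wide maximum per trait; pooled
  permutation thresholds across traits are not implemented.
* The hill-climbing start graph and tie-breaks are fixed conventions;
  equivalent-scoring structures (Markov-equivalence classes) are not
  enumerated — bootstrap averaging is the mechanism that absorbs this
  uncertainty.
* Mediation screening on strain means inherits attenuation from replicate
  noise in the mediator; estimates of a·b are mildly conservative.
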