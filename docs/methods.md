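# Methods

## Statistical model

All statistics are computed per gene, per population sample, per SNP
stratum (all / synonymous / nonsynonymous), on biallelic SNP genotypes of
diploid individuals. The sampled unit is the chromosome: a population of
N individuals contributes n = 2N chromosomes. Phasing is ignored — every
statistic here depends on genotypes only through per-site allele counts.

**Polymorphism is population-relative.** A site counts as a variant for
population j only if it is polymorphic within j's sample, and its minor
allele frequency (MAF) is computed within that sample. The pooled analysis
recomputes polymorphism and MAF on the combined sample. This convention is
forced by the statistics themselves: Tajima's D and the rare/total ratio
are sample statistics of one population, and a site fixed within a
population carries no information about it. A rare variant is a segregating
site with MAF strictly below the threshold (default 0.05; a site at exactly
0.05 is not rare).

**Diversity estimators.** With S segregating sites and
a₁ = Σ_{i=1}^{n−1} 1/i:

- Watterson's θ_W = S / a₁.
- Nucleotide diversity π = Σ_sites (n/(n−1)) · 2p(1−p). The n/(n−1)
  correction makes the per-site term the unbiased heterozygosity, so the
  sum equals the mean Hamming distance over all C(n,2) chromosome pairs
  exactly — the convention consistent with the D variance coefficients
  below (the test suite asserts this equivalence against a brute-force
  pairwise scan).
- Tajima's D = (π − S/a₁) / sqrt(e₁S + e₂S(S−1)) with
  a₂ = Σ 1/i², b₁ = (n+1)/(3(n−1)), b₂ = 2(n²+n+3)/(9n(n−1)),
  c₁ = b₁ − 1/a₁, c₂ = b₂ − (n+2)/(a₁n) + a₂/a₁², e₁ = c₁/a₁,
  e₂ = c₂/(a₁²+a₂).

D is undefined for S = 0 or n < 4 and is carried as missing (NaN in
memory, literal `NA` in every TSV), never coerced to 0; downstream
aggregation must see the missingness. Harmonic sums are accumulated
exactly in double precision (no asymptotic approximations; n stays in the
hundreds here) and cached per n.

**Rare-to-total regression.** Across genes i within population j the model
is rare(i,j) = B(j)·total(i,j) + e(i,j), fitted through the origin: a gene
with no variants has no rare variants by construction, so an intercept has
no meaning. B = Σxy/Σx²; SE = sqrt(Σ(y−Bx)²/(n_genes−1)/Σx²), the textbook
through-origin estimator with one parameter's degree of freedom. Slopes
are compared with t = (B_a−B_b)/sqrt(SE_a²+SE_b²), referred to the
standard normal: with thousands of genes per fit the normal and any
reasonable t reference agree beyond reporting precision, and the choice
avoids inventing a degrees-of-freedom convention for a difference of two
independent fits. Pairwise comparisons are reported unadjusted, with a
clearly-labelled Bonferroni column as a courtesy; the adjacent-pair view in
`population_summary.tsv` tests each slope-sorted row against the next.
Outliers on the pooled fit are the k genes with the largest positive and
largest negative residuals (observed − predicted), ties broken by gene
name for determinism.

**Individual-level measures.** An individual carries at a rare site if
they hold at least one copy of the population-level minor allele there —
so at a site where the *reference* allele is the rare one, reference-allele
carriers count. Per gene: the carrier proportion (individuals with ≥1 rare
site carried / N) and the mean number of rare variants per individual.
"Number of rare variants" is read as the count of rare *sites* at which
the individual carries the minor allele (presence/absence per site); the
carrier definition ("at least one rare variant") is site-presence
language, which is why presence is the default. An allele-dosage variant
is available (`counting="dosage"`) for sensitivity analysis. Two
populations are compared with a classic paired t test over the identical
ordered gene list (df = n_genes − 1), applied to each measure. If the
per-gene differences are constant and nonzero the p-value is reported at
the smallest positive normal double with a logged warning rather than NaN.

**Cross-population aggregation.** Per gene: mean and sample variance
(df = n_pops − 1) of D across populations for the chosen stratum; the
count columns always use the all-SNP stratum (mean total variants, mean of
per-population rare/total, mean of per-population rare-nonsynonymous /
rare-all). Because D can be undefined in some population, two aggregation
policies are provided: `available` (default) averages over populations
with defined D; `strict` invalidates mean and variance whenever any
population's D is undefined. The policy is recorded in the output. Genes
with D strictly below a negative threshold (defaults: −2 nonsynonymous,
−1.8 synonymous) are flagged per population; genes flagged in ≥2
populations are marked shared. The stratum dispersion — the across-gene
mean of the cross-population D variance — measures whether a stratum ranks
genes consistently across populations: a shared (selection-like) signal
lowers it, population-specific noise raises it.

## Input handling

Gene membership and the synonymous/nonsynonymous class come exclusively
from the annotation TSV — never from positional overlap — so the gene
model is an explicit input. Multiallelic or non-SNP records are rejected
(the MAF folding and heterozygosity formulas assume two alleles), not
decomposed. Missing genotypes are a hard error by default (`strict`),
because silently dropping calls would change n inside the D coefficients;
an opt-in `drop` mode removes any variant with ≥1 missing call, logged per
variant. `0/1` and `0|1` both count one alternate allele. All samples are
treated as diploid autosomal.

## The synthetic generator

The analysis consumes only each population's per-gene site frequency
spectrum, so demography is emulated directly at that level rather than via
explicit demographic simulation: per gene and population, S ~
Poisson(θ·a₁(n)) sites (the Watterson relation, so θ is in conventional
population-mutation-rate units per gene), and each site's derived-allele
count k ∈ {1..n−1} is drawn with probability ∝ k^(−α). α = 1 reproduces
the neutral expected SFS shape; larger α tilts toward rare alleles as in
an expanding population. Derived alleles are placed on exactly k of n
chromosomes uniformly (hypergeometric design — column frequencies are
exactly k/n, which keeps fixture reasoning simple), chromosomes are paired
consecutively into diploids, and the derived allele is written as ALT
(MAF folding downstream makes results invariant to that orientation).

Defaults: θ = 3 per gene and α between 1.10 and 1.35 in the
seven-population preset, chosen to give per-population gene sizes (≈15–20
segregating sites) and rare fractions in the range typical of
gene-partitioned resequencing panels; p_nonsyn = 2/3, the standard
expectation for random coding mutations. Each site is nonsynonymous with
probability p_nonsyn; nonsynonymous sites receive an extra skew
`nonsyn_extra_skew · E_g` with E_g ~ Exponential(1) drawn per gene —
shared across populations when `shared_gene_effects` is true (a
selection-like, biology-driven signal), redrawn per population otherwise.
Synonymous sites can receive an analogous but always
population-independent noise (`syn_skew_noise`), modelling
population-specific drift of the neutral spectrum. Random streams are
derived deterministically from (seed, gene index, population label), so a
dataset is reproducible regardless of generation order and identical
configs give byte-identical files.

Populations carry private variant sites: there is no shared ancestry,
migration or linkage between or within genes. Pooled-sample statistics are
computed on the union, where population-private variants appear at
deflated frequency — the substructure mechanism that genuinely inflates
the pooled rare/total slope. What the generator does *not* emulate:
shared polymorphism between populations (real continental panels share
most common variants), linkage disequilibrium within genes, ascertainment
bias of SNP discovery toward common alleles, admixture, and explicit
selection coefficients. Passing tests therefore demonstrate that the
statistics recover frequency-spectrum structure when it is present, not
that any particular real panel has that structure.

The neutral Kingman coalescent simulator (pairwise merging at rate
k(k−1)/2, Poisson mutations at rate θ/2 per branch, infinite sites) covers
the exactly-neutral case where analytic expectations exist — E[S] =
θ·a₁(n), E[TMRCA] = 2(1−1/n), E[D] ≈ 0 — and is used only for
calibration.

## Validation sizes

The test suite validates the estimators against independent oracles
(brute-force pairwise π, a dually-implemented D, a general least-squares
solver, scipy's paired t) and the directional properties on seeded
replicates: 20 replicates of 1,000 genes for the three-population skew
ordering (α = 1.0/1.3/1.6, θ = 8, 30 diploids per population), 20 × 500
genes for the stratum contrasts (α = 1.2, nonsyn_extra_skew = 1.5,
syn_skew_noise = 0.75, shared effects), 500 replicate pairs of 200 genes
for null calibration of the slope test, 2,000 coalescent genes (50
chromosomes, θ = 5) for neutral calibration, and one full-scale
seven-population run (3,205 genes, 697 individuals) end-to-end through the
file formats. These sizes were chosen so each directional check has high
replicate-level power while the whole suite stays comfortably
interactive.

## Known limitations

- No ascertainment-bias correction: with discovery biased toward common
  SNPs, positive-D inference is unreliable on real panels; the rare/total
  regression outliers below the line are the more robust signal for
  common-variant excess.
- No formal per-gene significance for D (no simulation-based null); the
  −2 / −1.8 thresholds are conventional flags, not calibrated p-values.
- No admixture or local-ancestry control; populations are taken as given
  labels.
- Sex chromosomes, indels, CNVs and multiallelic sites are out of scope.
- The paired comparison of individual-level measures requires an identical
  gene universe in both populations and errors otherwise (no partial
  alignment).
- Carrier measures depend on sample size through the MAF threshold: with
  unequal N the expected per-individual rare count is not monotone in the
  SFS skew alone, so between-population contrasts of these measures are
  cleanest at comparable sample sizes.
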