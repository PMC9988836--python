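# Methods

`modmap` implements the statistical workflow used to discover and prioritize
a modifier locus in inbred mouse strain panels — the setting where a binary
trait (here, pertussis-toxin-induced histamine sensitization, Bphs) is
screened across classical and wild-derived inbred strains, mapped in
backcrosses, and fine-mapped by mixed-model SNP association combined with
functional-network evidence. This note records the models, the defaults and
the design choices, in the order the pipeline runs them.

## Strain susceptibility testing

Per-strain dose-response counts (animals affected / tested at each
challenge dose) are pooled over doses, because the readout is death at a
fixed time — a binary outcome the source tables also pool into a "Total"
column. Each strain's pooled 2x2 table against a resistant reference strain
is tested with a **two-sided Fisher exact test** using the point-probability
rule: the p-value sums the hypergeometric probabilities (margins fixed) of
every table no more probable than the observed one, computed by enumeration
in log space with a 1e-7 relative tie tolerance. Two-sided point-probability
is the variant that reproduces every verifiable printed p in the published
screen tables; the one-sided test fails on the discriminating cases (e.g. a
3/15-vs-0/13 table gives 0.23 two-sided but 0.14 one-sided). Displayed
p-values are rounded to one significant figure, matching the publication
convention (`<0.0001` below 1e-4); the raw value is always stored.

One published row ("MOLF/MpJ" in the knockout-F1 panel) prints `<0.0001`
where the pairwise two-sided Fisher test of its pooled counts against the
knockout reference gives ~7e-4; the comparison set behind that printed value
is not stated, so we do not reproduce it and do not assert it.

A strain is classified susceptible, where the pipeline needs a binary
phenotype downstream, when its Fisher p against the reference is < 0.05
(configurable). On the published screen this rule reproduces exactly the
eight susceptible resistant-allotype strains.

## Backcross linkage scan

Each BC1 animal is Ho (homozygous recurrent parent) or He at every marker.
Each marker is tested with the **Pearson chi-square without continuity
correction**, chi2 = n(ad-bc)^2 / [(a+b)(c+d)(a+c)(b+d)], df = 1 upper-tail
p. No continuity correction is applied — with Yates' correction the first
published marker would give 27.1 rather than the printed 28.8. Animals with
a missing call at a marker are dropped for that marker only, which is why
per-marker totals vary (165-168 in the published scan). No multiple-testing
adjustment is applied in this stage (a dozen markers, raw p reported).

## Mixed-model SNP association

The scan fits the standard GWAS linear mixed model per SNP,

    y = X beta + u + e,  u ~ N(0, sigma_g^2 K),  e ~ N(0, sigma_e^2 I),

with K an identity-by-state kinship (fraction of jointly observed SNPs with
identical calls; inbred strains are haploid-coded). **Full maximum
likelihood** (not REML) is used throughout, matching the ML likelihood-ratio
variant of efficient mixed-model association: after eigendecomposition of K
the likelihood is profiled over delta = sigma_e^2/sigma_g^2 on a 100-point
log-spaced grid over [1e-5, 1e5]; each sign change of the profile derivative
is refined by bisection in log delta to 1e-6; the global maximum wins and a
grid-edge optimum is flagged as a boundary fit. The per-SNP statistic is
LRT = 2(l1 - l0) with l1 = intercept + SNP, l0 = intercept only, p from
chi-square(1). Binary phenotypes are treated as 0/1 quantitative traits.
Monomorphic SNPs get p = 1 and a flag; strains missing a SNP are dropped for
that SNP (the null model is refitted on the same subset, cached per
missingness pattern). With K = I the fit reduces exactly to OLS maximum
likelihood, which the suite asserts to 1e-6.

Significance thresholds are Bonferroni (0.05/#tests) plus a fixed moderate
0.05, both recorded in output headers. Note 0.05/13,257 = 3.77e-6; the
publication prints a stringent cut-off of 3.81e-6 whose effective test count
is unstated, so we compute the threshold from the actual count and flag the
~1% discrepancy here rather than hard-coding the printed value.

Calibration caveat: ML-LRT association is known to run slightly
anticonservative at small n, and in a block-structured panel many SNPs share
the same strain-partition pattern, so the rejection fraction of a *single*
null scan is highly variable (few effective tests). The calibration checks
therefore average the rejection fraction over several simulated panels and
phenotype permutations; under that averaged design the empirical type-I
error at alpha = 0.05 sits near 0.045 for 50-strain panels.

## HMM genotype imputation

Missing calls in a target strain are imputed by modelling its chromosome as
a mosaic of reference strains. Hidden state = reference strain being copied;
uniform initial distribution; transitions stay with probability 1 - tau and
switch to each other reference with tau/(k-1); emissions match the state
strain's call with probability 1 - epsilon (mismatch epsilon), and are
uninformative when either call is missing. Decoding is **Viterbi in log
space** with ties broken toward the lower state index for reproducibility.
The reference panel for each target is the k strains most concordant with it
over jointly observed SNPs — a computable stand-in for "phylogenetically
nearest"; the target is excluded from its own panel.

Defaults: k = 8, epsilon = 0.01, tau = 0.002 per adjacent-SNP interval
(constant; a distance-scaled tau(d) = 1 - exp(-r d) option exists). These
are pragmatic values — small enough that a single-group mosaic is preferred
on clean data, large enough that decoding recovers breakpoints; they are all
exposed in config. Observed calls are never altered, and a missing call
stays missing when the decoded reference is also missing there (residual
missingness is reported per strain with the median/max summary).

## Functional prioritization

Trait-term gene sets are clustered into modules of < 400 genes by
average-linkage hierarchical clustering on the correlation distance between
the genes' full network connectivity profiles; the tree is cut at the
fewest clusters satisfying the size bound and clusters of < 5 genes are
merged into their nearest sibling (mean inter-cluster profile distance).
The clustering scheme itself (linkage, distance, cut rule, merge rule) is a
package decision and is overridable.

Each module trains **100 linear-kernel SVMs**, each classifying the module
genes against an independent balanced sample of genes outside the parent
set, with features = connectivity weights from each gene to the module
genes and 10-fold cross-validation. Costs come from an iteratively narrowed
window: starting from log-spaced [1e-3, 1e3], 8 costs are evaluated by CV
accuracy, a half-width window is re-centred on the argmax, and the process
repeats for 3 rounds; the final 8 costs are cycled across the ensemble.
(The window may slide below the initial bounds when accuracy is flat; all
costs remain positive.)

A candidate gene's score is the mean decision value over the 100 SVMs; it
is converted to an empirical **false-positive rate** against the
out-of-fold decision scores of all sampled negatives (the null), floored at
1/(n_null + 1) so -log10 FPR is always finite. A gene's final FPR is the
minimum over all modules of all trait terms — its maximum functional
enrichment. Whether the null should instead be a genome-wide gene sample is
unstated in the source methodology; CV negatives are the default and a
genome-wide sample can be formed by passing arbitrary genes to the scorer.

## Combined gene score

SNPs are assigned to the single nearest gene within 1 Mb (distance 0 inside
the interval, else distance to the closer edge; ties to the lower-start
gene, logged; unassigned SNPs are reported, never dropped). A gene's
association score is the maximum -log10 p over its assigned SNPs (0 with no
SNP). The combined score is

    S_cg(g) = assoc(g) / max_assoc + func(g) / max_func,

with maxima over the positional candidates in the configured locus, so
S_cg is in [0, 2], invariant to positive rescaling of either component, and
exactly 2 for a gene attaining both maxima. An all-zero component
contributes 0 for every gene rather than dividing by zero. The candidate
universe includes every gene in the locus interval (the primary-locus gene
is not excluded).

## Synthetic data

The generators produce inputs with the statistical structure the analyses
assume; all are pure functions of (config, seed) with one explicit RNG per
call.

* **Strain panel** — strains fall into phylogenetic groups; per haplotype
  block (default 2 Mb) each group draws a haplotype differing from a common
  ancestral reference at the between-group divergence (default 0.3), and
  each strain mutates its group haplotype at the within-group rate (default
  0.02). Missingness is missing-completely-at-random per strain at a rate
  drawn uniformly from a range (default 0-0.3), a coarse emulation of the
  much patchier coverage of wild-derived strains. Defaults mirror a
  ~50-strain panel (7 groups x 7 strains) over a ~70 Mb interval with 2,000
  SNPs.
* **Two-locus complementation trait** — affected iff the animal carries a
  dominant susceptible primary allele, or a resistant primary allele
  together with a dominant enhancer allele; a primary-locus knockout is
  never affected; expression with incomplete penetrance (default 0.9).
  Strain-level alleles are embedded as genotype columns at the two loci so
  association scans can rediscover them.
* **Backcross** — each BC1 animal carries a recurrent-parent gamete plus an
  F1 gamete generated by a Markov walk whose switch probability between
  adjacent loci is the **Haldane** recombination fraction
  r = (1 - exp(-2d))/2 at 0.5 cM/Mb (no genetic map is given in the source
  setting; 0.5 cM/Mb is a standard mouse-scale value). Default cohort size
  114 animals.
* **Network** — planted-module weights: within-module edges Beta-distributed
  with mean 0.8, all others mean 0.1, shared concentration 10 (degenerating
  to the mean as concentration grows); symmetric with zero diagonal.

What the generators do *not* emulate: coalescent genealogies, selection,
linkage disequilibrium decay within blocks, strain-biased (non-random)
missingness patterns, sex chromosomes, or the tissue specificity of real
functional networks. Passing tests therefore demonstrate correctness of the
algorithms under the stated generative assumptions, not performance on real
strain databases.

## Problem sizes and numerical choices

The bundled demo runs 30 strains x ~400 SNPs, a 114-animal backcross, a
220-gene network with one 30-gene planted module and a 21-gene candidate
locus; it completes in well under a minute on one CPU. Calibration studies
use 50-strain panels with 2,000 SNPs (type-I error averaged over 4 panels x
6 permutations), 200-strain kinships from 100 SNPs for variance-component
recovery (fewer SNPs widen the IBS eigenvalue spread, which is what
identifies sigma_g^2 against sigma_e^2), 500-SNP/20-strain masking
experiments for imputation, and 300-gene networks for the SVM checks.
Numerical specifics: genotype calls are int8 with -1 as the missing
sentinel; kinships must be PSD within a 1e-6 tolerance (pairwise-complete
IBS from very few SNPs can violate this and errors rather than being
silently repaired); Viterbi and tie-breaks are fully deterministic; Fisher
enumeration uses log-space gammaln sums.

## Known limitations

* ML (not REML) variance components are mildly biased at small n; the LRT
  is slightly anticonservative for n around 50 (documented above).
* The imputation HMM has no posterior (forward-backward) output and no
  phasing — inputs are inbred/haploid by assumption.
* Homolog mapping for gene identifiers is out of scope; all inputs must use
  a consistent gene naming scheme.
* No BAM/FASTQ handling, variant calling, or genome-build liftover.
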