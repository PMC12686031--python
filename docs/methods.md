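# Methods

## Per-cohort EWAS

Each CpG's methylation β value is regressed by OLS on natural-log
adipokine concentration with covariates age (years), a female indicator,
cell-type proportions and numeric technical factors. The base model uses
five proportions (CD8T, CD4T, NK, Mono, B) with granulocytes as the
implicit reference; the extended-cells variant swaps in eleven
EpiDISH-style proportions with neutrophils excluded, since all twelve sum
to one and including the reference would make the design singular.
Standard errors are model-based and p-values two-sided from the t
distribution on the residual degrees of freedom. Because the synthetic
methylation matrices are complete, all CpGs in a cohort/model share one
design matrix and are solved in a single batched QR pass; CpGs with
missing β values fall back to per-CpG complete-case fits, which the
batched path reproduces exactly (tested against an explicit
normal-equations oracle at 1e-10 relative).

Phenotype cleaning happens once per cohort/model: values below the limit
of detection are removed, then values more than three IQRs beyond the
nearest quartile, both on the raw (pre-log) scale. Quartiles use linear
interpolation between order statistics — the common default; under it the
vector (1, 2, 3, 4, 100) has Q1 = 2, Q3 = 4 and flags only the 100.
Outlier trimming per variable on the raw scale is a deliberate
simplification; per-CpG methylation outlier removal is not applied
because the generator does not produce heavy-tailed β values.

## Bias/inflation correction

Genome-wide z-statistics are fitted with a three-component normal
mixture: a dominant central (null) component whose mean is the *bias* and
SD the *inflation*, plus two flanking components for true associations.
The fit is a deterministic penalized EM rather than a Gibbs sampler:

* initialization at the median, IQR-based robust scale, and flanking
  means at ±3 robust SDs;
* flanking means carry a Gaussian anchor at `bias ± 3·inflation` with a
  pseudo-count of 0.5% of the sample — strong enough to stop the side
  components from eating the null's tails on a pure-null input, weak
  enough to let genuine signal at ±4 pull them out;
* flanking SDs are floored at the central SD and the central weight at
  0.8, so the largest component always plays the null role;
* convergence at absolute log-likelihood change < 1e-8 (cap 10,000
  iterations; non-convergence is an error, not a silent result).

On 400,000 N(0,1) draws the estimator returns inflation within ±0.01 of
1 and bias within ±0.01 of 0; on 0.3 + 1.5·N(0,1) it recovers (0.3, 1.5);
with 5% signal at ±4 the null component stays within [0.95, 1.05]. The
classical shrinkage priors (α = 1.28, β = 0.36) of the Bayesian
formulation are recorded in the configuration for provenance; the EM's
hard constraints target the same estimand. Adjustment is per cohort and
per model: `beta_adj = beta − bias·se`, `se_adj = se·inflation`, p-values
recomputed from the standard normal.

## Meta-analysis

Fixed-effects inverse-variance pooling (w = 1/se²) over the cohorts
reporting each CpG; rows estimated from fewer than 50 observations are
dropped first. Cochran's Q and I² = max(0, (Q−df)/Q)·100 quantify
heterogeneity; CpGs with I² ≥ 80% are removed (under the generator's
shared-effect model essentially none are, matching expectation).
Benjamini–Hochberg FDR runs across all surviving CpGs within one model;
significance is q ≤ 0.05. Single-cohort CpGs are pooled trivially and
flagged rather than removed. The *robust* set intersects base-model
significance with q ≤ 0.05 in each sensitivity model (each with its own
within-model FDR over its own tested set); a CpG absent from a
sensitivity table — for example removed there by the heterogeneity
filter — counts as not surviving. CpGs significant in every model except
the BMI adjustment are reported separately as BMI-sensitive.

## DMR calling

A region needs ≥ 3 differentially methylated positions, every gap
between consecutive member CpGs < 1000 bp (a gap of exactly 1 kb
splits), and ≤ 3 non-DMP CpGs strictly between the first and last member
DMP. Regions are grown by a left-to-right greedy scan that stops when
the next CpG is too far or would overrun the non-DMP budget, then trims
trailing non-DMPs; this yields, from each leftmost unused DMP, the
maximal valid region, and is verified against an exhaustive
interval-enumeration oracle on 500 random instances. Distinct loci =
total DMPs − DMPs inside regions + number of regions. Effect-direction
consistency within a region is reported but not enforced.

## Enrichment

Trait and chromatin-state enrichment use logistic regression of feature
membership on target membership over the full CpG background (the fitted
OR equals the 2×2 cross-product ratio in this covariate-free setting,
checked to 1e-6). When any cell is zero the Haldane–Anscombe +0.5
correction replaces the regression and the result is flagged. The trait
catalogue is filtered before testing: PubMed ID present, study n ≥ 500,
≥ 100 CpGs reported, nominal p-values available, adults, whole
blood/leukocytes; synonymous trait names merge through an explicit
recode map. Gene-set over-representation is the one-sided hypergeometric
tail, with the universe defaulting to the union of the library's genes.
BH-FDR is applied within each family.

## eQTM

Counts become log₂CPM with pseudo-counts 0.5 (count) and 1.0 (library),
chosen for finiteness at zero; genes need CPM ≥ 1 in ≥ 50% of samples
and an autosomal location. Each kept gene is rank-inverse-normal
transformed with the Blom offset, Φ⁻¹((r − 3/8)/(n + 1/4)), average
ranks on ties. CpG–gene pairs lie within 100 kb of the nearer gene
boundary (distance 0 inside the gene body; strand ignored; nearest-gene
ties break by smaller start then lexicographic id). Covariates (age,
sex, technical, 12 cell proportions) are projected out of both sides
once (Frisch–Waugh–Lovell) so each pair reduces to a simple regression
with the full model's degrees of freedom — algebraically identical to
refitting per pair and checked against a normal-equations oracle.
Small adipocyte-style fixtures use plain Pearson correlation with no
covariates, by design.

## Mendelian randomization and triangulation

Harmonization aligns outcome to exposure effect alleles: swapped alleles
flip the outcome sign; identical alleles reported on the complementary
strand are kept; complement-plus-swap configurations (e.g. A/G vs C/T)
are ambiguous between a strand flip and a mismatch and are dropped
rather than guessed; palindromic variants are dropped above a
minor-allele frequency of 0.42 (disableable). Single instruments use the
Wald ratio β_Y/β_X with first-order SE se_Y/|β_X|; multiple instruments
use fixed-effect IVW, β = Σ(β_Xβ_Y/se_Y²)/Σ(β_X²/se_Y²), which equals
the Wald estimate for one instrument. No MR-Egger or weighted-median
variants; instruments are declared independent on input. FDR is applied
per design (CpG→adipokine, adipokine→CpG, CpG→trait).

Forward triangulation correlates, across CpGs, the lead cis-mQTL's
observed GWAS effect with the path product β_mQTL × β_EWAS. The product
is used exactly as stated even though the EWAS coefficient is a
DNAm-on-adipokine slope (units are internally inconsistent); only the
cross-CpG correlation is consumed, which is invariant to any consistent
rescaling. Reverse triangulation EAF-weights the adipokine instruments
(weights normalized to sum to one): observed = weighted mean trans-mQTL
effect on the CpG, predicted = (weighted mean SNP→adipokine effect) ×
β_EWAS.

## Synthetic data

The generators run the downstream models forward, so estimator checks
against the planted truth are exact by construction:

* **Cohorts.** β values = per-CpG baseline (U(0.1, 0.9)) + planted
  effect + small covariate effects + N(0, 0.05) noise, clipped to [0, 1]
  (clip fraction reported, ~0.15% at defaults; > 50% clipping is a
  generation error). Adipokines are log-normal — adiponectin
  (location 1.95, scale 0.5, µg/ml), leptin (2.5, 0.8, ng/ml) — with
  BMI correlation −0.3 and +0.7 respectively, mirroring leptin's much
  stronger adiposity coupling; current/former smoking lowers the
  adipokine slightly so smoking can confound. BMI-mediated plants carry
  their effect on standardized BMI with the coefficient scaled so the
  *marginal* slope on log adipokine equals the recorded true β — the
  BMI-adjusted model then nulls them, which is what the sensitivity
  filter must detect. Cell proportions come from one Dirichlet over 12
  leukocyte types (concentration 150, neutrophils ≈ 50%); the 5-type
  aggregates are sums of the extended types, and neutrophils are the
  implicit reference everywhere. Default consortium sizes are the
  published per-cohort n (adiponectin 807/718/701/124/441, leptin
  1702/723/701/94/441). Smoking and BMI carry 5%/2% missingness so the
  sensitivity models genuinely lose observations.
* **Annotation.** Probes fall in island-like clusters of 1–5 CpGs a few
  hundred bp apart separated by multi-kb gaps (so the DMR rules have
  non-trivial instances); ~2/2/3% carry sex-chromosome/blacklist/variant
  flags; 15-state chromatin labels follow PBMC-like frequencies, with an
  optional odds-multiplied enrichment of one state among designated
  CpGs; half the gene models anchor within 150 kb of a random probe.
* **Genetic scenarios.** Explicit structural models (forward SNP→CpG→
  adipokine, reverse SNP→adipokine→CpG, confounded via a pleiotropic
  latent path, null), 1–4 independent cis instruments per CpG, SEs
  scaling as σ/√(2n·EAF(1−EAF)), estimates drawn Normal(truth, se²).
  Causal effects get per-CpG Uniform(0.5, 1.5) magnitude spread with
  random signs — constant effects would leave triangulation with zero
  cross-CpG variance — and adipokine GWAS instruments are reported for
  the trait-increasing allele, as instrument tables conventionally are.
* **Expression.** Gamma–Poisson (negative binomial, dispersion 0.1)
  counts whose log₂ mean depends linearly on the paired CpG's β; default
  planted effects are 70% negative, echoing the predominance of inverse
  methylation–expression relationships in blood.

One global integer seed expands through fixed spawn keys (truth 0,
cohort 1, annotation 2, genetic 3, expression 4; cohort index appended
within a consortium); identical seed and config give byte-identical
output.

What the generator does **not** emulate: probe-level measurement error
structure and array chemistry, spatial correlation of methylation beyond
the planted clusters, LD between instruments, twin/family relatedness,
cell-type interactions, or heavy-tailed phenotype contamination. Passing
tests therefore demonstrate correctness and calibration of the
statistical machinery under the stated generative assumptions, not
robustness to every failure mode of real cohort data.

## Problem sizes and numerical choices

The acceptance-scale checks use 400,000 z-statistics for the calibration
fits, 20 replicate five-cohort consortia of 5000 CpGs with 50 planted
effects (SD 0.01), 1000-instance oracle comparisons, 500 random DMR
instances, 1000 CpG blocks for reverse-MR calibration and 50 replicate
200-CpG blocks for triangulation. Two hundred CpGs per triangulation
block is a power choice: with m CpGs the null correlation has SD
≈ 1/√(m−3), and keeping |r| < 0.15 in ≥ 90% of replicates needs that SD
below ~0.09, i.e. m ≳ 130. "Power at the detectable scale" is assessed
among planted effects with |β| ≥ 2 × (4 × median pooled SE) — four
pooled SEs being roughly the genome-wide FDR threshold — computed from
each run's own output, never tuned to it. Degenerate inputs raise
informative errors throughout (empty pools, constant RIN vectors, zero
exposure effects, rank-deficient designs naming the collinear columns).
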