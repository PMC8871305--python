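# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that make results reproducible.

## Genotype representation and quality control

Genotypes are minor-allele dosages in {0, 1, 2} with −1 as the missing
sentinel; every downstream operation branches on the sentinel explicitly
(complete-case per SNP in association tests, per-combination exclusion in
GMDR, rounded-mean substitution in the PRS — each noted below). After
reading PLINK bed/bim/fam, columns are re-oriented so dosages always count
the cohort-empirical minor allele; frequency ties at 0.5 break toward the
lexicographically smaller allele label so orientation is deterministic.

Sample QC removes missing call rate ≥ 4% and heterozygosity > 30% —
thresholds appropriate to a genome-wide chip, where mean heterozygosity is
well below 30%. On a small simulated panel of common SNPs the
heterozygosity rule would remove most samples (2pq ≈ 0.42 at MAF 0.3), so
the pipeline config exposes both thresholds; the small-panel demos relax
them deliberately. Genotyping accuracy is a chip-level metric that cannot
be derived from dosages; it is accepted as an optional per-sample input
column (default cutoff 98%). SNP QC defaults — MAF ≥ 0.01, HWE exact
p ≥ 10⁻⁶ computed on controls, call rate ≥ 0.95 — follow common GWAS
practice and are config-exposed.

The Hardy–Weinberg test is the exact conditional test: given the allele
counts, the heterozygote count follows a known discrete distribution and
the two-sided p sums the probabilities of all heterozygote counts no more
probable than the observed one. The implementation uses log-gamma weights
and is property-tested against an independent enumeration.

## Association screen

Per-SNP case-control association uses maximum-likelihood logistic
regression with additive dosage coding plus covariates; OR = exp(β̂) with
Wald 95% intervals (symmetric on the log scale, matching standard GWAS
output). Missing dosages are handled complete-case per SNP (a mean-dosage
policy is available by flag). Non-convergence or separation produces a
flagged result with missing p rather than an exception; a constant dosage
column raises a dedicated error. Screening retains p < 5×10⁻⁵; a strict
p < 5×10⁻⁸ flag marks genome-wide (Bonferroni) significance. Results are
sorted by p with ties broken by SNP id so the candidate order is total.

## LD estimation and pruning

Two-locus haplotype frequencies are estimated by EM over the
double-heterozygote phase ambiguity, initialized at linkage equilibrium
with tol 10⁻⁸ and max 1000 iterations (standard, deterministic). At
convergence D = p_AB − p_A·p_B and D′ = |D|/D_max with
D_max = min(p_A·p_b, p_a·p_B) for D > 0 and min(p_A·p_B, p_a·p_b) for
D < 0; D = 0 gives D′ = 0. The EM estimate is checked against a
brute-force likelihood grid over p_AB.

Pruning is greedy over the association-ranked list: keep the best-p SNP,
drop later same-chromosome SNPs with D′ > 0.3 against any retained SNP.
Which member of a high-LD pair to keep is an open convention; best-p is
adopted because it preserves the screen's ranking. Cross-chromosome pairs
are never pruned.

## GMDR

The score statistic is the raw residual sᵢ = yᵢ − p̂ᵢ of a covariates-only
logistic null model (the canonical score-based generalization of MDR for
a binary trait); with no covariates p̂ is the prevalence, and any
intercept model gives Σsᵢ = 0, so 0 is the natural cell threshold. Cells
with mean training score ≥ 0 are labeled high-risk; boundary cells go to
high (deterministic, matching the MDR convention), and cells empty in
training — including cells unseen at test time — are low. Balanced
accuracy uses hard case/control counts, ½(sens + spec), with an empty
class contributing ½; a score-weighted variant is available behind a
flag. The per-fold sign statistic counts folds with TEBA > ½ and is
tested with the exact one-sided binomial (10 folds, p floor 2⁻¹⁰); a
Wilcoxon signed-rank alternative against ½ is provided for sensitivity
analysis. CVC counts the folds in which a subset attains the fold-best
TRBA among the subsets searched (ties count for all tied subsets).
Selection requires sign-test p < 0.05 and CVC ≥ 9, ranking by mean TEBA
with ties broken by higher CVC then lexicographic SNP ids. Exhaustive
enumeration is guarded at 60 candidates, which keeps C(60, 2) = 1770
subsets at desk scale.

If the null model separates, scores fall back to prevalence residuals
with a warning — the covariate adjustment is lost but the statistic stays
well defined.

## PRS

Risk alleles are oriented from the association ORs (minor allele if
OR > 1, major otherwise; OR exactly 1 is rejected as ambiguous). The PRS
is the unweighted sum of risk-allele copies. A genotype missing at one
model SNP contributes that SNP's rounded cohort-mean risk count, keeping
category sizes stable; samples missing at every model SNP are excluded
with a report. Two published band sets exist for the 5-SNP model
(0–3 / 4–6 / >6 and 0–3 / 4–5 / ≥6); the first labels the reported odds
ratios and is the default, the second is selectable (`CUTOFF_SETS`).
Category odds ratios use indicator-coded logistic regression with Low as
the reference; the two covariate sets (model 1: demographic; model 2:
model 1 plus lifestyle) are config-defined lists, since which columns
exist depends on the cohort file.

## Diet and lifestyle

Frequency categories map to times/day by the midpoint of the category's
count range over its period, with month = 30.4375 days (365.25/12);
portion multipliers are less/equal/more = 0.5/1.0/1.5. Both are
config-exposed because the source conventions are not printed anywhere
authoritative. Nutrients follow from a per-100 g composition matrix;
macronutrient energy shares use 4/9/4 kcal/g, and %EER uses a sex × age
band lookup defaulting to Korean Dietary Reference Intake adult values.
HOMA-B uses the standard 20·I/(G − 3.5) form. Metabolic syndrome uses the
2005-revised NCEP-ATP III Asian criteria with the 100 mg/dL fasting
glucose cutoff of that revision.

Dietary patterns: PCA on the correlation matrix (food groups have
heterogeneous scales), retention at eigenvalue > 1.5, varimax rotation,
regression-method scores, significance at |loading| ≥ 0.40, high/low at
the 70th percentile. Column signs are fixed by making each factor's
largest-|loading| entry positive.

## PRS × exposure interaction

"High" exposure is inclusive of the cutoff, including at percentile
cutoffs, so ties resolve deterministically. The interaction p-value is a
likelihood-ratio test with the PRS entered ordinally (0/1/2) in the
product term — 1 df, matching a single reported p per exposure; an
indicator-coded 2-df variant is flagged. Stratified ORs refit the
category model within each stratum with Low-PRS as reference; empty cells
are flagged NaN, never imputed.

## Synthetic cohort generator

The generator is the package's test substrate and defines the study
conditions for the planted-signal checks:

* **Genotypes.** Unlinked SNPs drawn from HWE (q², 2pq, p²). LD blocks
  draw two haplotypes per person from a pair table with
  p_AB = p_A·p_B + D′·D_max, which is unique and feasible for any
  D′ ∈ [0, 1]; chained blocks link each SNP to the block's first.
  Missingness is uniform at the configured rate (≤ 5%).
* **Outcome.** Bernoulli from a logistic model: baseline logit, additive
  per-allele effects, an optional pure-epistasis term (a joint log-OR
  bump for carrying ≥ 1 risk allele at both loci of a pair — marginally
  null by construction when no main effects are planted), covariate
  terms, and an optional exposure-stratified genetic effect whose
  dichotomization uses the same cutoffs as the analysis, so the planted
  G×E truth is well defined.
* **Covariates/exposures.** Age U[40, 75]; sex Bernoulli(½); BMI
  N(24.5, 3²) truncated to [16, 40]; energy intake lognormal around 100%
  EER; macronutrient energy shares near Korean-cohort means; alcohol
  zero-inflated lognormal. These are parameters, not claims about any
  real cohort.
* **FFQ.** Latent pattern scores load on disjoint food-group sets
  (orthogonal planted loadings); item intensities map monotonically onto
  the nine frequency categories; portions are uniform.

Not emulated: realistic human LD maps, measurement error in biochemistry,
survey logistics, population structure, and correlated missingness.
Passing tests therefore demonstrate correctness of the algorithms under
the generative model, not robustness to those real-data features.

## Problem sizes and determinism

Planted-signal checks use n = 2000 (GMDR pair recovery, 12 SNPs, joint
log-OR ln 6, baseline prevalence 0.3), n = 5000 (PRS OR recovery) and
n = 8000 (stratum-specific G×E ORs); null calibration uses 200
interaction-LRT replicates at n = 2000 and 50 permuted-outcome GMDR
replicates at n = 500 with 8 SNPs. These sizes make the Monte Carlo error
comfortably smaller than the tolerances tested while keeping the whole
suite desk-scale. All randomness flows through explicit integer seeds
(numpy Generator); a fixed config reproduces every artifact bit for bit,
and the pipeline manifest records seeds, thresholds, stage counts and
output hashes.

## Known limitations

* GMDR covers the binary-outcome case only; the generalized framework's
  continuous-trait scores are out of scope.
* No population-structure correction (mixed models / principal
  components); the cohort is treated as homogeneous.
* The gene-level literature filter of the original workflow depends on
  external web services; it is replaced by a user-supplied SNP→gene map
  plus allow-list, which is the reproducible core of that step.
* Weighted (effect-size) PRS and additive-scale interaction measures
  (RERI) are deliberately not implemented.
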