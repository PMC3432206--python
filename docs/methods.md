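# Methods

## Scope and overall design

`snprisk` reconstructs, as a tested pipeline over synthetic data, a
genome-wide risk-classification and probability-estimation experiment: build
SNP-based risk rules by several methods over an importance-driven cascade of
nested SNP sets, and evaluate discrimination, calibration and pairwise
differences on a held-out test set.  Because real genome-wide
case-control data of this kind are access-restricted, a synthetic-data stage
with a fully known generating model replaces them; the known truth (causal
effects, the prospective intercept, every subject's true disease
probability) is what makes the recovery and consistency checks possible.

## Synthetic genotype and disease model

Genotypes.  Each SNP draws a minor allele frequency (MAF) uniformly from a
configurable interval (default 0.05-0.5).  Every subject receives two
independent haplotypes, so dosages of the minor allele follow Hardy-Weinberg
proportions (MAF², 2·MAF(1-MAF), (1-MAF)²).  Local linkage disequilibrium is
modelled by a first-order Gaussian-copula autoregression on the latent
haplotype normals: z_1 ~ N(0,1), z_j = ρ z_{j-1} + √(1-ρ²) ε_j, with the
allele indicator z_j < Φ⁻¹(MAF_j).  The single parameter ρ (default 0.15 in
the desk-scale experiment) controls adjacent-SNP correlation while leaving
every marginal in Hardy-Weinberg proportions.  This emulates blocky local
correlation only; it does not reproduce recombination hotspots, allele
frequency spectra, population stratification (beyond what a user simulates
explicitly) or genotyping error, so passing tests speak to the statistical
machinery, not to robustness against those features of real data.

Phenotypes.  Disease status is prospective-logistic:
P(y=1|g) = expit(α + Σ_j β_j g_j) with a sparse causal set.  The per-subject
true probability η(x) is stored on simulated datasets for oracle tests and
is never an input to any fitting routine.

Sampling and split.  Case-control samples are simple random draws within
phenotype class; the sampling fractions π₁ = sampled/available cases and
π₀ = sampled/available controls are recorded.  The train/test split is
stratified without replacement and partitions the sample exactly.

Desk-scale defaults.  2,000 SNPs, a cohort of 20,000, 10 causal SNPs with
|β| between ln 1.2 and ln 1.6 (a third protective), baseline log-odds -2.2
(cohort prevalence ≈ 0.22 after the causal effects), sampled to 700 cases
and 750 controls and split 476/487 (train) versus the 224/263 remainder —
a 1,445-subject analysis set over 1/250 of a 550k-chip SNP count, sized so
the full experiment runs in about 90 seconds on one CPU.

## Quality control and association

Monomorphic SNPs (a single dosage value) are removed, as are SNPs with a
1-df chi-square Hardy-Weinberg goodness-of-fit p below 1e-4.  HWE is tested
in controls only, the standard GWAS practice; since QC here runs on the
training split (see Leakage below), "controls" means training controls.
A chi-square rather than exact HWE test is used: at the 1e-4 threshold and
desk-scale sample sizes the two do not disagree materially, and the
chi-square test vectorizes.

Association per SNP is the Cochran-Armitage trend test with scores (0,1,2)
and the unconditional variance (verified against R's `prop.trend.test`),
plus a risk-oriented allelic odds ratio from the 2x2 allele-count table with
a Haldane-Anscombe +0.5 applied to all cells when any cell is zero.  The OR
is always reported for the risk allele, so log OR ≥ 0; the orientation flag
feeds the counting scores.  The genomic inflation factor is
λ = median(trend χ²)/0.4549; values above 1.10 trigger a warning (the
synthetic data are unstratified by construction, so λ monitoring replaces
any stratification correction).  Significance-threshold selection orders
hits by p, then genomic position, then SNP id; the genome-wide 5e-8
threshold is configurable and defaults to 1e-4 at desk scale, where 5e-8
would select nothing.

## Risk rules

* allele count — sum of risk-allele dosages over the SNP set.
* logOR — the same sum weighted by each SNP's training log odds ratio.
* logReg — unpenalized maximum-likelihood logistic regression over the
  smallest SNP set only, guarded by |SNPs| < n/5; separation raises an
  error that points at the lasso.
* lasso — L1-penalized logistic regression over a 100-point log-spaced
  penalty grid running from the smallest penalty that zeroes every
  coefficient (on standardized dosages) down four decades.  The penalty is
  chosen by 10-fold class-stratified cross-validation maximizing
  classification accuracy at the 0.5 probability cut-off; accuracy ties go
  to the larger penalty (the sparser model).  Folds are seeded; degenerate
  single-class folds are re-drawn up to three times.  Coefficients are
  mapped back to the dosage scale after fitting.
* forests — see below.

Thresholding.  Continuous scores classify by score ≥ t ⇒ case, with t
maximizing the Youden index J = sens + spec - 1 on training data over all
midpoints between adjacent distinct scores plus sentinels beyond the range;
ties resolve to the smallest threshold.  The rule direction (≥ ⇒ case) is a
package convention.

Retrospective-to-prospective correction.  A logistic model fitted to
case-control data has the prospective slopes but a shifted intercept.  With
sampling fractions π₁, π₀ of cases and controls from the cohort, sampling
shifts the intercept by ln(π₁/π₀), so the prospective intercept is
recovered as α = α* + ln(π₀/π₁), and a fitted probability vector is mapped
to the prospective scale by the same logit shift.  The sign convention is
fixed by the recovery requirement — applying the correction to a
retrospective fit must reproduce the known cohort intercept and prevalence
— which the tests verify by simulation.

## Probability forests

Trees are Gini CART on additive dosages.  On 0/1/2 data the only
informative binary splits are the cuts {≤0, ≤1}; the tree engine is
sklearn's `DecisionTreeClassifier` (whose thresholds on such data are
exactly those cuts; a threshold of 1.0, produced when a node lacks
heterozygotes, is canonicalized to the ≤1 cut at serialization).  Each
forest grows `n_trees` trees on independent bootstrap samples (n draws with
replacement) with out-of-bag (OOB) subjects recorded per tree.

Two modes:

* classification — min terminal node size 1, no pruning; a tree votes with
  its leaf majority (leaf tie → case) and the forest takes the majority of
  votes (tie → case).  Deep unpruned trees memorize the training data,
  which is why training sensitivity/specificity reach 1.0.
* regression/probability — minimum terminal node size 5 by default.  Since
  η(x) = E(y|x), probability estimation is nonparametric regression, and
  trees must keep some leaf impurity for averaged leaf relative
  frequencies to behave as probability estimates; splitting to purity
  bases each leaf estimate on one observation.  The forest output is the
  arithmetic mean of per-tree leaf case frequencies, a value in [0,1].
  (For binary y, variance-reduction and Gini splitting coincide, so the
  classifier engine serves both modes.)

Defaults: 500 trees (smaller in the desk-scale experiment, see below),
mtry = ⌊√p⌋ in classification and ⌊p/3⌋ in regression mode, both
overridable; mtry larger than p is clipped with a warning.

Importance is the permutation ("Liaw") score: per SNP and tree, the drop in
OOB accuracy (classification) or the rise in OOB mean squared error
(regression) after permuting the SNP's OOB values, averaged across trees.
SNPs a tree never splits on contribute exactly zero for that tree.  Mean
OOB accuracy decrease is used rather than Gini impurity importance because
it is the headline measure of the reference R implementation.

Backstep cascade.  Starting from the full (QC'd) SNP set, each round fits a
forest, ranks SNPs by importance (ties broken by better single-SNP trend p,
then SNP id) and keeps the top ⌈p/2⌉; every intermediate set is recorded
and the caller picks the sets nearest its target sizes (defaults 16, 63,
250, 1000).  Rounding is ceil, so 63 SNPs step to 32, 16, 8, 4, 2.

Forests serialize to a documented JSON structure of nested node records
(split SNP index, canonical cut, sample and class counts, leaf case
frequency), enabling independent re-traversal in tests.

## Evaluation

* AUC by the Mann-Whitney estimator with midrank tie handling; variance and
  95% CI (Wald, truncated to [0,1]) from DeLong placement values; paired
  AUC comparisons by the DeLong z-test using the placement covariance.
* Brier score — mean squared difference between outcome and predicted
  probability, computed only for probability-scale rules (logReg, lasso,
  regression forests); 95% Wald CI from the sample variance of the squared
  errors, truncated to [0,1].
* Sensitivity/specificity with Wilson score 95% intervals.
* Paired difference in proportions correctly classified, with a
  discordant-pair (McNemar-style) variance: d = (n10-n01)/n and
  var(d) = (n10+n01-(n10-n01)²/n)/n².  This Wald-type paired interval is a
  deliberate stand-in for the published paired-proportions interval it
  approximates, isolated in one function so an alternative can be swapped
  in.

## Orchestration, leakage and determinism

The experiment runs simulate → sample → split → QC → associate → cascade →
fit → threshold → evaluate.  Everything that learns — QC filters,
association weights, penalties, thresholds, the importance cascade — sees
only the training split; the test split enters only at evaluation.  QC is
run on the training data (rather than pre-split) precisely so that fitted
models are provably independent of the test subjects; the surviving SNP
universe is then imposed on the test split.  The logReg rule is fitted only
on the smallest cascade set (the unpenalized fit is meaningless at larger
p/n), and the largest set is restricted to the logOR and forest methods.

All randomness flows from one master seed through `numpy.random.SeedSequence`
derivations; two runs with the same configuration produce byte-identical CSV
reports.  Reports carry a configuration hash.

Desk-scale method settings: 300 trees per evaluation forest and 150 per
backstep round, chosen as the point where importance rankings and AUCs
stabilize at these problem sizes while the full experiment stays under two
minutes; both are configuration fields.

## Planted-signal test designs

The recovery and retention checks (lasso support recovery, backstep
retention, importance ranking) use fixed planted-signal families rather
than the fully random desk-scale defaults: all SNPs draw MAF from a
moderate 0.2-0.4 band and the causal effects are strong (|log OR| around
ln 1.8-1.9).  With a uniform 0.05-0.5 MAF draw, whether a causal SNP
survives selection is dominated by its MAF lottery rather than by the
selection machinery under test; pinning the band makes these checks
measure the machinery at well-defined power.  Consequences for
interpretation: passing them shows the cascade and the penalized fits
retain and recover detectable signals, not that weak or rare-variant
signals would be retained.

## Numerical choices and degenerate inputs

Monomorphic HWE input returns p = 1; a constant dosage vector gives trend
statistic 0 and p = 1.  Constant scores make the Youden scan return J = 0
with a warning.  Zero allele-table cells invoke the Haldane-Anscombe
correction.  The DeLong comparison of two identical (or rank-identical)
score vectors reports a difference of exactly 0 with p = 1.  Probability
inputs outside [0,1] are rejected rather than clipped.

## Known limitations

The LD model is exchangeable-AR and cannot represent long-range structure;
no missing genotypes, imputation, X chromosome, or covariates; the paired
correct-classification interval is the McNemar-style approximation noted
above; forest "default parameters" follow common R-implementation practice
rather than any one historical software version; and all empirical claims
in this note are limited to what the test suite and the acceptance script
compute on the synthetic family described here.
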