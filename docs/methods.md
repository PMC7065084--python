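# Methods

This package implements a stool-proteomics biomarker-panel discovery
pipeline for colorectal lesions whose progression risk is defined
molecularly, by arm-level DNA copy-number events, rather than by adenoma
morphology. This note records the models, the numerical choices, and what
the synthetic cohort does and does not establish.

## Molecular risk classification

Seven arm-level copy-number changes are treated as cancer-associated events
(CAEs): gains of 8q, 13q and 20q, and losses of 8p, 15q, 17p and 18q. An
adenoma carrying two or more CAEs is classified as high risk of progressing
to carcinoma; an individual is high risk if at least one of their adenomas
is. Only these seven arms influence the rule — other arms are ignored even
when called. The rule is deterministic, monotone (adding an event can never
lower the risk class) and order-independent, and the tests assert all three
properties.

A convenience adapter derives arm calls from pre-segmented log2-ratio
tables by length-weighted averaging over each arm, with gain/loss cutoffs
of +0.2/-0.2 on the log2 scale. These cutoffs are conventions of the
adapter, not calibrated values; segmentation itself is out of scope and
arm-level calls are the intended input boundary.

## Beta-binomial differential abundance

Spectral counts are modelled per protein as y ~ BetaBinomial(n, alpha,
beta), where n is the sample's total spectral count, with the
(pi, phi) parameterization

    alpha = pi (1 - phi) / phi,  beta = (1 - pi)(1 - phi) / phi,

so that E[y/n] = pi, Var(y/n) = pi(1 - pi)(phi + (1 - phi)/n), and phi -> 0
recovers the binomial. Case/control differences are tested by a
likelihood-ratio test: the null model fits a common pi, the alternative one
pi per group; phi is shared between groups under both hypotheses, so the
statistic has one degree of freedom and is referred to chi-square(1). The
two-sided p is combined with a post-hoc direction filter (the sign of the
log2 fold-change), matching a discovery workflow that keeps proteins more
abundant in cases.

Numerical choices:

* Maximization uses L-BFGS-B with box constraints (pi in (1e-9, 1 - 1e-6),
  phi in [0, 0.995]), a method-of-moments start plus one fallback start at
  the pooled proportion with phi = 0.01; the better optimum wins. The
  alternative fit additionally starts from the null solution, which
  guarantees a non-negative LRT statistic.
* Fold-changes use smoothed group proportions (sum y + 0.5)/(sum n + 1) so
  they are finite for zero counts; the likelihood itself uses raw counts.
* An all-zero protein carries no information; it is reported as null
  (log2FC 0, p 1) and flagged.
* Structural zeros are treated as sampling zeros — there is no
  zero-inflation term in the test. The generator's zero-inflation therefore
  stress-tests robustness rather than matching the test's assumptions.
* Multiple testing uses Benjamini-Hochberg by default (configurable to
  Holm/Bonferroni); the discovery field's default for candidate screening.

Candidate proteins are selected under two regimes: a loose regime (log2
fold-change > 0 and raw p <= 0.1) for the small high-risk-adenoma case
group, and a strict regime (log2 fold-change >= 2 and adjusted p <= 0.05)
for the larger combined high-risk + CRC case group. The overlap between the
two candidate lists is tested with the upper-tail hypergeometric
probability, computed with log-gamma terms and log-sum-exp for stability.

## Lasso-logistic panel selection

Panels are fitted by L1-penalized logistic regression over the candidate
proteins: minimize (1/n) NLL + lambda * ||beta||_1 with an unpenalized
intercept. Features are log2(normalized count + 1), centered and scaled to
unit variance on the training samples (normalized count = count / sample
total x median total). The log transform stabilizes the heavy-tailed counts
so standardization is meaningful; constant features are dropped with a
warning.

The solver is cyclic coordinate descent on the iteratively reweighted
quadratic approximation (glmnet-style), with IRLS weights floored at 1e-6
and re-linearization until the exact KKT conditions hold: for zero
coefficients |(1/n) x_j'(y - p)| <= lambda, for active ones equality with
lambda * sign(beta_j), at tolerance 1e-6 or better (direct fits converge to
1e-8; warm-started path points use a relaxed 1e-6/coefficient-change 1e-7
because active-set membership, not the final digits, is what the path walk
consumes). Coordinate order is the candidate-list order, which fixes the
tie-break among exactly collinear features and makes runs reproducible.

A panel of size k is the first model with exactly k non-zero coefficients
along a geometric lambda path (100 points down to lambda_max x 1e-3) walked
from sparse to dense. Correlated candidates can enter or leave the active
set together, so a size can be skipped; the bracketing lambda interval is
then refined once with a 25-point sub-grid, and if the size still never
occurs the panel is reported as not constructible together with the sizes
that were observed. This is the same mechanism by which a four-protein
panel can exist while the three- and two-protein panels cannot.

Class imbalance is left unweighted (plain logistic loss), reflecting a
screening setting where controls legitimately dominate.

## Cross-validated evaluation at high specificity

Because population screening requires very high specificity, panels are
judged on the ROC region with specificity in [0.95, 1]:

* ROC curves enumerate every distinct score threshold with ties grouped;
  the construction is tested for exact equality against brute-force
  enumeration.
* The partial AUC is the trapezoidal area of sensitivity over specificity
  in the band, with linear interpolation at the band edges. It is reported
  raw (in [0, 0.05]) and standardized,
  pauc_std = 0.5 (1 + (raw - A_chance)/(A_max - A_chance)), where A_max is
  the band width and A_chance the area of the chance diagonal in the band,
  so 0.5 is chance and 1 is perfect. The standardization makes values
  interpretable on a familiar AUC-like scale; the raw area is always
  reported alongside.
* Sensitivity at 95% specificity uses the smallest score cutoff that keeps
  false positives at or below floor(0.05 x n_controls) (with 129 controls:
  6 allowed, realized specificity 123/129 = 95.3%). The sensitivity carries
  an exact Clopper-Pearson interval from beta quantiles. Reported
  percentages round half away from zero.
* Leave-one-out cross-validation refits normalization, standardization and
  panel selection without the held-out sample in every fold; a test
  recomputes a fold from scratch to assert the absence of leakage. The
  candidate list itself is computed once on the full data and held fixed
  inside the loop, mirroring the discovery workflow; the optimism this
  induces is stated in the run report. Folds where the requested size is
  not constructible fall back to the largest constructed smaller panel on
  that fold's path (never a larger one) and are counted.
* Panels are compared with a hemoglobin comparator — the log-normalized
  HBA1 spectral count — by stratified bootstrap: cases and controls are
  resampled separately with replacement (2000 replicates by default), the
  standardized pAUC difference is recomputed per replicate, and the
  observed difference divided by the bootstrap SD is referred to the
  standard normal, two-sided.
* Applying a panel to the held-out low-risk adenomas uses the full-data
  panel model and the cutoff that attains the specificity target on its own
  case/control scores, then reports the positive fraction with an exact
  interval.

## Validation statistics

Assay-level validation uses rank-based procedures because immunoassay
concentrations are skewed and case groups small. Spearman correlation uses
mid-ranks, pairwise deletion of missing values, and the t-approximation on
n - 2 degrees of freedom. Group comparisons report the fold-change of group
means (medians alongside) with a two-sided Wilcoxon rank-sum p: full
enumeration over label assignments when the pooled size is at most 16
(exact even under ties), the classical exact distribution when there are no
ties and the smaller group has at most 12 observations, and the
tie-corrected normal approximation otherwise.

## The synthetic cohort

The generator draws cohorts with the statistical structure the analysis
assumes, so every stage is testable end to end without any external data.

* Default class sizes are 129 controls, 56 low-risk adenoma, 15 high-risk
  adenoma and 79 CRC individuals over 790 protein groups; all sizes are
  configurable and tests use smaller cohorts for speed.
* Baseline proportions are heavy-tailed (log-normal weights, sigma = 2,
  normalized), so a few proteins dominate totals and most counts are zero
  or near zero, as in real stool proteomics. Library sizes are log-normal
  with median 20,000 spectra.
* Counts are drawn from the same (pi, phi) beta-binomial law the test
  assumes, so parameter-recovery tests are meaningful. The default
  phi = 0.005 was chosen, together with effect sizes drawn uniformly from
  log2 1.0-2.5, so that the full-scale cohort reproduces the qualitative
  operating point of the motivating study: a high-risk-only panel that
  beats hemoglobin numerically but not significantly (15 cases carry
  little information) and combined high-risk + CRC panels that beat it
  significantly with sensitivity near 60% at 95% specificity. The source
  data report no dispersion or zero-rate estimates; these remain free
  parameters of the generator, not claims about the real data.
* Case effects multiply the affected proteins' proportions by 2^log2fc,
  after which each sample's proportions are renormalized — totals stay
  realistic, at the cost of a small compositional depression of all other
  proteins. Differential proteins are drawn from the middle-to-upper
  baseline-abundance band (quantiles 0.5-0.95 by default): candidate
  biomarkers must be detectable, while a dominant protein would distort
  every other proportion through the renormalization.
* Structural zeros are injected at rate 0.05 on top of the count law.
* A single latent bleeding intensity (log-normal, class-dependent mean:
  CRC >> high-risk > low-risk > control) multiplies the hemoglobin-family
  proteins' proportions and drives the FIT value; haptoglobin receives a
  damped bleeding component plus a class-dependent tissue component. This
  reproduces the hemoglobin/haptoglobin/FIT correlation structure by
  construction, and assay noise can be calibrated to a target Spearman
  correlation through the Gaussian-copula relation rho_s = (6/pi)
  asin(r/2).
* Arm-call profiles draw each CAE independently with a per-arm probability
  calibrated so that P(Binomial(7, p) >= 2) = 0.158, the high-risk fraction
  the rule should produce; adenoma morphology is assigned with
  P(advanced | high risk) = 0.80 and P(advanced | low risk) = 0.26, which
  reproduces high-risk fractions of roughly 36% among advanced and 5% among
  non-advanced adenomas. Within a cohort, profiles are rejection-sampled to
  agree with each patient's designed risk class, and each adenoma patient
  carries 1 + Poisson(0.34) adenomas.

What passing tests on this cohort do not show: robustness to
peptide-to-protein inference errors, to intensity-based (non-count)
quantification, to batch effects, or to zero-generating mechanisms other
than the injected structural-zero rate. The generator matches the analysis
model by design; it demonstrates correctness and calibration of the
machinery, not performance on real stool proteomes.

## Problem sizes used by the test suite and the reproduction script

The reproduction script (`scripts/acceptance.py`) runs the full pipeline at
the default design (790 proteins x 279 samples, 2000 bootstrap replicates).
The test suite uses smaller cohorts chosen per property: the type-I-error
check uses 1000 null proteins over 30 + 30 samples; the end-to-end recovery
check uses 129 controls and 60 cases with four truly elevated proteins
(log2 effect 1.6, phi 0.005, abundance band 0.65-0.95) among 31 candidates
— conditions under which the markers are reliably recoverable across
seeds, so that the selection-frequency property is a test of the machinery
rather than of one lucky draw.

## Known limitations

* The LRT p-value relies on the chi-square(1) asymptotics; calibration is
  verified by simulation at the defaults but very small groups or extremely
  rare proteins will be less well calibrated.
* The path-based panel search reports not-constructible relative to its
  grid (after one refinement); an adversarial geometry could in principle
  hide a size between grid points.
* The bootstrap comparison uses the normal approximation on the difference
  statistic, the convention of the ROC-comparison literature it follows,
  rather than percentile intervals.
* Patient-level and sample-level units coincide in the generator (one
  stool sample per individual); repeated samples per patient are not
  modelled.
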