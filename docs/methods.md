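# Methods

## The measurement problem

Viewing reaction time (VRT) is an indirect, latency-based measure of sexual
interest: when people rate the sexual attractiveness of images as quickly as
possible, they dwell longer on categories they find sexually salient.  The
paradigm modelled here presents 8 trials in each of 10 stimulus categories —
male and female figures in Tanner stages 1–5 of pubertal development — with a
5000 ms response window; a trial without a response in the window is recorded
as missing.  The package implements the full analysis pipeline for such data:
eligibility filtering, imputation of timed-out trials, within-person
standardization, a max-difference interest index, an equivalence-testing
regression of the index on diagnosis and offense-history dummies, subgroup
ROC accuracy with a CI-encompassment equivalence rule, and Spearman
criterion-validity tables against actuarial risk instruments.

## The VRT index

Raw latencies are *ipsatized*: z-standardized within each participant over
all of their valid trials pooled across categories (n−1 denominator).  This
removes individual differences in general response speed, putting every
participant on a within-person-SD scale.  We interpret "ipsatized" as full
z-standardization rather than mean-centering only because the index is then
naturally read in within-person SD units (the clinical contrast of interest
is about one such unit), and because the stated purpose of the step is to
control for group differences in general reaction time, which centering
alone does not fully achieve when trial-level variability differs between
groups.  Mean-centering is available via `ipsatize(..., mode="center")`.

The index for one participant is

    VRT index = max over child categories (MT1–MT3, FT1–FT3) of the mean
                ipsatized latency  −  max over adult categories (MT4, MT5,
                FT4, FT5) of the mean ipsatized latency.

Maxima rather than averages are used so that a strong interest in one target
sex is not diluted by averaging with the other.  A positive index means
longer dwelling on child than adult stimuli.  Ties in a maximum (possible
after mean imputation) break deterministically by fixed category order (male
before female, ascending Tanner stage) and the winning categories are
recorded.  Imputation of raw latencies runs *before* ipsatization because
all three imputation schemes are defined on raw reaction times per category;
the reverse order would impute on a scale that itself depends on which
trials are missing.

## Eligibility

A participant enters the analysis only if

* the fraction of missing trials is not above 10%.  The boundary case is a
  declared decision: strictly-greater-than excludes, so exactly 10% (8 of
  80) is retained.  The threshold is configurable.
* every one of the 10 categories has at least one valid trial (the index
  requires all 10 category means);
* the test took place within 28 days (four weeks) of the clinical
  interview.  Unknown intervals are eligible by default — exclusion is made
  on documented intervals only — with a switch to exclude them;
* the clinical diagnosis is known.

Reasons are accumulated, not mutually exclusive, and every excluded
participant carries at least one.  No lower latency floor is applied by
default; an anticipatory-response cutoff can be configured but is off.

## Imputation

Three schemes for missing latencies, mirroring common practice for this
paradigm:

* **individual mean** — the participant's own observed mean in the same
  category; deterministic, the reference method;
* **whole-sample regression** — per target category, OLS over the whole
  sample predicting a participant's category mean from their other observed
  category means; missing trials take the prediction; deterministic;
* **predictive mean matching (PMM)** — the same predictive model with
  type-1 matching: each missing cell receives an *observed* donor value
  drawn uniformly from the k = 5 donors whose predictions are nearest;
  m = 5 completed datasets.  With *individuals as separate classes* the
  donor pool is restricted to the participant's own observed trials in the
  target category.  This donor-pool reading of "individuals as separate
  classes" is one plausible interpretation of an under-specified phrase and
  is the main interpretive choice of this module; within-participant
  donors share one prediction, so the draw is effectively uniform over the
  participant's own observed values.

Predictive models operate on the participant-by-category mean matrix and
assign one value per missing trial, retaining per-category trial counts.
m = 5 follows the convention of five imputed datasets; k = 5 is the
standard PMM default.  Multiply imputed fits are combined by Rubin's rules
(pooled estimate = mean, total variance T = W + (1+1/m)B) with the
Barnard–Rubin small-sample degrees of freedom; when B = 0 the
complete-data df is used.

## Equivalence-testing regression

The index is regressed on dummy-coded diagnosis (P), prior child sexual
offenses (CSO), prior child sexual abuse material use (CSAM), and all
interactions, by OLS with t-based CIs (t CIs reproduce published
coefficient tables from printed β/SE/df to 4 decimals; normal-quantile CIs
do not).  Externally studentized residuals beyond |3| are reported as
outliers.  The smallest-effect-size-of-interest region for the diagnosis
interactions is

    −LL95(β_P)  <  β_interaction  ≤  0 ,

i.e. an interaction is negligible unless it could cancel the diagnosis
effect (lower bound) or amplify it (conservative upper bound of zero).
Equivalence is assessed at α = 0.05 with 90% CIs (TOST logic): the upper
boundary is violated when UL90 > 0 (strict), the lower when
LL90 + LL95(β_P) ≤ 0.  The lower-violation arithmetic follows the
footnote convention of the published coefficient table — "the negative of
the lower limit" — which resolves an inconsistency in the prose statement
of the hypotheses.  No multiplicity adjustment is applied across the three
interaction verdicts.  With multiply imputed data, bounds and verdicts
derive from the Rubin-pooled coefficients.

## Subgroup ROC comparison

Two ROC analyses classify diagnosis from the index (higher index ⇒
predicted diagnosed), one within participants with an offense history
(CSO or CSAM) and one within participants with neither.  AUC is the
Mann–Whitney probability with ties counted ½.  CIs are stratified
(within-class) percentile bootstrap with 2000 replicates by default
(configurable).  Equivalence of accuracy uses the encompassment rule: the
offense-history group's 95% CI must contain the no-history group's 90% CI
(closed intervals).  AUCs are compared by the unpaired DeLong test with
placement-value variances and Welch–Satterthwaite fractional degrees of
freedom (component df = group total − 1), matching the pROC reference
implementation to 10 decimals on a frozen fixture.  The optimal cutoff
maximizes Youden's J on both groups combined; the reported threshold is
the midpoint between adjacent observed scores and J-ties resolve toward
the higher-specificity cutoff.  Published results report two different
"optimal" cutoffs (−0.5 and −0.3) in different sections; neither is
treated as ground truth here.

## Criterion scales

SSPI-2 (sum of five yes/no items, 0–5), an adapted static actuarial risk
scale (index-offense violence dropped, age at assessment < 25 replacing
age at release; documented maximum total 11 under our coding with the
prior-sex-offenses item graded 0–3), STABLE-2007 (13 items 0–2) and
ACUTE-2007 (7 items 0–2).  Factor scores follow the published factor
definitions: static paraphilia (5 components), youthful stranger
aggression (4 components — the published observed range of 0–3 conflicts
with the 4-component definition; the definition wins), general
criminality (convictions count + violence); STABLE antisociality (7 items
with capacity-for-relationship-stability reverse-coded), sexual deviance
and hypersexuality (2 items each).  A score is NA exactly when one of its
constituent items is unknown.  Raw scores only — no norms or recidivism
probabilities.

## Synthetic cohort generator

The generator emulates the data situation of a Dunkelfeld (help-seeking,
non-forensic) clinical cohort.  Defaults are the published descriptive
structure: per-group per-category latency means/SDs and rating means of
the study's descriptive table, group sizes 68 (no sexual interest in
minors) vs 214 (any such interest), and offense-history margins (any CSO
84/282, any CSAM 202/282, neither 49/282) converted to four cells
(CSO-only 31, CSAM-only 149, both 53, neither 49).  The diagnosis is
crossed with the offense cells independently because the joint table is
not published; this is an assumption.

Per trial:  latency = group/category mean + speed_i + pref_ic + noise,
clipped below at 150 ms, with

* speed_i ~ N(0, 470 ms): general response speed.  470 ms is set from the
  published SDs of the mean overall viewing reaction time (426 and 518 ms),
  which for an 80-trial mean is essentially the between-person speed SD;
* pref_ic ~ N(0, 400 ms): person × category preference.  Without this
  term every participant in a group would have an identical noise-free
  index (the speed offset cancels in a max-minus-max contrast), leaving
  nothing for criterion scores to correlate with and far less
  between-person index spread than the published raw-index SDs (659 and
  558 ms).  400 ms puts the simulated raw-index SD near those values;
* noise ~ N(0, category SD) per trial, using the printed per-category SDs;
  a log-normal option with matched mean/SD is exposed since reaction times
  are right-skewed.

Latent latencies above 5000 ms become missing trials — missingness that is
MAR by category, since slow categories lose more trials — plus an extra
MCAR rate of 2%.  Censoring alone produces well under 1% missingness at
the published means, too little to exercise the imputation machinery, so
the MCAR component represents the non-response seen in practice while
keeping nearly all simulated participants under the 10% eligibility rule.
All randomness is drawn before censoring is applied, so lowering the
censor threshold on the same seed only adds missing trials.  Ratings are
a rounded, clamped Gaussian around the printed group/category rating
means.  Degenerate configurations (n = 0) return empty tables.

Criterion scores are generated by a Gaussian copula on the participant's
*latent deviance* — the true, noise-free max-child − max-adult contrast in
ms — using the Spearman-to-copula conversion r = 2 sin(πρ/6) and binomial
quantile marginals near the published scale descriptives.  Default rank
correlations are the published index column of the correlation table
(SSPI-2 0.27 … STABLE sexual deviance 0.47).  Discretization to coarse
ordinal scales attenuates the realized ρ slightly (≈ 0.04 at ρ = 0.9 for
a 6-level scale), within the tolerance the calibration tests use.

**What the generator does not model:** order/sequence effects,
task-instruction effects, the post-interview testing context, within-person
covariance between categories beyond the speed + preference random effects
(the published data report only marginal per-category moments), and any
dependence of diagnosis on the offense cells.  Passing tests therefore
demonstrate that the pipeline recovers the structure this generator
encodes, not that the VRT paradigm is valid in real cohorts.

## Numerical and design choices

* Yates-corrected 2×2 chi-square is the default cohort-comparison test
  because it reproduces the published comparison column from printed
  counts to 2 decimals (verified for five rows); the uncorrected statistic
  is available.  Some published rows do not reproduce from printed counts
  (likely undocumented missing data) and are not used as fixtures.
* Spearman correlations use averaged ranks for ties, pairwise-complete n
  per pair (reported), and the t-approximation for p-values (uniform under
  the null by KS in the test suite).
* ICC(1) is the one-way random-effects intraclass correlation,
  (MSB − MSW)/(MSB + (k−1)MSW), with an F-based 95% CI; items with missing
  ratings are dropped for a balanced ANOVA, and zero-variance rating sets
  return "not calculable" rather than a number.
* Problem sizes in the simulation-based tests — 500 pipeline replicates of
  n = 282 for CI coverage, 200 replicates for bootstrap-interval coverage,
  1000 null replicates for the p-value uniformity checks, a single n =
  20 000 cohort for the generator-implied contrast — were chosen so that
  Monte-Carlo error is small relative to the asserted bands while a full
  run of the suite stays in the low minutes on one core.
* The ß-coverage experiment regresses the pipeline's index on the
  diagnosis dummy alone; its 95% CI covers the generator-implied contrast
  (estimated once from the large cohort, Monte-Carlo SE ≈ 0.015 ≪ the CI
  half-width of ≈ 0.25) at 93–97% over replicates.

## Known limitations

* The whole pipeline treats the diagnosis as ground truth; nothing here
  validates the clinical diagnostic procedure itself, and the tool reports
  statistics, never a diagnosis.
* The equivalence region is data-dependent (it derives from the fitted
  diagnosis effect), so verdicts inherit that estimate's sampling error.
* PMM's "individuals as separate classes" is one reading of an ambiguous
  specification; results under that method should be interpreted with the
  donor-pool definition above in mind.
* The generator's Gaussian latency model matches the published means and
  SDs but not necessarily the shape of real latency distributions; use the
  log-normal option for skew-sensitivity checks.
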