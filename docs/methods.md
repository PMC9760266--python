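# Methods

## Problem and endpoint

The package models a binary endpoint — admission to a palliative care unit
(PCU) within six months of the first visit ("early deterioration") — in
treatment-naïve advanced cancer patients, from two data sources: routine
clinical covariates (demographics, stage, ECOG performance status, 17
laboratory values) and serum miRNA levels measured on a 2,588-probe
oligo-chip microarray. Three model families are built: a clinical-only
linear diagnostic index, miRNA-panel discriminants, and combined
miRNA + clinical indices.

## Microarray preprocessing

Raw per-spot fluorescence is processed per sample:

1. **Chip QC.** A sample is excluded when the coefficient of variation of
   its negative-control spots exceeds 0.15 or more than 10 spots are
   flagged as uneven images. Both thresholds are strict (`>`); values
   exactly at the threshold pass. The CV is computed on the linear scale,
   the conventional scale for spot-level QC.
2. **Presence call.** A probe is "present" when its raw signal exceeds
   mean + 2·SD of the negative-control spots after trimming
   `floor(0.05·m)` spots from each extreme of the sorted list (SD with
   denominator m′−1). The floor rounding keeps small control sets intact.
   The threshold is not monotone in individual spot values (raising a
   below-mean spot shrinks the SD) — the properties that do hold, and are
   tested, are shift/scale equivariance and permutation invariance.
3. **Background subtraction.** The untrimmed negative-control mean is
   subtracted on the linear scale and the result log2-transformed.
   Subtraction happens before the log because the floor rule is defined on
   the log2 scale. A switch (`subtract_trimmed_mean`) uses the trimmed
   mean instead; the untrimmed mean is the default reading of "the mean
   signal of the negative controls".
4. **Floor replacement.** Probes that are absent, flagged, or non-positive
   after subtraction receive the sample's lowest detected log2 value minus
   0.1. Flagged spots are treated as undetected for that sample in
   addition to counting toward chip QC.
5. **Internal-control normalization.** Each sample is shifted so that the
   mean log2 level of miR-149-3p, miR-2861 and miR-4463 equals a common
   target — by default the grand mean of the per-sample control means over
   retained samples (an absolute constant is configurable). Samples in
   which any control probe fails its presence call are excluded with a
   warning. The operation is idempotent and removes any per-sample
   common-mode (array gain) offset exactly; with a fixed absolute target
   the removal is exact to machine precision, which the test suite asserts
   at 1e-6.

## Clinical screening and index models

Laboratory covariates are tested with the pooled-variance (Student)
two-sample *t*-test; categorical covariates (sex, primary site, stage,
performance status, age dichotomized at 65 years, BMI at 22 kg/m²) with
Pearson's chi-square without continuity correction. The pooled *t* (not
Welch) and the uncorrected chi-square are the variants that reproduce the
published summary-table p-values from its own printed summaries (LDH
0.004, Neut 0.007, PS 0.031); Welch would give LDH ≈ 0.13. Selection is
*p* < 0.05. One caveat found while validating: the printed creatinine
summaries (0.7 ± 0.2 vs 0.8 ± 0.2) imply p ≈ 0.015 although the published
p-value from unrounded data is 0.923 — one-decimal rounding manufactures a
difference. The printed-summary screen therefore flags Cre in addition to
the published significant set, and the tests document exactly that.

The multivariate model is a **linear probability model**: OLS of the 0/1
outcome on the selected covariates, performance status entered as an
integer score (0/1/2). OLS is used because the published index is an
unconstrained linear score whose intercept (−7.819) and coefficient
magnitudes are inconsistent with a logistic scale on these covariate
ranges; a logistic fit of the same design is available via
`family="logistic"`. In the univariate screen PS is tested as a 3-level
categorical (reproducing p = 0.031); in the index model it is a single
integer-scored term, matching the single published PS coefficient. Other
selected categorical variables (site, stage, dichotomized age/BMI) are not
carried into the index model, mirroring the published variable set.
Missing data fail fast; the generator produces complete data.

## miRNA panel search

Panels are grown by beam search of width 10 up to `k_max` = 10 probes. A
candidate probe set is scored by the AUC of its pooled leave-one-out
cross-validated Fisher LDA scores: for each left-out sample the class
means and pooled within-class covariance are downdated in closed form
(rank-one update, verified against explicit refits to 1e-15) and the
held-out sample is scored against the refitted midpoint intercept. A
relative ridge (1e-8 × trace/k) keeps near-singular pooled covariances
invertible; zero-variance probes are skipped with a warning. Ties in AUC
are broken lexicographically on the sorted probe-index tuple, making the
search deterministic across platforms. Duplicate probe sets reached via
different parents are collapsed before ranking.

The working panel size k\* is the smallest size whose mean top-10 LOOCV
AUC is within epsilon (default 0.002) of the curve's maximum — a "ceiling"
rule; epsilon is a configuration knob since the original procedure states
no explicit value.

Two caveats are intrinsic to the procedure and documented in the result
summary. First, LOOCV covers weight fitting within a fixed probe set;
probe-set *selection* happens outside the CV loop, so reported AUCs carry
selection optimism (under a global null with 500 probes the selected
candidates score well above 0.5, while a fixed panel scores 0.5 — both
are tested). Second, LOOCV AUC is not monotone in panel size; only the
resubstitution AUC of the exhaustive best panel is, which the tests assert
against brute force on small pools. The original description credits a
logistic LASSO in one place and the Fisher-LDA beam search in another; the
beam search is implemented as the canonical path.

## Combined models

Each retained panel is refitted jointly with the clinical covariates into
a single OLS index — one coefficient per probe log2 level and per clinical
variable, rather than entering the panel's scalar discriminant score,
because the published combination model carries a coefficient per miRNA.
The clinical coefficients are re-estimated jointly (the published combined
model's Alb coefficient, 1.693, differs from the clinical-only 1.819,
which supports joint refitting). An empty probe set reduces exactly to the
clinical-only refit.

## Evaluation

AUC is the Mann–Whitney probability with ties counted ½ (verified against
the O(n²) pairwise oracle). Operating points report sensitivity,
specificity, PPV and NPV at a cutoff chosen by Youden's J over observed
score values, ties broken toward higher specificity; the original cutoff
rule is unstated (its published clinical operating point, sens 0.448 /
spec 0.973, suggests a non-Youden choice), so the rule is a configuration
flag and the report records it. PPV/NPV follow the Bayes identity at the
sample prevalence; degenerate empty predicted classes report 1.0 with a
warning flag. The paired DeLong test uses midrank placement values, the
2×2 covariance of the paired placements, and a two-sided normal reference;
its variance is validated against a 5,000-replicate paired bootstrap
(within 15%) and its empirical size at α = 0.05 against 1,000 null
replicates (within [0.03, 0.07]). No multiplicity correction is applied
across the ten combination-model comparisons.

## Synthetic cohort generator

The generator emulates the study conditions: 178 patients with
round(29/178·n) early-deterioration events, covariate distributions taken
from the published per-group means/SDs and category counts, and a chip
signal model with per-sample array gain offsets, negative-control spots,
three internal controls and flagged spots.

Numerical choices:

- **Continuous covariates** are drawn per outcome group from left-truncated
  normals (floor 0 for laboratory values, physiologic floors for age, BMI,
  electrolytes). The printed SD is used as the scale and the location is
  solved (Brent root-finding on the truncated-normal mean) so the
  *truncated* mean equals the printed group mean. For strongly skewed labs
  (CRP, T-Bil, ALT) no truncated normal can match both printed moments —
  the printed coefficient of variation exceeds the truncated-normal
  maximum — so means are matched exactly and realized SDs fall below the
  printed ones. Covariates are mutually independent given the outcome
  (only marginals are published); this inflates multivariate separation
  relative to the real cohort, which is one reason synthetic clinical AUCs
  (~0.9) exceed the published 0.741. Correlation structure is a
  deliberate non-goal.
- **Probe signals** are log-normal: per-probe baseline ~ N(6.5, 2.0) log2
  units, per-sample array offset ~ N(0, 0.3²) log2 shared by every spot of
  the sample (making normalization non-trivial), and per-probe per-sample
  noise ~ N(0, 0.8²) log2 — inter-patient biological variability plus
  technical noise, the dominant realistic scale for serum miRNA levels.
  Informative probes add their log2 effect (default six probes at 1.0, a
  2-fold change) to event-group samples, and draw their baselines from the
  upper half of the baseline distribution: a biomarker candidate is by
  definition a reliably detected miRNA, so effects are never planted on
  probes below the detection floor.
- **Negative controls** are log-normal with log2 mean 4.0 and log2 SD
  0.115, giving chip-realistic CVs (~0.08, passing QC) and leaving roughly
  10–20% of target probes below the presence threshold (measured ≈ 14%).
  Internal controls sit at log2 10 with 0.05 noise.
- **Flags** are Bernoulli per spot (default rate 0.001, ≈ 0.3 flags per
  array, occasionally excluding a sample whose internal control is hit —
  exercised deliberately).
- All randomness flows from a single integer seed through named
  sub-streams; no global state is touched. Generation is byte-identical
  across runs with equal seeds.

What passing tests on this generator do **not** show: performance on the
real cohort. The generator's covariates are conditionally independent, its
probe effects are planted and homoscedastic, and its noise is Gaussian on
the log scale; real serum profiles are correlated, heteroscedastic and
batch-structured. The published headline AUCs (clinical 0.741, best
combined 0.806) are therefore not reproduction targets — the synthetic
pipeline validates the *machinery* (statistics, search, calibration,
invariants), not the clinical effect sizes.

## Problem sizes used in tests and the acceptance script

Tests and the acceptance run scale the chip down (typically 80–500 target
probes, k_max ≤ 6, ten generator seeds for the recovery experiment, 1,000
null replicates for DeLong size, 5,000 bootstrap replicates) — sizes chosen
so the full validation runs in minutes on one CPU while keeping every
statistical check at its stated tolerance. The planted-probe recovery
experiment at these conditions (effect 1.0 log2, noise 0.8 log2, 500
probes, n = 178) recovers on average ~4 of 6 planted probes in the best
6-probe panel; recovery is sensitive to the effect-to-noise ratio, and at
technical-noise-only levels (0.3 log2) it is near-perfect.

## Known limitations

- The linear probability model can produce indices outside [0, 1]; it is a
  scoring device, not a calibrated probability.
- Selection optimism of the panel search is reported, not corrected; a
  nested-CV wrapper would be the natural extension.
- The DeLong normal reference is slightly liberal at very small event
  counts; measured size at 20 events / 60 samples is ≈ 0.052.
- PPV/NPV are prevalence-bound to the cohort's 16.3% event rate and do not
  transport to populations with different referral mixes.
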