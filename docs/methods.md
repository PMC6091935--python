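# Methods

This note documents the statistical model, the identification arguments,
the synthetic data generator, and the numerical and design choices made
where more than one defensible option existed.

## Misclassification model and prevalence estimation

Every questioning design is reduced to a misclassification pair
`(p₁|₁, p₁|₀)` with `p₁|y = Pr(Y = 1 | Y* = y)`, known by design:

| design | p₁|₁ | p₁|₀ | identifiability constraint |
|--------|------|------|----------------------------|
| DQ | 1 | 0 | — |
| CM | p_z | 1 − p_z | p_z ≠ 1/2 |
| UQ | 1 − p_u(1 − p_z) | p_u·p_z | p_u < 1 |
| FR | 1 − p_no | p_yes | p_yes + p_no < 1 |

Prevalence is the linear inversion `π̂ = (Ȳ − p₁|₀)/(p₁|₁ − p₁|₀)` with
variance `V(Ȳ)/(p₁|₁ − p₁|₀)²`, `V(Ȳ) = Ȳ(1 − Ȳ)/(n − 1)`.  Note the
`n − 1` denominator: it is kept exactly in this form so that the delta
method applied to a single mean reproduces the closed-form standard
error to the last bit.  For the crosswise model with a rare unrelated
question (p_z ≈ 1/6 here) the slope `p₁|₁ − p₁|₀ = 2p_z − 1` is
*negative*; all formulas handle the sign, and only `p₁|₁ = p₁|₀`
(p_z = 1/2) is rejected as unidentifiable.

Estimates outside [0, 1] are returned unmodified.  This is deliberate: a
significantly negative estimate is the canonical symptom of
non-compliance with a forced-response design and would be destroyed by
truncation at the estimation layer.

Confidence intervals are Wald intervals with z = 1.96 throughout.  Where
respondents within one arm faced different unrelated questions, the
inversion uses the arm-average pair; because the device outcome is
independent of the true answer, `E[Ȳ] = p̄₁|₁ π + p̄₁|₀ (1 − π)`, so the
average pair is the correct inversion target, and for CM/UQ (linear in
p_z) it equals the pair evaluated at the arm-average p_z.

## Individual-level validation

Write `X*` for a true win, `X` for a claimed win; cheaters have
`X = 1, X* = 0`.  Both dice games have `Pr(X* = 1) = 1/6` by design.

**Observed truth (roll-a-six).**  TPR and FPR are the
misclassification-corrected conditional prevalences in the cheater
(`X ≠ X*`) and non-cheater (`X = X*`) groups, and
`CCR = TPR·Pr(X≠X*) + (1−FPR)·Pr(X=X*)`.

**Latent truth (prediction).**  Under A1 (no false losers) the cheating
rate is `Pr(X=1) − 1/6`.  With `inv(q) = (q − p₁|₀)/(p₁|₁ − p₁|₀)`:

* A1+A2 (winners' and losers' false-positive rates equal):
  `FPR = inv(Pr(Y=1|X=0))` and
  `TPR = [Pr(X=1)·inv(Pr(Y=1|X=1)) − (1/6)·inv(Pr(Y=1|X=0))] / (Pr(X=1) − 1/6)`.
* A1+A2′ (winners' false-positive rate zero): the winner joint term
  drops from the TPR numerator, and the *overall* FPR reweights onto
  true losers: `FPR′ = Pr(X=0)·inv(Pr(Y=1|X=0)) / (Pr(X=0) + 1/6)`,
  i.e. `FPR′ = FPR · Pr(X=0)/(Pr(X=0) + 1/6) ≤ FPR` whenever `FPR ≥ 0`.

A negative FPR estimate (possible after inversion) is truncated to zero
**only inside the CCR**; the reported `fpr` field keeps the raw value
with an `fpr_truncated` flag, preserving its diagnostic content.

A sample whose claim rate does not exceed 1/6 carries no identifiable
cheating mass; the latent-truth estimator refuses it with an explicit
error rather than returning an exploding ratio.

## Variances

Every statistic in both regimes is a smooth function of three
per-respondent means — `(c̄, ā, b̄)` with `c = 1{X≠X*}`, `a = Y·c`,
`b = Y·(1−c)` for observed truth, and the analogue with `x = X` for
latent truth.  The covariance of the mean vector is the sample
covariance (ddof = 1) divided by n (consistent with the
`Ȳ(1−Ȳ)/(n−1)` convention), and standard errors propagate through
analytic gradients (delta method).  When the FPR is truncated inside the
CCR, the truncated branch has zero gradient in the FPR components
(sub-gradient of `max(·, 0)` on the active branch).

The nonparametric bootstrap resamples respondents with replacement
within the arm, re-estimates, and reports the SD over B replicates
(default B = 2000, seeded, deterministic).  Degenerate replicates (empty
conditioning group, no cheating mass) are redrawn and counted; more than
1% redraws triggers a warning since it indicates an estimate near an
identification boundary.  Delta is the default variance method; the
bootstrap is the cross-check, and the test suite verifies the two agree
within 10% and that both track the true sampling SD.

## Randomizing devices

The UQ routing digit follows Benford's law,
`Pr(d) = log₁₀(1 + 1/d)`, sampled by inverse CDF; the cumulative
probability of digits 1–5 (the sensitive-question route) telescopes to
`log₁₀ 6 ≈ 0.778`.  Birthday-question "yes"-probabilities use a
uniform-birthday convention with a 365.25-day year and 12 equal months
of 30.4375 days (e.g. "first half of the month" = 15/30.4375, "between
the 1st and the 6th" = 72/365.25).  These are defaults, not claims: any
p_z can be overridden with an empirically estimated proportion via
`RRTDesign.replace_pz`.  The FR field allocation defaults to
8/12 "Answer question", 2/12 forced "yes", 2/12 forced "no" and is fully
configurable.

## Synthetic data generator

The generator emulates the survey's data-generating process per
respondent in a fixed order: game arm → die roll (uniform 1..6; the
prediction game wins on a privately predicted face, the roll-a-six game
on a six, both 1/6) → cheat decision (losers only, per-game propensity)
→ claim and true answer → technique arm (1/8, 3/8, 2/8, 2/8) → device
outcome → behavior class → observed response.  Respondent-level
artifacts (survey completion 0.995, screener pass 0.97, roll recorded
0.98) feed the exclusion pipeline; false losers are off by default so A1
holds by construction (an optional rate switches them on).

Behavior defaults are the study conditions: cheat propensity among
losers 0.30 (prediction) / 0.06 (roll-a-six), giving overall cheating
rates near 25% and 5%; behavioral truthfulness of cheaters calibrated so
the measured TPRs land near the observed ones (prediction: DQ 10%,
UQ 15%, CM ≈ 28%, FR ≈ 10%; roll-a-six: DQ 70%, CM ≈ 45%, UQ ≈ 43%,
FR ≈ 42%); CM instrument confusion 0.21 / 0.24 (a confused respondent
answers uniformly, so the induced FPR is confusion/2 ≈ 10–12%); and FR
self-protective "no"-saying 0.10 (inducing a mildly negative FPR).  The
confused-response distribution is a modeling choice — nothing in the
observed data pins down *how* confused respondents answer, only that a
stable fraction of CM respondents produces false positives.  CM
self-protective responding is likewise modeled as uniform because the
crosswise design has no unambiguous safe answer; for DQ/UQ/FR it is a
deterministic "no".  Non-game items (shoplifting 0.40, tax evasion 0.15,
non-voting 0.35) are answered truthfully by compliant respondents, so
technique differences on them isolate instrument noncompliance; a
social-desirability mechanism for these items is not modeled.

Randomness uses one master seed and a fixed-width block of uniforms per
respondent, so a change in any allocation parameter re-maps only the
draws it consumes: arm-share changes never reshuffle other respondents,
and identical seeds give bit-identical tables.

What passing tests on this generator do **not** show about real data:
the generator satisfies A1/A2 by construction (unless switched off),
uses constant behavior within each game × technique cell, and has no
covariate structure, panel conditioning, or selective attrition — so the
tests validate the estimators and identification algebra, not the
substantive assumptions themselves.

## Pipeline conventions

Exclusion rules run in a fixed order (screener failures, unrecorded
rolls, roll-a-six false losers), each record attributed to the first
rule it fails, with a ledger that must conserve counts.  The single
false loser is an exclusion, not a model feature.  The non-voting and
dice-game honesty items are reverse-coded; recoding is an involution.
Item nonresponse is handled by per-item listwise deletion.  Differences
between techniques use two-sided Wald z-tests; no multiple-testing
correction is applied (none is needed for the descriptive tables, and
the output records this).  The comparative stage pools both games for
the three non-game items and splits the cheating item by game.

## Problem sizes used in the test suite

Parameter-recovery and agreement checks run at n = 10⁵ per arm (3
Monte-Carlo SEs tolerance); variance calibration uses 2000 replications
at n = 2000 and bootstrap B = 2000; interval coverage uses 2000
replications at n = 1000 (accepting 93–97% at nominal 95%); the
acceptance script reproduces the study scale (6,505 recruited) and adds
a 200,000-respondent run where Monte-Carlo noise is negligible.

## Known limitations

* The latent-truth identification inherits A1/A2(′) — violations bias
  TPR/FPR in ways the package flags only indirectly (e.g. negative
  estimates).
* Delta-method variances are first-order; near identification
  boundaries (cheat rate → 0) they degrade, which is why the bootstrap
  counts and warns about degenerate resamples.
* Regression-style modeling of sensitive answers on covariates is out
  of scope; covariates pass through untouched.
* Estimates for small arms at the original study scale carry large
  sampling error (a DQ roll-a-six arm has ~20 observable cheaters); the
  acceptance script therefore reports both study-scale and large-sample
  values.
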