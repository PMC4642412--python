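# Methods

`tailorpa` implements the analysis chain of a web-based personalized
physical-activity (PA) intervention trial: minute-epoch accelerometry is
processed into energy-expenditure outcomes, PA adequacy drives a rule-based
tailored-feedback engine with four personalization levels, and intervention
effects are estimated with three orthogonal group contrasts. Because the
trial's raw wearable data are not public, a synthetic cohort generator with
known ground truth stands in for them; every downstream stage is exercised
against that ground truth or against independent brute-force oracles.

## Accelerometer processing

**Count-to-PAL model.** The device exports one activity-count total per
1-minute epoch. Daily physical activity level is linear in the summed
counts over 24 h:

    PAL = 1.354 + 256e-9 × counts_day

Counts are first multiplied by a wearing-position correction factor
(belt = 1.0 reference). The published factors for the other positions are
not available, so the shipped table is belt-equivalent (all 1.0) and a
calibrated table can be supplied as a CSV. Per-minute PAL applies the same
regression to the minute's corrected count rate sustained over a day
(counts/min × 1440), so a constant count rate yields identical per-minute
and daily values. This 1440-scaling is this package's documented surrogate
for the device vendor's unpublished per-minute estimator.

**Non-wear detection.** A Choi-style rule adapted to PAL units: an interval
of ≥ 90 consecutive minutes of per-minute PAL < 1.3889 is non-wear, with
allowance for spikes of ≤ 2 consecutive above-threshold minutes when the 30
values immediately upstream *or* downstream of the spike are all
sub-threshold (disjunctive, taken literally from the rule's wording). A
spike failing the test terminates the interval. Flank windows may overlap
the candidate interval itself, and any number of admissible spikes may
occur. Missing epochs are treated as sub-threshold for detection and as
non-wear for wear-time accounting, so every minute of a day is classified
and `wear + non-wear = 1440` always holds. Detection runs on the continuous
series; runs are split at local midnight for daily accounting. The
implementation is a linear run-length scan; tests check it exhaustively
against a window-enumeration oracle over a run-length grammar spanning all
boundaries of the 90/2/30 rule.

**Valid days and windows.** A valid day has 10–18 h of wear, both bounds
inclusive (600–1080 min). Weekend = Saturday and Sunday. Each timepoint is
assessed over the 14 calendar days ending the day before feedback
derivation; the window is *sufficient* with ≥ 3 valid weekdays and ≥ 2
valid weekend days. Insufficient windows are flagged, never imputed.

## Energy expenditure and intensity

Basal metabolic rate comes from the Henry/Oxford weight-only equations
(CSV fixture; bands 18–30, 30–60, ≥ 60 years by sex, band lower bounds
inclusive), published in MJ/d and converted at 239.005 kcal/MJ. Daily
activity energy expenditure is `AEE = (0.9 × PAL − 1) × BMR`, reported as
computed (it is negative below PAL ≈ 1.11, not clamped). The per-minute
AEE rate divides the same relation by weight and 1440 min and is floored
at 0 so sub-basal minutes classify as sedentary.

Intensity cut-points are 0.025, 0.05 and 0.1 kcal/(kg·min), identically
MET/60 for 1.5, 3 and 6 METs under the 1 MET = 1 kcal/(kg·h) convention.
Boundary values classify upward (a rate of exactly 0.05 is moderate),
matching the convention that 3 METs is moderate. Classes partition worn
minutes exactly; non-wear minutes belong to no class.

Moderate-equivalent PA is `MPA + 2 × VPA`. Its bouted variant credits only
minutes inside modified bouts: maximal windows ≥ 10 min, starting and
ending at-or-above moderate, with interruptions of ≤ 2 consecutive
below-moderate minutes. Interruption minutes contribute 0 and vigorous
minutes inside bouts count double; classes are exclusive, so vigorous
minutes are not additionally counted as moderate anywhere else. Aggregation
weights weekday and weekend means 5:2 (daily mean `(5·wd + 2·we)/7`, weekly
total `5·wd + 2·we`, identically 7× the daily mean).

## Baecke questionnaire scoring

Work, sport and leisure (non-sport) indices each range 1–5; the total index
is their sum (3–15). The scoring formulas follow the original protocol:
work = mean of the occupation activity score (low/middle/high → 1/3/5) and
seven 1–5 items with the sitting item reversed; sport = mean of the
sport-score ordinal and three items; leisure = mean of four items with the
television item reversed. The sport score sums intensity (0.76/1.26/1.76) ×
hours-per-week (0.5–4.5) × months-per-year (0.04–0.92) over up to two
sports and maps to ordinals at 0, 4, 8 and 12. Items are stored in the
questionnaire's raw orientation with per-item direction metadata. For
retired or unemployed respondents the work index, and hence the total
index, is missing.

## Feedback rules

Adequacy from objective PAL: adequate ≥ 1.8, low ≥ 1.5 and < 1.8, very low
< 1.5; from the Baecke total index (fallback when no sufficient
accelerometer window exists): 8.5 and 5.5. Adequacy maps onto the
green/amber/red report line. The advice category table — maintain when
adequate; increase when low; increase strongly when very low or when low
with BMI ≥ 30 — and the phenotype cut-offs (waist ≥ 102 cm men / 88 cm
women; total cholesterol ≥ 5.0 mmol/L; BMI component shown from 25) were
internal study algorithms never published; the defaults here are documented
surrogates chosen from standard clinical cut-offs, and all are
configurable. Message content is emitted as tagged components rather than
prose so tests are string-independent. Component sets grow monotonically
with level (L1 ⊆ L2 ⊆ L3); the FTO risk component appears only for L3
risk-allele carriers (AA/AT), and an L3 non-carrier receives the L2
decision. Controls (L0) receive only the generic 150-min/week guideline;
their advised-to-increase flag is the counterfactual level-1 decision,
which defines the matched-control subset of the targeted analysis.

## Trial analysis

Three orthogonal contrasts over arms L0–L3: C1 = L0 vs mean(L1–L3), C2 =
L1 vs mean(L2, L3), C3 = L2 vs L3, coded as Helmert-type columns scaled so
each coefficient estimates the corresponding difference of group means.
The model regresses the follow-up outcome on the contrasts plus baseline
outcome, sex, age, country, smoking, baseline BMI, baseline season (four
meteorological seasons) and change in body weight; accelerometer outcomes
additionally adjust for change in wear time. Analysis is complete-case per
outcome. The robust estimator is iteratively reweighted least squares with
the redescending Tukey biweight ψ and MAD scale; an OLS fallback is
provided and must agree with the robust fit within CI overlap on Gaussian
data (verified in tests, along with a 5%-contamination check that the
robust fit is less biased than OLS). CIs and p-values use the asymptotic
normal approximation at the 0.05 level. Rank-deficient designs raise an
error naming the aliased columns.

## Synthetic cohort

Profiles: block randomization in blocks of four over the arms; sex, age,
BMI, smoking, seven countries, and FTO genotypes under Hardy–Weinberg with
risk-allele frequency 0.446 (carrier fraction ≈ 0.693) echo the trial's
baseline table; all targets are configurable.

True PAL is shifted-lognormal, floored at the count-to-PAL intercept 1.354
and calibrated to mean 1.73 / SD 0.18. The shifted-lognormal family was
chosen because PAL has a hard floor at the device intercept and cohort PAL
distributions are right-skewed; it also reproduces the observed fraction of
participants below the adequacy cut-off (~72–73% of personalized
participants advised to increase) that a symmetric normal would
underestimate.

Minute counts follow a two-regime Markov process (background vs activity
bout; mean bout length 6 min) with lognormal counts in each regime
(background mean 900 counts/min, bouts 12 000). Each day's bout occupancy
is calibrated so the summed counts reproduce the day's target PAL through
the daily equation, with the background mean conditioned on the realized
bout minutes to keep the daily total unbiased; intervention effects
(default +0.02 PAL at month 3, +0.01 at month 6 in every arm, matching the
small observed cohort-wide drifts, with per-participant response SD 0.02)
therefore act through the bout rate. Weekday/weekend targets are tied by
the 5:2 weighting so the weighted weekly mean equals the participant's
true PAL (default weekend ratio 0.9). Day-to-day variation is lognormal
with σ = 0.08.

Non-wear gaps: per day a Poisson(1.4) number of gaps, the first anchored
at midnight with length ~ N(420, 84²) truncated to [90, 900] min
(overnight device-off), later gaps 90 + Exp(60) min; all zero-count. A
rate of 0 produces no gaps at all. Days without gaps carry 24 h of wear
and are invalid under the 10–18 h rule, which yields the realistic
pattern of imperfect compliance (~80% sufficient windows).

Baecke responses come from a piecewise-linear map from true PAL to a
latent 1–5 item level (knots (1.354, 1.0), (1.73, 2.6), (2.40, 5.0)),
with N(0, 0.7) item noise, occupation class and a sport-entry lookup
matched to the latent level. There is no published generative link between
PAL and Baecke items; the map is a test scaffold calibrated so a cohort at
PAL 1.73 lands near the observed mean total index of ~7.8. The
`reporting_bias` parameter shifts each latent item by bias/3, inflating
the expected total index by approximately the bias (models self-report
divergence from objective PA).

All random streams derive from (seed, participant index, stage), so
identical seed and configuration give identical output at every stage.

**What the generator does not emulate:** raw triaxial waveforms (counts
are the atomic unit), light-intensity activity volume (the two-regime
model concentrates activity in moderate-and-above bouts, so simulated LPA
minutes are well below free-living levels), seasonal and within-person
trends beyond the injected effects, informative missingness (gaps are
independent of activity level), and any dietary outcomes. Passing tests
therefore demonstrate correctness of the processing and inference chain
under a plausible data-generating process, not device-level realism.

## Problem sizes and numerical choices

Simulation-based tests use 200-participant cohorts for parameter-recovery
checks, 1480 participants for the advised-fraction calibration, 200
replicates for the type-I-error check of the contrast analysis (run at the
outcome level, where the property lives), and exhaustive enumeration for
the non-wear (run-length grammar, ≤ 300 min) and bout (all {LPA, MPA}
sequences of length ≤ 20) oracles — sizes chosen to give stable checks at
desk scale. Equality tolerances: exact worked examples assert to machine
precision or printed precision; stochastic checks use 2-SE bands or the
stated percentage-point bands. Degenerate inputs: empty class sequences
score 0 bouted minutes; empty targeted cohorts and rank-deficient designs
raise informative errors; boundary values at every published cut-off are
pinned by tests (1.80/1.79, 8.5/5.4, 600/1081 min, 90/89 min, 0.05
kcal/(kg·min)).

## Known limitations

* The per-minute PAL estimator and position-correction factors of the
  device vendor are unpublished; both surrogates are documented above and
  configurable, so absolute per-minute intensities (and hence simulated
  LPA/MPA splits) should not be read as device-faithful.
* The robust estimator is an M-estimator, not a high-breakdown S-start
  design-robust fit; with clean designs and ≤ 5–10% response outliers the
  two coincide in practice, and the OLS cross-check bounds the difference.
* The advice decision table and phenotype cut-offs are surrogates; swap in
  study-specific tables via configuration before using the engine outside
  simulation.
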