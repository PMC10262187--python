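# Methods

This note documents the statistical procedures implemented in
`chronopanel`, the assumptions behind them, the synthetic cohort the
package ships for validation, and the numerical choices made where the
design was genuinely open.

## Circadian variables from sleep-timing questionnaires

For each participant the package derives the standard MCTQ quantities from
reported bed and wake times on workdays and free days. With onset `o` and
offset `e` on the 24-hour circle, sleep duration is `SD = (e − o) mod 24`
and mid-sleep is `MS = (o + SD/2) mod 24`. Mid-sleep phases are mapped to
the canonical window (−6, 18] hours (values above 18 h have 24 subtracted)
so that typical population mid-sleeps around 2–6 AM form a continuous
scale for regression; without this, phases just before midnight would wrap
discontinuously.

Derived per person:

* `SD_w`, `SD_f` — workday / free-day sleep duration (h);
* `SD_week = (WD·SD_w + (7−WD)·SD_f)/7` with `WD` workdays per week;
* `MSW`, `MSF` — workday / free-day mid-sleep (h);
* chronotype `MSF_sc = MSF − (SD_f − SD_week)/2` when `SD_f > SD_w`
  (free-day oversleep is treated as recovery from workweek sleep debt),
  otherwise `MSF_sc = MSF`;
* social jetlag `SJL = |MSF − MSW|`, computed as the minimal circular
  difference mod 24 so that extreme phase pairs cannot produce artefactual
  23-hour jetlags;
* `Bamid` — the midpoint of the self-reported best-alertness interval, a
  subjective chronotype proxy.

Validity rules: a missing day-type pair marks the profile `missing`; a
zero-length interval marks it `irregular`; an alarm clock on free days
invalidates `MSF_sc` (the unconstrained phase is not observable) but not
`SJL`. The alarm rule's strictness is a flag (`strict_alarm`). A missing
`WD` defaults to 5 with a logged warning; `WD = 0` (non-workers) collapses
`SD_week` to `SD_f` while `SJL` is still computed from both reported
schedules, since non-workers do report distinct schedules and carry
non-zero social jetlag.

Outliers are removed by a single-pass filter: values farther than 5 sample
standard deviations from the sample mean (computed before any exclusion)
are dropped, independently for `MSF_sc`, `SJL` and `SD_week`, per wave. A
single pass was chosen over iteration because the filter is meant to catch
gross reporting errors, not to trim the tails of the distribution; with a
5-sigma cut the two differ only pathologically.

Sleep onset is taken directly as the reported fell-asleep time; no sleep
latency arithmetic is applied.

## Age/sex normalization and extreme chronotypes

Chronotype declines nonlinearly with age and differs by sex, so raw
`MSF_sc` values are not comparable across a household panel spanning ages
18–97. The package fits a cubic polynomial of `MSF_sc` on age separately
per sex (least squares, adults only, requiring ≥ 4 distinct ages and ≥ 10
records per sex) and shifts each person to a reference age of 30:

    MSF_sasc = MSF_sc − fit_sex(age) + anchor,

where `anchor` is by default the mean of the two sexes' predictions at age
30. Anchoring at the pooled prediction removes both the age and the sex
trend, which is what the name "age- and sex-corrected" promises; a config
switch (`anchor_mode="by_sex"`) preserves the sex difference instead, for
users who want an age-only correction. The extreme-chronotype score is the
per-person absolute deviation from the sample median,
`MAD_MSF_sasc = |MSF_sasc − median(MSF_sasc)|`, computed on the analysis
sample of the same wave (not a fixed external reference), so it is
invariant to constant shifts of the whole population. The lowest and
highest empirical deciles of `MSF_sasc` define "extreme early" / "extreme
late" categories; decile edges use linear-interpolation quantiles and ties
at an edge fall to the non-extreme side (a conservative extreme
definition).

## Biomarker preprocessing and categorizations

Biomarkers from multiple laboratories are median-centered: each value gets
`x − (median_lab − median_pooled)` subtracted, so every lab's median
equals the pooled pre-correction median while within-lab ranks are
untouched. Labs with fewer than 3 observations are left uncorrected with a
warning (their median is too unstable to estimate a batch offset).
The atherogenic index of plasma is `AIP = log10(TAG/HDL)`; base 10 is the
convention of the AIP literature, with natural log available by flag.
BMI is `weight/height²` with implausible inputs (height outside 1.0–2.5 m,
weight outside 25–300 kg) flagged rather than dropped. Composite indices
are a sum (time stress, five 1–5 items) or an affirmative count (diseases,
12 diagnosis items plus one general item, range 0–13); with at most one
missing item the index is completed by person-mean imputation, otherwise
it is missing. The shipped item lists are documented stand-ins with the
same shape as the survey's (the survey's exact wording and coding tables
are not public); every coding is overridable through `IndexSpec`.

Continuous variables are split into two equal bins at the empirical median
with ties going to the high bin, so a printed cutoff of the form
"< t / ≥ t" is matched exactly; the threshold is stored for reuse on other
waves. The age split is a fixed threshold at 50.5 years (younger ≤ 50,
older ≥ 51) rather than re-estimated per sample.

## Univariate and discriminant inference

Group comparisons use rank statistics throughout: Mann–Whitney U (exact
for small untied samples, tie-corrected normal approximation otherwise),
Kruskal–Wallis with Dunn's post-hoc pairwise z tests (rank-mean contrasts
with the pooled tie correction; Holm adjustment by default, Bonferroni or
none by flag). Partial Spearman correlation rank-transforms all variables,
residualizes the two of interest on the covariate ranks by least squares,
and reports the Pearson correlation of the residuals with a
t-approximation on `n − 2 − k` degrees of freedom; with no covariates this
is exactly Spearman's rho. The paired two-wave comparison is the Wilcoxon
signed-rank test with zero differences dropped; the mean and median paired
difference are always reported, even when every difference is zero and the
test itself is undefined.

The two-group discriminant is a Fisher linear discriminant: projection
`w = S⁻¹(μ₁ − μ₀)` with the pooled within-class covariance `S` plus a
ridge of `1e-6 ×` its mean diagonal for conditioning. Separation of the
full-data discriminant scores is tested by Mann–Whitney; allocation
accuracy is the mean ± SD over 10 repeats of seeded 5-fold stratified
cross-validation, with the held-out confusion matrix averaged over repeats
(so its entries sum to n). The ridge makes the projection not exactly
invariant to rescaling a single feature; the effect on accuracy is below
cross-validation noise.

## Household random-intercept models

Households share diet, schedules and socioeconomic environment, so
participants are not independent. Each biomarker outcome is modeled as

    y_ij = x_ij' β + u_j + ε_ij,   u_j ~ N(0, σ²_u),  ε_ij ~ N(0, σ²_ε)

with a random intercept `u_j` per household (no wave-level or random-slope
terms). Estimation is delegated to statsmodels' `MixedLM`. Coefficients
and Wald z tests are reported from REML fits; likelihood-ratio chi-square
tests of the main explanatory variable refit both nested models by ML on
the identical complete-case rows (the standard convention, since REML
likelihoods of models with different fixed effects are not comparable).
Regressors are mean-centered internally for optimizer conditioning, so the
reported intercept is the expected outcome at covariate means; slopes and
their standard errors are unaffected. Complete-case analysis is used
throughout — no imputation — so n varies slightly between models. P-values
carry no cross-outcome multiplicity adjustment, matching the one-model-
per-biomarker presentation.

The default model suite pairs each lipid outcome with its exposure of
interest: social jetlag (plus chronotype) for total and LDL cholesterol;
social jetlag plus the extreme-chronotype score `MAD_MSF_sasc` for HDL,
triglycerides and AIP. Adjustment covariates are sex, age, BMI and the
diseases index, plus cross-lipid covariates (TAG for total cholesterol;
TAG and HDL for LDL; LDL and TAG for HDL; LDL and HDL for TAG; LDL for
AIP). Total cholesterol is never a covariate for its own components, and
HDL/LDL are not covariates for total cholesterol, to avoid the structural
collinearity of a sum with its parts.

## The synthetic cohort

The generator emulates the features of a household biobank panel that the
analysis relies on, with every planted quantity recoverable by the
corresponding pipeline stage:

* **Households and demographics.** Household sizes 1–6; head age
  ~N(52, 16.5²) clipped to [18, 97]; partners close in age, additional
  members a generation younger. Employment probability declines
  logistically around age 62; workers get weekly work hours, commuting
  time and 4–6 workdays; five stress items and thirteen disease items are
  generated so the composite-index code paths are exercised end to end.
* **Chronotype.** `MSF_sc = cubic_sex(age) + N(0, 0.9²)`, with sex-specific
  cubics running from ≈ 4.9 h at 18 to ≈ 3.2 h at 90 and men ≈ 0.1–0.2 h
  later than women.
* **Social jetlag.** A zero-inflated gamma: exact zeros with probability
  0.08 (workers) / 0.30 (non-workers), otherwise a gamma draw (shape 2.05)
  whose log-mean is linear in centered chronotype, age, work hours,
  commuting, time stress and sex. The gamma component is strictly positive,
  so no truncation or resampling is ever needed, and its right skew is what
  lets the distribution have sex means near 0.95/0.83 h while the median
  sits near 0.65 h. Coefficients were calibrated once by forward
  simulation to those reported marginals and frozen in the defaults.
* **Raw clock times.** Onset/offset emitted as `mid ∓ SD/2` (mod 24), so
  scoring inverts generation exactly (the round-trip is < 1e-9 h); a
  "realistic" mode rounds to whole minutes instead. 10% of participants
  use a free-day alarm and are excluded from chronotype-based analyses by
  the standard validity rule.
* **Biomarkers.** Each marker is linear in its planted effects (social
  jetlag +0.13 on total and +0.109 on LDL cholesterol; extreme-chronotype
  deviation −0.032 on HDL, +0.085 on TAG, +0.078 on AIP; mmol/L per hour)
  plus demographic covariate effects, a household intercept, a per-lab
  batch offset (8 labs), and residual noise scaled so that fitted standard
  errors match the observed-cohort scale at n ≈ 1600. Sampling time is
  8.32 h on average (SD 1.13 h) with a slope on chronotype targeting
  r ≈ 0.17; morning cortisol declines with sampling time (−28 nmol/L per
  hour) and rises with chronotype so that the marginal cortisol–chronotype
  correlation is ≈ 0.14. Markers are conditionally independent given the
  exposures and demographics: there are no cross-lipid causal terms, so
  including the cross-lipid covariates in the fitted models cannot bias
  the exposure coefficients (their fitted values are ≈ 0 in synthetic
  data, unlike in real serum panels — a deliberate simplification).
  AIP is generated "direct" (its own linear model) by default because
  planting the TAG and HDL effects does not algebraically imply any
  particular AIP coefficient; a "derived" mode computes log10(TAG/HDL)
  instead.
* **Follow-up wave.** A home-office subgroup (default 400) is drawn from
  commuting workers with baseline SJL ≥ 0.5 h and receives planted
  within-person shifts (+11 min chronotype, −18.6 min social jetlag,
  +12.6 min weekly sleep) plus N(0, 10 min) paired noise; the SJL shift is
  applied as a reflected subtraction `|SJL − D|` so the SJL ≥ 0 floor
  cannot distort the planted mean. Controls keep chronotype and SJL and
  lose 6 min of sleep. The 10-minute paired noise is deliberately small —
  it makes the planted group means recoverable from a single cohort to
  within ≈ ±1 min — and is therefore much tighter than real year-to-year
  within-person variability; detecting shifts of this size against
  realistic (≈ 1 h) paired noise is a power question the generator does
  not model. A side effect of the reflection is a ≈ +1–2 min drift in the
  control group's SJL (noise reflecting off zero), visible in the control
  row of the longitudinal table.

What passing tests show — and do not. The synthetic cohort demonstrates
that every formula, filter and model in the pipeline recovers what was
planted under the stated noise model: Gaussian residuals, linear effects,
conditionally independent markers, no attrition, no reporting error beyond
the optional minute rounding. It does not demonstrate robustness to the
things real survey data add: non-Gaussian biomarker tails, correlated
measurement error in self-reported times, informative missingness, or
joint socioeconomic structure beyond the simple work → commute → stress
chain the generator uses.

## Problem sizes used in the shipped checks

The recovery checks average the five exposure coefficients over 50
simulated cohorts of 1600 participants (~1000 households) each; the
longitudinal check uses one cohort with 400 home-office pairs; marginal
calibration uses one cohort of 10 000 and the cortisol correlation one of
5 000. At these sizes the Monte-Carlo standard error of each averaged
coefficient is 13–15% of its single-cohort standard error, a few percent
of the planted values.

## Known limitations

* The cubic age trend extrapolates poorly outside 18–97 and is fitted only
  on adults; no spline/LOESS alternative is provided.
* `MAD_MSF_sasc` inherits estimation error from the fitted cubic and the
  sample median, attenuating its fitted coefficients by ~1–3% at n ≈ 1600.
* The mixed models assume homoscedastic Gaussian residuals; heavy-tailed
  markers such as CRP are generated near-Gaussian here and would need
  transformation on real data.
* Survey weights, attrition, and causal identification are out of scope.
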