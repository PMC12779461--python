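# Methods

`nvhap` implements two surveillance definitions for non-ventilator
hospital-acquired pneumonia (NV-HAP) and the statistical machinery to
evaluate a staggered, multi-site prevention initiative with them: temporal
trend models, a clustered comparison of the two definitions, and a
counterfactual (g-computation) pre/post effect estimator with delta-method
uncertainty and correlated fixed-effect pooling. Because the motivating
data (multi-hospital electronic health records) cannot be distributed, a
first-class synthetic-data generator reproduces the statistical structure
the analysis assumes, with known ground truth for every estimand.

## Surveillance definitions

**Electronic clinical definition.** A deterministic rule set over
patient-day data. An event is called at onset day *d* ≥ 3 when all of the
following hold, with windows clipped to the stay:

1. worsening oxygenation on days *d* and *d*+1 — supplemental-oxygen
   device escalation on the 6-level ladder (room air, low-flow cannula,
   face mask, high-flow cannula, non-invasive ventilation, invasive
   ventilation), or a daily-minimum SpO2 drop of ≥ 3 points at unchanged
   device — after ≥ 2 days of stable or improving oxygenation;
2. fever (≥ 38.0 °C) or leukocytosis (≥ 12.0 × 10³/µL) in [*d*−1, *d*+1];
3. chest imaging in [*d*−1, *d*+2];
4. a *new* antibiotic class — absent on days [*d*−2, *d*−1] — started in
   [*d*−1, *d*+1] and given on 3 consecutive in-stay days (discharge
   before the third day disqualifies; the 2-day washout means a start at
   *d*−1 can never qualify, so effective starts are *d* or *d*+1);
5. no invasive ventilation on days [*d*−2, *d*].

Missing values never create evidence: a missing SpO2 at unchanged device
rank counts as stable, and missing temperature/WBC cannot satisfy
criterion 2. Only the first adjudicated event per hospitalization is
kept. Every threshold and window is a knob on `DetectorRules`; the
defaults above are one defensible operationalization of the published
clinical wording, not a certified port of any reference implementation.

**Diagnosis-coding definition.** A hospitalization is coded NV-HAP when a
primary or secondary discharge diagnosis carries a qualifying pneumonia
ICD-10 code (exact codes B95.3, B96.0, J13, J84.111, J84.116, J84.117,
J84.2, J85.1, J85.2, plus the whole J15–J18 families including bare
roots) flagged *not present on admission* (POA = N). POA values U, W and
missing do not qualify: hospital-onset surveillance requires an
affirmative N. Dotted and undotted code dialects are normalized first.

## Trend models

Each outcome (NV-HAP by either definition, 30-day death) is modeled by
logistic regression with a linear term in days since the study start;
slopes are reported per year (×365.25). Endpoint risks and their
difference carry delta-method 95% CIs. Length of stay (LOS) uses a hurdle
model — logistic hurdle at LOS = 1 day, zero-truncated negative binomial
(NB2: variance µ + αµ², θ = 1/α) for LOS − 1 — with the same time term in
both components; the mean trajectory and its CI come from the joint
block-diagonal parameter covariance (the two component likelihoods are
orthogonal).

The two definitions are compared on a long table with two rows per
hospitalization and a definition-by-time interaction, estimated by GEE
with an independence working correlation and hospitalization-level
clusters. With independence working correlation this estimator is
*numerically identical* to a logistic GLM with cluster-robust (sandwich)
standard errors, which is how it is computed; the interaction is the
electronic-minus-coding difference in log-odds slope per year.

## Counterfactual pre/post estimator

For each site, pre = [start − 365 d, start) and post = [start, start +
365 d), half-open, with optional date shifts (e.g. −3 months for
anticipatory effects) and a non-ICU subgroup restriction. On pooled
pre-period data two models share one design — site indicators, calendar
year as a continuous term, an annual sine/cosine pair for week-of-year
seasonality, and the binary patient flags:

1. a hurdle model for LOS given the design;
2. a logistic model for the event given LOS (linear) and the design.

The counterfactual probability for a post-period patient is the
law-of-total-probability sum Σ_l P̂(LOS = l | x) · P̂(event | l, x) over
l = 1..L_max, with the LOS mass renormalized over that support
(L_max = 99.9th percentile of pre-period LOS, capped at 120 days). Site
counterfactual risk is the average over the site's post patients; the
site effect is rd = actual − counterfactual, so protection is negative.
The continuous year term extrapolates linearly into the post year —
categorical year levels unseen in the pre period could not be predicted
at all. Identification of that term rests on the staggered rollout: sites
enter pre/post windows at different calendar times.

**Rare-event fitting.** The outcome model uses Firth's bias-reduced
logistic regression (Jeffreys-prior penalty) with a subsequent intercept
recalibration that pins the in-sample mean prediction to the observed
event rate (FLIC). With ~0.6% events, site cells with zero events are
common at moderate n; plain maximum likelihood then separates, sending a
site's counterfactual risk to 0 with a spuriously tiny variance and
letting that site dominate the pooled weight. Firth keeps every
coefficient finite; the recalibration removes the toward-1/2 prediction
bias Firth otherwise introduces at rare event rates.

**Delta-method covariance.** The K×K covariance of the site effects is
Σ = G V Gᵀ plus a binomial diagonal, where V is block-diagonal over the
fitted components (hurdle logistic, truncated-NB, outcome logistic — the
pre-period LOS and outcome likelihoods are treated as independent) and G
holds each site's gradient of the standardized risk with respect to the
stacked parameters. Gradients are exact (analytic) for both logistic
blocks and for the NB mean coefficients, and forward finite differences
(relative step 1e−5) for the single dispersion parameter; an internal
`values(theta)` path recomputes everything from any parameter vector so
the analytic pieces are verified against pure finite differences in the
test suite. Two stabilizations, both validated by the calibration study
below:

* gradient rows are rescaled to a common level (the pooled counterfactual
  level, inflated by (observed/fitted)^0.3 when the fitted level falls
  below the observed post rate). The raw gradient of the exp-like
  standardization map scales with the site's own estimate, so a site
  whose standardized risk comes out randomly low would get a randomly
  small variance and an inflated inverse-variance weight — a positive
  bias of the pooled estimate; and in replicates where the shared
  calendar terms draw low, the local gradient understates the error of
  every site at once;
* the binomial variance of the actual risk uses the pooled post-period
  rate rather than each site's own rate, again so that weights cannot
  track site-level noise.

**Pooling.** Fixed-effect inverse-variance weights w_i ∝ 1/Σ_ii, pooled
rd = Σ w_i rd_i, and — because the shared pre-period fits correlate the
site estimates — pooled variance wᵀ Σ w with the full covariance;
95% CI = rd ± 1.96·SE. Secondary outcomes reuse the machinery: 30-day
death standardizes a covariates-only logistic model (no LOS mediation);
the LOS outcome contrasts the actual post mean LOS with the
counterfactual mean from the pre-fitted hurdle model, in days. Crude
(unadjusted) differences with two-sample SEs and diagonal pooling are
also provided.

## Synthetic-data generator

Admissions arrive as weekly Poisson streams per site (default 17 sites,
88/site/week ⇒ ~333k hospitalizations over 10/2015–12/2019, matching the
scale of a large hospital-system study); implementation dates are
staggered evenly across the window with one year of data on each side.
Binary patient flags are independent Bernoulli draws (defaults: age ≥ 75
(35%), male (95%), heart failure (20%), COPD (25%), dysphagia (5%),
immunocompromise (10%), abnormal admission WBC (20%) and temperature
(10%), low admission SpO2 (15%), ICU ward (16%)). LOS follows the same
hurdle family the analysis fits, with site offsets (±0.15 on the log
mean), seasonality, an optional secular trend, and a post-implementation
multiplier on the NB mean — the indirect intervention channel (defaults:
P(LOS = 1) ≈ 0.19, NB mean 4.4, θ = 1.3 ⇒ mean LOS ≈ 5.9 days). The true
event is Bernoulli with logit linear in the flags, in realized LOS
(+0.05/day), in a post indicator (the direct channel), and in an annual
sinusoid (amplitude 0.1); the baseline (−6.21) is tuned so the marginal
risk is ≈ 0.6%. 30-day death is Bernoulli (≈ 5%) from flags and LOS.

Events in stays of ≥ 5 days receive an onset day uniform on
{3, …, LOS−2} and a full clinical signature planted into otherwise quiet
daily records (stable baseline, two worsening days, fever, imaging, a new
3-day antibiotic course from an 8-class vocabulary, no ventilation);
shorter stays keep truth = event with no detectable signature — the
electronic definition structurally needs two baseline days, two worsening
days and a completed course. Background noise (±1-point SpO2 jitter, 2%
daily imaging, 15% background antibiotic courses) cannot create
candidates, so on default cohorts detection equals planting exactly; this
round-trip is the core fixture contract. A discharge pneumonia code with
POA = N is emitted with sensitivity 0.5 given a true event and
1 − specificity = 0.004 otherwise, each shifted on the log-odds scale by
an optional secular coding drift; with drift −0.22/yr the *marginal*
coded trend is −0.18 log-odds/yr (the sensitivity channel, sitting near
probability 0.5, attenuates the raw knob) while the true-event trend
stays flat — diverging surveillance trends with no change in true risk.

The truth table carries each hospitalization's realized event, onset day,
event probability, and a closed-form counterfactual probability (post
indicators switched off, LOS integrated out); `ground_truth_effects`
integrates the generative logits exactly (covariate-pattern enumeration ×
site × season grid × LOS summation with tail mass < 1e−12) to give the
true marginal pre/post risks and risk difference — the oracle for effect
recovery. All randomness flows from one seed through named per-table
substreams, so identical (config, seed) is byte-identical and new tables
cannot perturb existing ones.

What the generator does *not* emulate: correlated comorbidity profiles,
ward transfers (ward type is a static flag), free-text or microbiology,
time-varying within-stay acuity beyond the planted signature, readmission
linkage (every hospitalization is independent), and coding practice
heterogeneity across sites. Passing tests therefore demonstrate that the
estimators are correct and calibrated *under the assumed structure*, not
that the definitions are clinically valid on real records.

## Numerical choices

* Zero-truncated NB fits by L-BFGS with analytic score; dispersion
  optimized as log α within [−8, 4]; covariance from a finite-difference
  Hessian of the analytic gradient; gamma/digamma terms evaluated once
  per distinct count. The statsmodels left-truncated NB is the
  independent cross-check in the tests (same estimates to ~1e−3).
* Logistic fits: statsmodels GLM for trend models; damped Newton for the
  hurdle component; Firth+FLIC for the rare-event outcome model; a small
  ridge fallback exists for separated designs outside the Firth path.
* Sigma is symmetrized; eigenvalue deficits below 1e−10 of the largest
  eigenvalue are projected to PSD with a warning, larger ones raise.
* Ties/degenerate inputs: duplicate patient-days, gapped day indices,
  single-level outcomes, all-equal LOS, empty windows and missing
  implementation dates all raise explicit errors.

## Scaled-down study conditions in the test suite

Replicate-based checks run at reduced size, chosen once as conditions a
simulation study of this design would use: 17 sites with staggered
rollout, three patient flags, event risk 0.6%, ~1,150 admissions per site
and window for null calibration (500 replicates; pooled 95% CI covers
zero in ~95.6% of replicates) and ~2,300 for effect recovery (200
replicates; induced true rd = −0.15 pp recovered within 0.03 pp). The
delta-vs-bootstrap oracle uses 4 sites × ~2,000 admissions at a ~5% event
rate, where Wald asymptotics are in regime. Staggering is load-bearing at
these sizes: with a common implementation date the calendar-year term is
identified only within a single year and its extrapolation into the post
window is unstable.

## Known limitations

* Site-level effect heterogeneity is not modeled (fixed-effect pooling
  only; no random-effects variant).
* The delta method is first-order; at very small per-site event counts
  the year-coefficient likelihood is skewed and rare large errors exceed
  the nominal tails (visible as occasional |z| > 3 replicates at the
  smallest scales; the stabilized variance keeps overall coverage
  nominal).
* The detector evaluates calendar-day granularity only; within-day
  ordering (e.g. ventilation started after the morning SpO2 minimum) is
  not represented.
* The L_max truncation reassigns 0.1% of LOS mass; with event risk
  increasing in LOS this understates the counterfactual risk by ~1e−5
  absolute — negligible at the scales studied.
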