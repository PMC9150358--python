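# Methods

## The estimation protocol

The package emulates a two-arm target trial from four relational registry
tables. Baseline is the start of the index therapy: the earliest episode of
either study drug beginning on or after the control drug's availability
date (internal day 0) and persisting at least 90 days; prior exposure to
therapies with an extended duration of effect (mitoxantrone, alemtuzumab,
cladribine, daclizumab, rituximab, ocrelizumab, cyclophosphamide)
disqualifies the patient. Month-denominated rules are fixed at day
resolution — 3 months = 90 days, 6 months = 183 days (except the
*confirmation* interval of the EDSS detector, ≥ 180 days), 12 months = 365
days — so every decision is deterministic. Eligibility requires an EDSS
visit in the closed window [index − 183 d, index] (the most recent is the
baseline score; a day-0 visit counts as pre-treatment), two post-index EDSS
visits spanning ≥ 183 days, and an EDSS visit during the index episode
(day 0 counts).

The propensity score is a logistic model for the probability of the
treated drug given sex, age (linear, years), MS duration (linear, years),
EDSS band (<2, 2–3.5, ≥4), prior-relapse band (0/1/2/3+), prior-treatment
band (0/1/2/3+) and prior 12-month clinical activity, with country as
either a variational-Bayes random intercept or fixed indicators. Two
coding facts matter:

- The banded coding is a modelling inference from how balance tables report
  these covariates, not an externally fixed fact; continuous alternatives
  would be defensible.
- The 4-level activity factor (none / worsening / relapse / both) is
  *exactly* collinear with the relapse bands, because activity is
  relapse-classified iff the count is ≥ 1. The design therefore codes
  activity by its worsening component only (two indicators); this spans the
  identical model space and is the unique identifiable parametrization.
  Consequently the "relapse only" activity effect is absorbed into the
  relapse-band coefficients.

Scores are clipped to [1e−6, 1 − 1e−6] before weighting: clipping prevents
numeric underflow from manufacturing infinite weights while leaving true
positivity violations visible in the overlap report (common-support
interval, per-arm densities, two-sample KS). A mixed-model fit that fails
falls back to fixed country indicators and records the fall-back — the
scientific target is the score, not the variance component.

Designs: greedy 1:1 nearest-neighbour matching on the probability scale
(caliper = multiplier × SD of the pooled PS, sample SD with ddof = 1;
seeded random processing order; ties broken uniformly at random, seeded; no
replacement), or weights (IPTW, sIPTW, odds). No weight trimming anywhere:
stabilization is the chosen guard against extreme weights. Matching and
odds weighting estimate the ATT; IPTW/sIPTW the ATE.

Windows: ITT runs from index to the last data entry (maximum over all four
tables); per-protocol ends at episode end or last entry, whichever is
earlier. Pairwise censoring truncates both members of a matched pair to the
pair's shorter window; it is applied after the contrast windows are formed,
and events landing exactly on a window end are inside (closed right
endpoint; relapse onsets on day 0 belong to baseline history — half-open on
the left).

Confirmed EDSS change scans post-baseline visits against the *fixed*
baseline score. Thresholds: worsening +1.5 from EDSS 0, +1.0 from 1.0–5.5,
+0.5 above 5.5 (baseline 0.5, which the published bands skip, uses +1.0 as
the nearest band); improvement −1.5 from 1.5, −1.0 from 2.0–6.0, −0.5 above
6.0, undefined (structurally censored) below 1.5. A candidate onset is
confirmed iff some visit ≥ 180 days later exists with every intervening
visit (inclusive) meeting the threshold; for worsening the confirming visit
must not fall within (0, 30] days after any relapse onset — the exclusion
applies to the confirming visit only and only for worsening. A broken
candidate is discarded and scanning resumes after the breaking visit, so
later genuine events are still found. Events are timed at the onset visit
(registry convention; the confirmation visit would be the other defensible
choice). Whether an EDSS measured during a relapse may serve as the onset
is unrestricted — only confirmation is relapse-restricted.

Estimation follows the design: relapse counts by negative-binomial
regression on the arm indicator with a log-exposure offset, fitted as
independence estimating equations — design weights with robust sandwich
variance for weighted designs, pair-clustered GEE for matched designs. The
NB dispersion is a moment estimator from weighted Pearson residuals of a
Poisson fit; a vanishing estimate reduces the model to Poisson with robust
variance (recorded in the diagnostics). Time-to-event outcomes use Cox
partial likelihood (Efron ties, lifelines) with robust variance; matched
designs use pair-clustered robust (sandwich) variance as the paired
variance method — a shared-frailty term would be the main alternative, but
cluster-robust variance targets the same marginal estimand, is stable at
small pair counts, and avoids a distributional assumption on the pair
effect. Disability models always adjust for annualized visit density
(linear on the log hazard), since event detection depends on how often
EDSS is measured. Confidence intervals are Wald on the log scale. Median
follow-up is summarized by the reverse Kaplan–Meier (censoring as the
event), with log-log intervals.

The default grid is the full crossing — 4 outcomes × (3 calipers × 2
contrasts × 2 pairwise + 2 weighting schemes × 2 contrasts) = 64 cells —
with the two weighting schemes being sIPTW (ATE) and odds (ATT). Cell
failures are isolated and recorded. One master seed is expanded
deterministically into per-stage seeds, so identical seeds reproduce the
grid byte for byte.

## The synthetic registry

The generator's defaults encode the emulated study conditions: 72% female;
age ≈ N(37.5, 9.5²) years; MS duration log-normal with median ≈ 6.9 y;
EDSS bands 30/46/24%; prior-relapse bands 36/39/19/6%; prior-treatment
bands 16/50/23/11%; data sources 64/28/8% with small assignment
intercepts; assignment log-odds favouring the treated drug in active and
disabled patients (positive EDSS- and relapse-band coefficients, negative
prior-treatment coefficients), the intercept calibrated so the marginal
treated fraction is ≈ 39%. Follow-up is administrative, uniform 1.5–5 y;
visits every ~90 days with per-patient density multipliers in [0.7, 1.4]
and jitter; discontinuation is exponential (0.22/y per arm by default,
zero hazard before day 90, since sub-3-month starts are not index cases)
with an optional log-hazard increase per on-treatment relapse (informative
censoring) and an optional rule that the treated effect ends at
discontinuation — both off by default, since the emulated comparison
reports no discontinuation asymmetry.

Relapses are a gamma-frailty Poisson process (frailty variance 0.2, giving
mildly negative-binomial counts) whose rate carries the confounding path:
log-rate increments of 0.2/0.4/0.6 by prior-relapse band and 0.05/0.10 by
EDSS band over a base 0.35/y. These magnitudes are deliberately moderate so
that the marginal first-relapse hazard ratio essentially coincides with
the conditional rate ratio (non-collapsibility under heavier frailty would
detach the observable marginal estimand from the declared truth). Because
relapse counts and first-relapse times come from one point process, the
declared IRR and relapse HR are a single parameter and the configuration
rejects unequal values.

Disability is driven by latent proportional-hazards event times (worsening
base 0.08/y scaled by EDSS band, improvement 0.12/y, each multiplied by its
hazard ratio while treated). A trajectory realizes whichever latent
transition comes first and masks the later one; the realized step equals
the detector's threshold for the baseline score. Visits within 30 days
after a relapse get a transient +1.0 bump (exercising the exclusion rule)
and post-index scores flip by ±0.5 with probability 0.05. Two consequences
are documented rather than hidden: (i) patients whose improvement fired
remain in the worsening risk set with zero hazard, so with non-null
improvement effects the observable worsening HR sits a few percent below
the declared latent one; (ii) detection is interval-censored at visits, so
event times are late by about half a visit gap in both arms.

Pre-index histories are constructed so the cohort stage *re-derives the
generating covariates exactly*: noise-free pre-index visits, drawn prior
relapses placed inside [−360, −55] days, prior DMT episodes stacked before
the index, and a drawn prior-worsening manifested as a sustained EDSS step
(onset ≈ day −210, reference visits ≈ −350/−300 at the pre-step score) that
the confirmed-change detector recovers through the 12-month-lookback
anchoring used by the baseline stage. Drawn EDSS values with no valid
pre-step score (below 2.0 other than 1.5) cannot display prior worsening
and have the flag cleared. This makes the "correctly specified PS model"
regime literally true, which is what parameter-recovery and balance checks
require.

The era switch models the positivity violation at patient level: a
configurable fraction of patients is indexed uniformly in [−1460, −90]
days, assigned the treated drug with probability one (true PS recorded as
1), and given a 1.5× relapse-rate multiplier — a calendar-time effect
invisible to the propensity covariates, which is what makes the
unrestricted analysis genuinely biased rather than merely noisier.

What the generator does **not** emulate: MRI activity, real EDSS
measurement error structure (ours is symmetric and transient), secondary
progression, treatment-effect heterogeneity, registry-specific schema
quirks, attrition differing by arm, or more than two study drugs. Passing
tests therefore certify the pipeline's logic and its statistical behaviour
under the stated generating laws — not robustness to real-data pathologies
outside them.

## Numerical and testing choices

Dates are integer day offsets from the availability date; ISO-8601 only at
I/O. Half-point EDSS grids are validated everywhere; off-grid scores are
rejected, generated scores are snapped after noise. Mahalanobis balance
uses the K−1 proportion vector with the averaged multinomial covariance and
a 1e−10 ridge; zero pooled variance with unequal means reports an infinite,
flagged distance. Matching is unstratified (country enters the PS model
only).

Verification sizes were chosen to give the stochastic checks clear
resolution while keeping the whole suite on one CPU: parameter recovery
uses 50 replicates of n = 4000 (median of each estimator in [0.6, 0.8] and
≥ 90% CI coverage of the true 0.7); the type-I-error check uses 200 null
replicates of n = 2000 (rejection between 2% and 9%); ITT-attenuation and
positivity-bias checks use 50 replicates of n = 1500; balance attainment
uses a single n = 5000 cohort; matcher-oracle equivalence uses 100 random
instances of ≤ 50 per arm. The acceptance script runs the full 64-cell
grid at n = 3000.

## Known limitations

- Matched Cox variance is pair-cluster-robust, not shared-frailty; matched
  interval widths can differ slightly from a frailty formulation.
- The sandwich variance treats estimated propensity scores and the NB
  dispersion as fixed; for sIPTW this is mildly conservative.
- The observable worsening HR under non-null improvement effects is
  attenuated relative to the declared latent HR (risk-set contamination,
  see above).
- Weighted and matched designs cannot be combined (rejected with a
  message); the protocol never crosses them.
- The generator's assignment and outcome models share the pipeline's
  covariate coding; the package does not probe misspecification of the PS
  functional form.
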