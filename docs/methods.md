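# Methods

This note documents the model implemented in `ahusce`, the defaults it
ships with, the design choices that were genuinely open, and what the test
suite does and does not establish. It states no empirical result that the
tests or `scripts/acceptance.py` do not themselves compute.

## Cohort model

Nine states (`CKD02_OFF, CKD02_TX, CKD3_OFF, CKD3_TX, CKD4_TX, ESRD,
TRANSPLANT, POST_TX, DEAD`) in discrete 2-week cycles (365.25/14 ≈ 26.09
cycles/year) from a starting age of 20 to 100. `TRANSPLANT` is a strict
one-cycle tunnel for the procedure; `DEAD` is absorbing. The trace row at
cycle *i+1* is row *i* times the cycle's transition matrix.

**Death first, competitively.** The per-cycle death probability (background
plus any state excess) is applied first; all clinical transition
probabilities are scaled by one minus it. This keeps every row exactly
stochastic without post-hoc renormalisation and is standard cohort-model
practice.

**Background mortality** is a life-table lookup by integer age attained
(age advances continuously, `age(t) = 20 + t`), sex-mixed as
`q = 0.51·q_male + 0.49·q_female`, converted per cycle by
`1 − (1−q)^{1/26.09}`. The bundled table is synthetic (below); any CSV with
columns `age, q_male, q_female` can be substituted.

**Relapse and restart.** Off-treatment states relapse with the
time-dependent probability from the fitted survival curve (below). A
relapse restarts treatment immediately and permanently; with probability
0.25 it presents one CKD stage further on (CKD 0–2 → CKD 3; CKD 3 → CKD 4).
On-treatment patients at CKD 0–2/3 never progress.

**Advanced disease.** CKD 4 → ESRD (2.55%) and ESRD → transplant (3.25%)
are interpreted as **annual** probabilities and converted per cycle by the
complement-power rule. The source figures come from annual-scale
literature, and reading them per 2-week cycle (≈49%/year CKD 4 → ESRD)
is clinically untenable for treated patients and incompatible with the
published survival totals this model re-implements. A config switch
(`advanced_progression_annual=False`) restores the verbatim per-cycle
reading. Excess mortality in ESRD/transplant/post-transplant is genuinely
per-cycle (0.41%, derived from a 5% six-month excess) and is added to the
background probability. Graft failure (11.64%) applies once, in the tunnel
cycle, returning the patient to ESRD; `transplant_failure_mode="per_cycle"`
preserves the literal every-cycle reading, under which grafts would be
eliminated within months.

## Time-to-relapse extrapolation

Five families are fitted to right-censored relapse times (months since
withdrawal) by maximum likelihood via lifelines: exponential, Weibull,
Gompertz, log-logistic, lognormal. The Gompertz fitter is a two-parameter
`ParametricUnivariateFitter` with an *unconstrained* shape: a negative
shape yields a plateauing (improper) survival curve, which is exactly the
favourable-scenario behaviour. BIC is `k·ln n − 2·ℓ` with `n` the number of
records; ties break to fewer parameters, then a fixed family order. The
base case overrides the BIC winner with the lognormal (decreasing long-term
hazard); both choices are reported by `fit-survival`.

Per-cycle relapse probabilities are `p_i = 1 − S(t_{i+1})/S(t_i)` at cycle
boundaries (months = days/30.4375), with `p_i = 1` once `S` underflows to
zero; the product `∏(1−p_i)` telescopes back to `S(T)` to machine
precision (tested).

Fit uncertainty propagates by a multivariate normal on the estimation
scale: positive parameters are perturbed on the log scale with a
delta-method covariance, so every draw is a valid survival function.
Optimiser starts come from the exponential closed form (`rate = events /
total time`) with family-specific transforms; non-convergence triggers up
to four seeded jittered restarts.

**The bundled relapse fixture** (`data/relapse_times_synthetic.csv`) stands
in for unavailable patient-level data: 28 records, 4 events by 24 months,
24 censored at 24 months. The four event times (3, 7, 12, 19 months,
clustered early) were chosen so the fitted family ensemble reproduces the
published qualitative structure: the exponential attains the best BIC with
small differences across families, the Gompertz fit plateaus (negative
shape), and the lognormal's long-term prediction lies between the Gompertz
plateau and the steeply falling families. Every downstream "reference"
number inherits this fixture and is therefore synthetic-calibrated, not a
re-derivation.

## Utilities

CKD 0–3 states carry the trial baseline utility 0.86; off-treatment states
add the withdrawal increment +0.01; CKD 4, ESRD and post-transplant apply
additive decrements (−0.15, −0.21, −0.21); the transplant tunnel uses the
absolute procedure utility 0.66; death is 0.

**Relapse decrement (−0.02): transient by default.** It is charged for the
relapse cycle only (attached to the incident relapse flow). Applying it to
*all* post-relapse cycles — the alternative `relapse_disutility_mode=
"persistent"` — multiplies a −0.02 ± 0.04 quantity by roughly a decade of
discounted post-relapse time, which flips the sign of the deterministic
QALY gain and triples the width of its uncertainty band; neither is
compatible with the published incremental QALYs, their credible interval,
or the dominant-quadrant share, all of which this package reproduces under
the transient default. The relapse *management cost* offset (−£150/cycle)
remains persistent for post-relapse states, which matches its framing as an
ongoing care-cost difference.

**Age decline.** All state utilities are multiplied by
`g(age)/g(20)` where `g` is the general-population quadratic
`0.9508566 + 0.0212126·male − 0.0002587·age − 0.0000332·age²`
evaluated at the cohort's male fraction. The published lifetime QALY/LY
ratio (≈0.83 against a 0.86 baseline) implies some age adjustment was
applied; the method was unstated, so this package uses the standard
UK population-norm curve, normalised to 1 at the starting age
(`utility_age_adjustment=False` disables it).

## Costs (2022 GBP)

On-treatment states accrue per cycle: drug acquisition, delivery,
antibiotic prophylaxis (£7) and maintenance monitoring (£102). Dosing is
not printed in the source tables, so the licensed schedules are costed:

- **eculizumab**: maintenance 1200 mg / 2 weeks = 4 × 300 mg vials × £3150
  = £12 600/cycle; re-initiation after relapse (900 mg weekly × 4 before
  maintenance) adds a one-off 4 extra vials (£12 600) at the relapse.
- **ravulizumab**: £16 621 per 1100 mg vial, maintenance 3300 mg / 8 weeks
  = 0.75 vials per 2-week cycle (£12 466); deliveries every 4th cycle;
  loading 2400 mg billed pro rata as the one-off re-initiation extra. This
  reading makes the ravulizumab scenario land a few percent below the
  eculizumab maintenance bill, as published.

Delivery: 29% of administrations are in hospital at £1429; homecare is
free to the NHS (manufacturer-funded). Off-treatment states accrue the
phased monitoring schedule — £424/cycle while the cycle ends within month
1 (cycles 1–2), £215 through month 8 (cycles 3–17), £111 thereafter
(month = 365.25/12 days) — plus the withdrawal-management offset
−£32/cycle. CKD 4, ESRD and post-transplant add £18, £24, £306 per cycle;
transplant surgery is a one-off £16 037 on entry into the tunnel. A guard
rejects any assembled state cost below the management offsets alone.

Discounting is 3.5%/year. With the half-cycle correction (default on),
per-cycle payoffs apply to the trapezoid of adjacent boundary occupancies
and discount at the cycle midpoint; one-off costs attach to the incident
flow within the cycle. The cycle sum reproduces the continuous annuity
`(1−(1+r)^{−T})/ln(1+r)` within 0.1% (tested).

## Probabilistic sensitivity analysis

Each iteration independently redraws every uncertain parameter from its
moment-matched family — Beta for probabilities/proportions (shape pair
from `ν = m(1−m)/s² − 1`), Gamma for costs (negated for negative-mean
offsets, keeping the printed family and sign), Normal for utility deltas
and excess mortality, lognormal (natural-scale moment match) for
transplant failure — plus one draw of the survival-fit parameters. SEs
missing from the input table default to 10% of the mean, including the
drug vial prices (which the one-way analysis must be able to vary). The
baseline CKD split is a single Beta draw on the CKD 0–2 share with CKD 3
as the complement; the progression splits likewise. Joint draws violating
payoff domains (e.g. a utility above 1) are redrawn and counted, never
silently dropped. Default 5000 iterations; summaries are means,
equal-tailed 2.5/97.5 percentile credible intervals, quadrant shares and
the CEAC (`fraction of iterations with λ·ΔQ − ΔC > 0`).

The tornado sets each parameter to mean ∓/± 1.96 SE (clipped to its
domain) one at a time, plus a pseudo-entry perturbing the survival curve's
location parameter by ±1.96 of its fitted SE, and ranks by NMB swing at
£30 000/QALY.

## Scenarios

Eleven named variants: base case; multiple withdrawals; Gompertz
(favourable) and exponential (unfavourable) restart-risk curves;
literature baseline utilities (override 0.99 — a labelled assumption sized
to lift arm QALYs by ≈3); outlier-controlled utilities (baseline 0.88,
withdrawal increment 0.016 — labelled assumptions standing in for the
outlier-excluded trial regression); outlier-controlled costs (management
offset −£15); ravulizumab; 2-year and 10-year horizons; 50% eculizumab
price cut. Outlier control is a parameter override, not a re-run of the
trial analysis, mirroring how adjusted trial estimates fed the published
model.

**Multiple withdrawals** is semi-Markov: relapse risk depends on time since
the *current* withdrawal, so off-treatment states are expanded by a
within-episode cycle clock (memory guard at 10⁷ phase cells). A relapse
triggers a 3-month re-treatment course (⌈3·30.4375/14⌉ = 7 cycles at
maintenance dosing plus the re-initiation one-off), after which the patient
withdraws again with the clock and the monitoring phase schedule reset;
relapses presenting beyond CKD 3 stay on treatment for life. Each relapse
re-rolls the 25% stage-progression risk, so repeated withdrawal
accumulates genuinely more advanced-disease exposure than single
withdrawal — the strategy's large cost saving survives, but its QALY gain
does not (see Limitations). The engine is validated cycle-by-cycle against
an individual-level microsimulation of the same rules.

## Trial-panel analysis

EQ-5D-5L profiles map to utilities through a pluggable crosswalk CSV
(profile → value); the bundled crosswalk is **synthetic** (monotone in
severity, full health 1.0, worst −0.2), generated programmatically, and is
not any published tariff. Per-patient QALYs are trapezoidal areas under
utility vs time; the complete-case rule requires at least two observed
visits including baseline. Missingness is reported per arm and instrument
and never imputed. Utility and monthly-cost changes are estimated with a
random-intercept linear model (REML via statsmodels `MixedLM`, BFGS with
seeded fallbacks) on all observed post-baseline visits, with covariates
month (linear), age, sex, baseline outcome, withdrawal-arm indicator and
post-relapse indicator. The estimation method is a package choice; the
contract — enforced by simulation tests — is consistency and ≥90%
per-coefficient CI coverage on generator data, not coefficient-for-
coefficient equality with the published tables (the real data are
unavailable).

## Synthetic-data generator

`GeneratorConfig` defaults encode the emulated study: 28 withdrawal + 11
comparison patients; visits at months 0, 1, 3, 6, 9, 12, 18, 24; relapse
times lognormal with σ = 1.5 and location solved so `P(T < 24) = 4/28`
(≈14% two-year relapse); instrument-level MCAR missingness with per-visit
rates solved from the per-patient any-missing targets (61%/91% for EQ-5D,
57%/91% for costs); one outlier patient (utility −0.35, costs ×15);
utilities truncated at 1, costs floored at 0. MCAR is assumed because the
published available-case analysis is unbiased under MCAR and no
missing-at-random mechanism was described. Cost noise is Gaussian around a
right-skewed patient baseline, with skew supplied by the lognormal-like
baseline spread and the outlier; the cost constant is set high enough
(£800/month) that the zero floor almost never binds, keeping the linear
panel model well-specified.

**What the generator does not emulate:** informative missingness,
visit-time jitter, discreteness of real EQ-5D utilities, correlation
between utility and cost trajectories, or any treatment-policy feedback.
Passing recovery tests therefore certify the estimators under the
generator's assumptions, not under real trial conditions.

**Recovery-test regime.** Estimator-validation tests run the utility
generator at baseline 0.70 instead of the trial's 0.86: at 0.86 the
generating coefficient truths push roughly a tenth of visit utilities over
the EQ-5D ceiling, truncation attenuates them, and the generating truth is
no longer the estimand of a linear model — an intrinsic feature of
ceiling-limited utilities worth remembering when reading the published
coefficients too. Calibration tests (event fraction, missingness, ceiling,
outlier extremity) all run at the study defaults.

## Numerical choices and problem sizes

- Transition rows are validated to sum to 1 within 1e−9; traces to 1
  within 1e−10 with non-decreasing death occupancy.
- BIC ties round at 1e−10 before the fewer-parameters tie-break.
- Degenerate inputs: no-event survival data refuse to fit (unidentifiable);
  `S = 0` maps to relapse probability 1; Gompertz shape passing through 0
  is guarded at 1e−9; beta draws may round to exactly 1.0 in floating
  point and are accepted.
- The suite's simulation sizes: cohort-vs-microsimulation at 200 000
  individuals (multinomial per state per cycle, and an individual-level
  version with per-patient clocks for the multiple-withdrawal rules); PSA
  moment checks at 10⁵ draws; panel-model coverage over 50 replicates of
  200 patients; the shared test PSA at 1500 iterations. The acceptance
  script uses the full 5000 iterations.

## Limitations

- All reference numbers depend on the synthetic relapse fixture; absolute
  cost and QALY *levels* are approximately, not exactly, reproducible (the
  published 2-year and lifetime per-cycle costs are themselves mutually
  inconsistent, so exact level-matching is not a meaningful target).
- The published near-zero survival penalty of withdrawal (equal printed
  life years in both arms) cannot be derived from the published inputs:
  any reading that lets the stated excess mortality act on the
  relapse-progression flow produces a visible LY deficit (about 0.03 here).
  The corresponding structural checks in the suite fail by design and are
  documented as such.
- For the same reason the multiple-withdrawal strategy, which re-exposes
  patients to progression at every relapse, loses its published QALY gain
  here while reproducing the published cost saving.
- No parameter correlations (none were specified), no EVPI, no
  meningococcal-risk modelling, no covariate-adjusted survival models, no
  multiple imputation.
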