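# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, and what the packaged tests do and do not
demonstrate.

## Structural model

Balovaptan kinetics are described by a one-compartment disposition
model (amounts in mg) with three interacting mechanisms:

**Transit-compartment absorption.**  An oral dose reaches the
absorption depot `Aa` through a chain of hypothetical transit
compartments.  Rather than integrating a discretised chain, each dose
contributes the analytic gamma flux

    Input(t) = D · Ktr^(Ntr+1) · (t−td)^Ntr · e^(−Ktr(t−td)) / Γ(Ntr+1)

with `Ktr = (Ntr+1)/MTT`, evaluated through log-gamma so non-integer
`Ntr` (5.81) is exact and the flux integrates to the dose.  The same
`Ktr` drives the depot-to-central transfer, as implied by the single
mean-transit-time parameterisation.  Because doses enter only through
this flux, all state trajectories are continuous; dose times and
infusion boundaries are hard integration restarts, not state jumps.

**Dynamic central volume.**  `Vc = V0·(1 − VLmax·Ac/(Ac+VL_A50))` is an
empirical stand-in for capacity-limited peripheral binding.  With the
packaged estimates the apparent half-life runs from ≈9 h when the
central amount is far above `VL_A50` to ln2·V0/CL ≈ 46 h in the terminal
phase, which is what couples dose to washout speed and accumulation.
`VL_A50` and `S` are interpreted on the mg amount scale, the only
reading under which the packaged IV reference table and the long
steady-state half-life are simultaneously reproducible.

**Gut extraction.**  A turnover state `At` (initial value 1, input and
output rate `Kin = Kout = 0.00205 /h`) gates a pre-systemic loss
`At·Kgut·Aa` from the depot; depot drug stimulates the degradation of
`At` by the factor `(1 + S·Aa)`.  Because `Kout` is slow, `At`
integrates over days of dosing: availability per dose is lowest for
small single doses (~0.76 at 1.5 mg QD steady state, fed) and
approaches 1 at 50 mg.  The per-dose availability reported in
`ConcentrationProfile.F_interval` attributes losses between consecutive
dose times to the earlier dose — exact when absorption completes within
the interval, approximate otherwise.

**IV route.**  Infusions are zero-order inputs directly into the
central compartment with `CL` and `Vc` unchanged from the oral model
(complete oral bioavailability at reference dosing); absorption and gut
extraction are bypassed.

**Covariates.**  `V0` scales proportionally with body weight around the
76 kg reference with a fixed exponent of 1.  Clearance maturation uses
the logistic `f(age) = 1/(1 + e^(−AGE_slope·(age−AGE50)))`, which is
exactly 0.5 at `AGE50` (5.34 y), ≈0.91 at 14 y, and plateaus near age
20.  This functional form is a reconstruction: it is the standard
monotone asymptotic maturation curve consistent with the definition of
`AGE50` as the age of half-maximal adult clearance.

**Food effect.**  The fixed food-effect parameter (3.39) is applied
multiplicatively: `MTT_fed = 0.367 × 3.39 = 1.244 h`.  The alternative
reading — fed MTT of 3.39 h outright — is available via
`food_effect_mode="absolute"`.  The multiplicative default was chosen
because it keeps dose-normalised steady-state AUC within the −10%/+15%
band across 1.5–50 mg QD fed dosing (the absolute reading drives the
1.5 mg deviation to −32%, inconsistent with the near-proportional
steady-state exposure the model is meant to represent) and yields a fed
steady-state Tmax of ≈3 h.

**Residual error.**  Proportional variance decays mono-exponentially
with time after dose from 1.20 to 0.216 (half-life ln2/1.32 ≈ 0.53 h),
plus additive variance 0.025² (ng/mL)².  Both quantities are variances;
the additive SD equals half the 0.05 ng/mL LLOQ.  Simulated
observations below the LLOQ are flagged BLQ but never truncated or
deleted; estimation excludes them.

## Receptor occupancy

`RO = 100·Cp·fu/(Kb + Cp·fu)` on the free-concentration scale with
`fu = 0.13`.  No assay value of `Kb` is packaged; the default
(0.4220 ng/mL) is calibrated once by least squares on the occupancy
scale against the four paired trough anchors of the packaged reference
scenario (74→96%, 59→95%, 42→93%, 15→82%) and then frozen.  The
calibration is identifiable only up to `Kb/fu`: any joint rescaling of
`fu` and `Kb` leaves occupancy unchanged (property-tested).  Occupancy
is always computed on model-predicted concentrations without residual
error — the target is a biological state, not an assay reading — and
only between-subject variability enters the attainment bands.

The attainment target is ≥80% occupancy in ≥95% of subjects over 72 h.
The window is scored from the end of the first infusion (occupancy
necessarily starts at zero) to 72 h.  Under the packaged reference
scenario (50/25/15 mg daily 60-min infusions) the minimum attainment
fraction is ≈0.93, reached at the 72-h mark as the 5th percentile slips
under 80% shortly before the window closes; `criterion_met` is
therefore formally `False` for this scenario and the summary exposes
the minimum fraction and crossing times so such near-misses can be
judged on their merits.  Scenario ranking places criterion-met
scenarios first (lowest total dose, then earliest post-window offset)
and orders near-misses by their minimum attainment fraction.

## Virtual populations and synthetic datasets

The original trial populations are not redistributable, so the
generators emulate structure, not data:

* adult phase-I style populations: fixed 76 kg or truncated-normal
  weight (mean 82.2, SD 20.3, range 41–136 kg for the sensitivity
  setting);
* a pediatric/adult mixture for dose selection: 70% children with ages
  uniform on 2–18 y, 30% young adults uniform on 18–25 y;
* age-linked weights: log-normal scatter (CV 15%) around a
  piecewise-linear median growth curve through (2 y, 12 kg), (5 y,
  18 kg), (10 y, 32 kg), (14 y, 50 kg), (18+ y, 70 kg).  This curve is
  a synthetic stand-in carrying the qualitative age–weight coupling the
  analysis needs; it is not a demographic claim.

Sampling-scheme presets mirror the source study designs (rich
first-in-human MAD sampling with a 312-h washout; trough-dominated
interaction-study sampling; sparse phase-II visit grids; the pediatric
at-home sample drawn from an arbitrary 8–14 h evening window).  Etas
are drawn per subject from spawned RNG streams, so enlarging a
population leaves earlier subjects unchanged; identical seeds produce
byte-identical datasets.

What passing tests on these populations do **not** show: behaviour
under real covariate correlations (weight–age–sex joint structure
beyond the median curve), real adherence patterns, assay artefacts
beyond the Gaussian error model, or disease/age groups outside the
2–65 y range the maturation and allometric models cover.

## Pediatric dose selection

Each subject receives `adult_dose × fraction(age)` orally QD (fed) to
steady state; steady-state AUC is summarised by age bin (2–4, 5–9,
10–14, 15–17, adult) as geometric means with 90% intervals, and each
pediatric bin is compared with the adult bin as a geometric-mean ratio.
The pass band (0.8, 1.25) is the standard bioequivalence convention,
adopted here as a packaged convention for "equivalent and homogeneous",
not an external estimate.  The packaged updated scheme (100% from 10 y,
70% at 5–9 y, 40% at 2–4 y) keeps all bins within the band; a flat
adult dose at all ages overexposes 2–4-year-olds by roughly 2–3-fold.
The `fraction_recommender` inverts the logic: suggested fractions are
ratios of band geometric-mean clearance to adult geometric-mean
clearance (hence independent of the reference dose), rounded to 5%.

## Estimation stage

The estimation layer is an identifiability surface for the implemented
model, not a reproduction of a mixed-effects trial fit.  A single
Gaussian −2·log-likelihood kernel (time-varying combined error, or
constant proportional, with BLQ records excluded) backs both:

* `map_ebe` — per-subject MAP (empirical Bayes) etas: observation
  likelihood plus the log-normal prior; subjects with no quantifiable
  observations return the prior mode (zero).
* `fit_pooled` — pooled maximum likelihood over free fixed effects with
  etas at zero, optimised on the log scale by L-BFGS-B with five
  jittered starts (best objective wins, ties to the first start),
  finite-difference steps set above the ODE-solver noise floor, and
  relative standard errors from a central-difference Hessian.

The packaged recovery experiment uses three typical subjects at 5, 12
and 52 mg QD for 7 days with day-1 rich sampling, interdose troughs and
a 96-h washout, 5% proportional noise; it returns CL, V0, VLmax and
VL_A50 within a few percent.  The dose range is what identifies the
binding-capacity parameters; fits of `VLmax`/`VL_A50`/`Kgut`/`S` on
single-dose-level data are flagged.  Note that with rich day-1 sampling
a single dose level still constrains `VL_A50` weakly through the
concentration *shape* (the likelihood profile is not flat, only much
shallower than with a dose range).

## Numerical choices

* LSODA with rtol 1e-8 / atol 1e-10 for single-subject work; population
  runs default to rtol 1e-6 / atol 1e-9, where integration error is far
  below Monte-Carlo spread.
* Steady state: repeat the interval until consecutive interval AUCs
  (trapezoid on a 97-point within-interval grid) change by <0.5%, with
  a 14-interval minimum and 60-interval cap; transient tolerance
  crossings reset the convergence marker.  Interval AUC at the stop
  rule sits within ~0.5% of the asymptote; tests that need the exact
  linear-limit identity tighten the tolerance.
* Percentiles are type-7 (linear interpolation) throughout, so
  quantile-based tolerances are well defined.
* Transit fluxes from doses more than ~12 mean-transit-times in the
  past are dropped (relative contributions < 1e-12).
* Concentration output is `1000·Ac/Vc` (mg/L → ng/mL); negative ODE
  round-off in `Ac` is clamped at zero before the volume map.

## Problem sizes

Packaged test and reproduction runs use: 2000 subjects for the IV
exposure/occupancy population; a 6-dose scan (1.5–50 mg) to steady
state for dose proportionality; 1000 (updated scheme) and 600 (flat
comparator) subjects for pediatric equivalence; 3 subjects × 3 dose
levels for parameter recovery; 120–200 replicates for VPC checks.
These sizes put Monte-Carlo error comfortably inside the stated
tolerances (e.g. median concentration SE ≈ 1% at n = 2000).

## Known limitations

* The maturation curve, `Kb`, and the pediatric growth curve are
  reconstructions/calibrations, identifiable only against the packaged
  reference quantities, and marked as such in code.
* The gut-extraction turnover is empirical; outside the 1.5–75 mg
  dosing range its extrapolation is unvalidated, and the dose scan
  refuses doses outside that range.
* `F_interval` attribution is approximate when absorption spills past
  the next dose (fasted regimens with dosing intervals ≪ MTT are not a
  practical concern).
* No covariate effects on clearance other than age are modelled (body
  size affects volume only), matching the final covariate structure the
  parameters encode.
* The estimation stage omits full nonlinear mixed-effects machinery
  (FOCE/SAEM), bootstrap uncertainty and covariate selection by design.
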