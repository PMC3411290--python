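# Methods

## Scope

`lymphorad` estimates the mortality consequences of the ionising-radiation
exposure that patients with malignant lymphoma receive from CT and
¹⁸F-FDG PET during diagnosis, therapy response assessment and follow-up.
It covers two built-in populations: paediatric Hodgkin's disease (ages at
diagnosis 0, 1, 5, 10, 15 y) and adult diffuse large B-cell lymphoma
(55, 65, 75 y), both sexes. Chest radiography, ultrasound and the
attenuation-correction low-dose CT of combined PET/CT are excluded as
negligible or out of scope; only mortality (not morbidity/incidence) is
modelled.

## Dose accumulation

Per-examination doses (organ doses, effective dose, total-body dose for CT;
all mSv) are tabulated on six phantom age categories and interpolated
linearly, component-wise, to the patient age at each scheduled exam. The
adult anchor sits at 20 y by default: the adult reference phantom weighs
74 kg, which a growth trajectory through the 56.8-kg 15-year phantom
reaches around age 20, not 18; this choice also reproduces the reference
cumulative doses for the oldest paediatric category (113 mSv at age 15)
where an 18-y anchor overshoots by ~3 mSv. Beyond the anchor, adult values
apply as a plateau. Tabulated equivalent doses (mSv) are used numerically
as absorbed dose (mGy) in the risk models — exact for photon/positron
radiation (radiation weighting factor 1).

The two built-in schedules (12 CTs + 2 PETs over 60 months for HD; 7 CTs +
1 PET over 24 months for DLBCL) carry exam-type assignments and follow-up
timings from the published protocols. Two under-determined details are
fixed by configurable defaults: therapy-phase CTs at 2 and 4 months with
the post-therapy PET at 6 months (children) / therapy PET at 3 months
(adults) — shifting these moves paediatric doses by well under 1 mSv — and
the split of paediatric follow-up CTs (7 neck–chest at 3–24 months, 2
whole-body at 36/60 months), for which the published sources disagree
internally; the chosen split reproduces the published cumulative doses,
and the alternative (5 neck–chest) is available via `swap_followup=True`.
Custom schedules load from YAML.

## Risk model

Site-specific solid-cancer mortality ERR uses the standard three-parameter
form β_sex·d·exp(γe*)·(a/60)^η with e* = (e−30)/10 truncated at 0 from age
30; leukaemia uses the linear–quadratic, time-since-exposure-modified form
β_sex·d(1+θd)·exp[γe* + δ ln(t/25) + φ e* ln(t/25)], driven by bone-marrow
dose. Parameter values are transcribed into `data/err_solid.csv` /
`data/err_leukemia.csv` and are user-overridable. Risk transport is purely
multiplicative (ERR-only): excess mortality at attained age a is
Σ_s λ_s(a,sex)·ERR_s, with baseline site rates λ_s from the cancer-rate
tables. Sex-specific sites (breast, uterus, ovary; prostate) contribute
only for the matching sex. No thyroid *mortality* ERR fit exists; the
incidence coefficients are applied to the (very small) baseline
thyroid-mortality rate, which slightly overstates that term — set its β to
zero in a custom parameter file to drop it.

Tunable constants (`RiskConfig`):

| parameter | default | meaning |
|---|---|---|
| `ddref` | 1.5 | dose & dose-rate effectiveness factor dividing solid-cancer ERR (≥1; the leukaemia model carries its own curvature and is never divided) |
| `latency_solid_years` | 5 | minimum lag between exposure and expressed solid-cancer risk |
| `latency_leukemia_years` | 2 | same for leukaemia |

Whether the original analysis applied a DDREF or latency is not
recoverable; both are exposed and the defaults are the conventional
choices of BEIR-style lifetime-risk calculators. Multiple exposures add on
the ERR scale (linear no-threshold superposition).

## Life table

Cohorts start at the age at diagnosis with survivorship 1 and run to
`max_age` = 110 y in steps of `step_years` (default 1). Within each step
the three hazards — background all-cause μ(a,sex), radiation excess M(a),
disease excess h_D(t since diagnosis) — are evaluated at the interval
midpoint and treated as constant, giving q = 1 − exp(−μΔt). Midpoint
evaluation is what makes annual and monthly tables agree to <0.5% despite
the exponentially growing background hazard. Deaths are attributed to the
three causes proportionally to their hazard components (the standard
competing-risks partition; the attribution rule is a modelling convention,
not an observable). Person-years accumulate trapezoidally
(Δt·l·(1 − q/2)); survivors at `max_age` are treated as dying there and
contribute no further person-years (<0.1% effect for realistic tables).
Radiation excess is *not* subtracted from the background table (the excess
is <1% of background, so the double-count is negligible).

Derived estimators: REID = Σ radiation-attributed deaths; life expectancy
at diagnosis (conditional on being alive at diagnosis); reductions of life
expectancy as LE differences against counterfactual runs with one hazard
removed, reported in days (×365.25); survival at the disease horizon.
Cohort summaries average categories with unweighted arithmetic means.

## Disease-related mortality

A constant excess hazard h = −ln(S_T)/T is calibrated to the published
survival anchor (HD: S₁₀ = 0.94 → h ≈ 0.00619/y; DLBCL: S₅ = 0.58 →
h ≈ 0.109/y), making the disease-specific survival multiplier at the
horizon exact by construction. The hazard persists for life by default.
This was a genuinely open design choice — a cure model (hazard zero after
T) is the other natural reading — but the persistent form is the only one
consistent with the reference corrected estimators it is meant to
reproduce: disease-related life-expectancy reductions of thousands of days
for paediatric patients and the strong (50–80% in adults) suppression of
radiation-attributed deaths both require continued cohort depletion after
the horizon. `calibrate_disease_hazard(..., cure_after_years=T)` restores
the cure model.

## Synthetic input tables

The analysis needs two external tables that cannot be redistributed:
sex/age all-cause mortality for the European population and Euro-American
baseline cancer mortality by sex, age and site. The generator emulates
them:

* **Background**: Gompertz–Makeham hazard μ(a) = c + A·exp(B·a) per sex.
  Defaults (male c = 2.0e-4, A = 4.51e-5, B = 0.092; female c = 1.5e-4,
  A = 1.36e-5, B = 0.101) are calibrated to life expectancy at birth of
  76 y (male) and 82 y (female) with a Makeham floor matching European
  child/young-adult mortality (~1.5–2 × 10⁻⁴/y). Optional seeded
  log-normal noise (σ = 0.02) emulates the roughness of empirical period
  tables; the seed is recorded in the output metadata.
* **Cancer rates**: per site and sex, λ(a) = scale·((a − onset)/10)^power
  above an onset age. Onsets/powers are chosen per site (e.g. lung onset
  35, power 4; breast onset 25, power 2.5; leukaemia onset 0, power 2) and
  scales are calibrated so lifetime site-mortality fractions match
  published Euro-American magnitudes (≈20% of men, ≈17% of women dying of
  the modelled cancers). A validator enforces Σ_s λ_s(a) < μ(a) at every
  age.

What the synthetic tables do **not** reproduce: infant-mortality spike,
accident hump, cohort trends, country stratification, the detailed age
profiles of real site-specific registries (e.g. the premenopausal breast
plateau, the bimodal leukaemia curve). Consequently, absolute life
expectancies and REID values computed on synthetic inputs are
realistic-order reproductions, not registry-grade estimates; tests assert
them within wide (factor-two) windows plus strict orderings, while
structural invariants (conservation, monotonicity, closed forms) are
asserted tightly. Substituting genuine Eurostat/ICRP-format CSVs via the
documented schema is the production path, and absolute results then
inherit the vintage of those tables.

## Numerical choices and degenerate inputs

* q = 1 − exp(−μΔt) is exact for the piecewise-constant hazard assumption;
  no Taylor approximation is used anywhere.
* Rate tables live on integer age grids and are linearly interpolated at
  midpoints; lookups beyond the grid raise rather than extrapolate.
* Zero dose, zero baseline rates, empty exposure histories and S_T = 1 are
  all exact zeros along the whole pipeline (no epsilon floors).
* Attained age ≤ exposure age raises; exposures inside the latency window
  contribute exactly zero.
* The hand-checkable toy bundle (`make_toy_worked_example`) freezes
  closed-form golden values (flat hazards, inert ERR modifiers) to 1e-12
  for regression testing of the whole engine.

## Known limitations

* ERR-only risk transport; no ERR/EAR weighting, no uncertainty
  propagation of the risk-parameter covariances — point estimates only.
* Mortality only; radiation-induced *incidence* (morbidity) is larger and
  not modelled.
* The disease hazard is a single constant; real lymphoma mortality is
  front-loaded, so survival between 0 and T is slightly optimistic early
  and pessimistic late, though exact at the calibration horizon.
* Period, not cohort, life tables: no projection of future survival or
  background-mortality improvement.
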