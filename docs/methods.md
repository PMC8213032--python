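# Methods

This note documents the model as implemented: its assumptions, parameters,
numerical choices, what the synthetic inputs do and do not emulate, and the
design decisions taken where the published description left the design open.

## Model structure

The proportional multistate lifetable (PMSLT) couples three parts.

**Exposure.** Cohort systolic blood pressure (SBP) is modelled as normal with
a cohort-specific mean and a common standard deviation. The salt→SBP
dose-response is linear: the pooled effect is 4.18 mmHg per 4.4 g/day of
salt (≈0.95 mmHg per g/day). People with hypertension respond more strongly
than those without; the stratum slopes default to 5.39 and 2.42 mmHg per
4.4 g/day (hypertensive/normotensive) and are rescaled at construction so
that their prevalence-weighted mean at the reference hypertension prevalence
(30.6 %) equals the pooled slope exactly. Stratum membership is fixed by
pre-shift SBP (<140 vs ≥140 mmHg), so shifted hypertensive individuals may
end below the 140 mmHg threshold — this is how the intervention lowers
hypertension prevalence.

**Potential impact fraction.** The PIF compares the RR-weighted mass of the
original and shifted SBP distributions over 90–220 mmHg, with the stratum
split at 140 mmHg. The relative risk is log-linear per 10 mmHg above a
theoretical-minimum SBP of 115 mmHg, `RR(x) = rr₁₀^((x−115)/10)`, with
central `rr₁₀` = 1.6 for haemorrhagic and 1.45 for ischaemic stroke
(haemorrhagic steeper, consistent with the literature; both overridable).
The log-linear form is the comparative-risk-assessment convention; the
source for the relative risks does not print a functional form.

**Disease and lifetable.** Each disease/sex/age cohort runs a five-state
Markov model under reference and intervention incidence; the
disease-mortality difference is added to all-cause mortality in the
intervention lifetable. HALYs weight person-years by background comorbidity
and stroke disability; costs attach to first-ever incident events only.

## Numerical choices

- **Quadrature.** The PIF integrals use a composite trapezoid rule on a
  fixed 0.1 mmHg grid over [90, 220], with separate sub-integrals on
  [90, 140] and [140, 220] so the stratum discontinuity falls exactly on a
  panel boundary. The rule is refinement-checked in the tests (a 10× finer
  grid changes the result by <1e-6) and validated against a 10⁶-sample
  Monte-Carlo oracle (agreement within 0.001).
- **Pre-shift integration variable.** The shifted-distribution integral is
  evaluated by change of variables in pre-shift exposure space:
  `∫ RR(x − s(x)) P(x) dx` with `s(x)` the stratum shift. This keeps the
  90/220 truncation limits on the original distribution, so a null shift or
  a flat RR yields a PIF of exactly zero, and the two strata partition the
  population without gap or overlap. The 139.9/140 boundary in the source
  formula is treated as a half-open split at 140 (a discretisation artefact
  of the original spreadsheet implementation).
- **Truncation.** The [90, 220] window leaves <0.5 % of mass outside for
  typical cohorts; young female cohorts with low mean SBP truncate up to
  ~3 % below 90 mmHg, but RR = 1 below 115 mmHg so the truncated region
  cancels between numerator and denominator and the PIF is insensitive to
  it. The mass is exposed as `SBPStratifiedDistribution.truncation_mass`.
- **Rate→probability.** All hazards convert via `1 − exp(−rate·Δt)` with a
  1-year cycle.
- **Cycle ordering.** Incidence first; 28-day case fatality among that
  cycle's incident cases; first-year (months 2–12) chronic excess mortality
  among the acute survivors; long-term chronic excess among the previously
  diseased; cause-deleted background mortality (all-cause minus the
  disease's own contribution, to avoid double counting) among the remaining
  healthy and previously diseased. Person conservation is exact and checked
  to 1e-9 relative; negative compartments raise rather than being clipped.
- **Half-cycle correction.** Applied in the lifetable only
  (`person_years = (alive_start + alive_end)/2`), not inside the disease
  models, keeping disease-model conservation exact.
- **Age cap.** Five-year input bands (25–29 … 95–99) are expanded to
  single-year cohorts by uniform within-band allocation; cohorts age one
  year per cycle and leave the simulation at age 100.
- **Discounting.** 3 %/year from the 2019 base year, applied in the year of
  accrual; base-year amounts are undiscounted.
- **Negative adjusted mortality** (possible in principle with extreme
  deltas) is clipped to zero with a logged warning — the only place the
  model clips rather than raises, because the lifetable contract treats the
  delta as an externally supplied adjustment.

## Scenarios

Nine scenarios: targets 8 g/day by 2025, 7 g/day by 2030, 5 g/day by 2030,
each evaluated (i) cumulatively through the target-year cycle, (ii) over the
remaining lifetime with the achieved reduction sustained, and (iii) over the
lifetime with the SBP effect decaying after the target year. Salt declines
in equal annual decrements from each cohort's baseline to the target;
cohorts already at or below the target are unchanged (reduction proportional
to consumption). A cohort's salt intake is frozen at its baseline-age value
(a closed cohort keeps its consumption habit) while its SBP mean follows the
cross-sectional age profile as it ages; the source is silent on both points.

The decay ladder holds the full effect for five years after the target year,
then steps through 75/50/25/0 % in successive 5-year blocks (so the effect
is zero beyond 2045 for a 2025 target and beyond 2050 for a 2030 target).
The published wording admits a second reading — dropping *to* 25 % per
block — implemented behind `decay_mode="geometric"` (100/25/6.25/…);
the ladder is the default because both wordings are described as reaching
zero 20–25 years after the target.

Scenario horizons end with the target-year cycle inclusive ("by 2025" counts
the 2025 cycle).

## Probabilistic sensitivity analysis

Uncertain parameters and their families: salt–SBP pooled slope — normal
(mean 0.95 mmHg per g/day, SD 0.16, ≈17 % CV consistent with the spread of
long-term trial meta-analyses); relative risks per 10 mmHg — lognormal
(medians 1.45/1.6, σ_log 0.06); unit costs — gamma (means US$600/700 per
first-ever ischaemic/haemorrhagic case, CV 0.25). Default 2,000 draws.
Within a draw the same parameter values are applied to every scenario
(common random numbers), so per-draw scenario contrasts are coherent. Point
estimates are computed from central parameter values, not PSA means;
uncertainty intervals are empirical 2.5/97.5 percentiles. The stratum-slope
calibration is re-run inside each draw, and costs are drawn inside the same
loop as the epidemiology (joint uncertainty). All randomness flows from one
mandatory integer seed; identical seeds give byte-identical summaries.

## Synthetic inputs

The fixture generator emulates the *structure* of the original inputs, with
published summary anchors reproduced exactly by construction:

| quantity | value | status |
|---|---|---|
| adults ≥25, total / men / women | 61 M / 29.5 M / 31.5 M | anchor |
| adult mean salt, men / women | 10.5 / 8.3 g/day | anchor |
| 30–49-year mean salt, men / women | 10.3 / 8.2 g/day | anchor (consistency-derived) |
| crude first-ever stroke incidence | 115.7 / 100,000 py | anchor (calibrated) |
| haemorrhagic : ischaemic 28-day CF | 2.0 | anchor (ratio exact per cohort) |
| hypertension prevalence, 30–69 | ~0.30–0.32 | emergent from SBP profile |
| SBP SD | 15 mmHg | assumed (typical survey value) |
| SBP mean at 50, men / women | 136 / 132 mmHg | assumed, tuned to prevalence |
| ischaemic share of incidence | 0.55 | assumed |
| disability weights, isch / haem | 0.266 / 0.320 | assumed (GBD-style) |
| background YLD rate | 0.05→0.20 linear in age | assumed |
| chronic excess mortality | 2.0/2.5× background (year 1), 0.8/1.0× thereafter | assumed |

Salt follows a linear age profile solved against the realised population
weights so the all-adult and 30–49 means hit their anchors exactly; the
30–49 baselines are the values that make the three linear target
trajectories reproduce all six published annual-reduction rates. Band
population weights carry a small seeded lognormal jitter (2 % SD), so
different seeds give different age structures while every anchor still
holds exactly (the solves use the realised weights).

What the fixtures do **not** emulate: real survey microdata (sampling
design, within-cohort salt/SBP correlation), age-specific salt and SBP
values beyond the anchors (the gradients are configurable placeholders),
DISMOD-consistent chronic case fatality (replaced by explicit background
multipliers), and realistic absolute burden totals. Passing tests therefore
demonstrate the *mechanics* of the model — calibration identities,
conservation, dominance and asymmetry directions, uncertainty propagation —
not a quantitative reproduction of the original projections, which would
require the undeposited microdata.

## Problem sizes

The default full run simulates 150 single-year cohorts (2 sexes × ages
25–99) for up to 75 annual cycles and 2 diseases; one scenario evaluates in
~0.1–0.2 s, so the full 9-scenario deterministic set plus a 2,000-draw PSA
over the three base scenarios completes in a few minutes on one CPU. The
test suite uses scaled PSA runs (10–600 draws) and the resampling
consistency check compares 150 draws against a 600-draw reference interval.

## Known limitations

- Closed cohort: no births or migration, so long-horizon benefits are
  conservative.
- Stroke only; other blood-pressure-mediated outcomes (ischaemic heart
  disease, chronic kidney disease, hypertensive heart disease) are out of
  scope, as are societal/productivity costs and equity analysis.
- No stroke recurrence, remission or treatment effects; first-ever events
  only, which is also why costs attach to incidence.
- The salt→SBP relationship is linear with no J-curve; salt increases are
  rejected rather than modelled.
- Within-draw parameter uncertainty only; structural uncertainty (e.g. the
  RR functional form) is not propagated.
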