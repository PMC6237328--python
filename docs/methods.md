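# Methods

This note records the model, the numerical choices, and the reasoning
behind the places where the design was genuinely open.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Model overview

One categorical risk factor with ordered states (reference state listed
first) and a set of diseases, each with one of three mortality processes:

* **chronic-constant** — once present, a constant age/sex-specific
  attributable mortality rate `Am` (additive across diseases);
* **acutely-fatal** — additionally, individuals *without* the disease face
  an acute fatality hazard `M0_CF · RR_(r→i) · Π RR_(c→i)` modelling
  instantly fatal incident cases;
* **cured-fraction** — incident mass splits at diagnosis into a not-cured
  copy (carrying `Am`) and a cured copy (`Am = 0`), by an age-specific
  cured fraction.

Incidence follows the product form `I_i(r, C) = I0_i · RR_(r→i) ·
Π_j RR_(cj→i)` over causal diseases present; total mortality is
`M0_OC · RR_(r→OC) + Σ_i Am_i·d_i` plus acute-fatality terms.  The
risk-factor effect on other-cause mortality is optional and off by default.
Causal dependency is restricted to a single layer: a disease with causal
parents cannot itself be causal.

All quantities live on an integer age grid 0..`a_max` (default 95), one-year
piecewise-constant rates, with two sexes computed fully independently.
Disease prevalence, incidence and excess mortality inputs are held constant
above a cap age (default 87) because disease data become too sparse there.

## Initial-population construction

For each sex, age and disease, the baseline odds `b` solve
`Σ_r w_r · (rr_r b)/(rr_r b + 1) = p`.  The left side is strictly
increasing in `b`, so the root is unique; it is found with bracketed
root-finding (`scipy.optimize.brentq`) on `[0, (p/(1-p))/min positive rr]`,
and the residual is verified to be ≤ 1e-12.  Degenerate inputs: `p = 0`
gives `b = 0`; `p ≥ 1`, or `p` exceeding the total weight of strata with
positive `w·rr`, is an error.

Stage 1 assigns every disease without causal parents its per-risk-state
probability `rr·b/(rr·b+1)`; within a risk state diseases combine by
conditional independence (the construction has no other coupling channel).
Stage 2 forms composite strata (risk state × causal-parent states) with
stratum RR equal to the product of the risk RR and the RRs of parents
present, and solves each dependent disease's baseline odds against those
strata.  By construction, risk marginals are exact, disease marginals are
recovered to solver tolerance, and the prevalence odds ratio between any
stratum and the reference equals the input RR product exactly — the
constitutive assumption, made testable.

Cured-fraction diseases split their *prevalent* mass by the current-age
cured fraction.  The split is defined at diagnosis, but no diagnosis-age
rule for prevalent cases exists in this framework; the proportional
current-age split is the minimal assumption and is the one implemented.

Sampling is quota-first: `floor(n·mass)` individuals per risk state, the
remainder drawn from the fractional-part distribution, then disease states
drawn from the conditional distribution given the assigned risk state.

## Net transitions

Stationarity of the age/sex risk-factor prevalence is enforced by the
minimal-flow solution of the balance equations: for each boundary k between
adjacent ordered states, the signed net flow is `F_k(a) − F_k(a+1)` (F the
cumulative prevalence of states 1..k), converted to a probability by
dividing by the source-state prevalence.  `prev(a)·T(a) = prev(a+1)` holds
to rounding; flows exceeding their source mass raise "infeasible net flow".
The last age maps to the identity.

Two properties are deliberate:

* off-diagonal mass only between adjacent ordered states, at most one
  direction per boundary per age — so a *rising* never-smoker share forces
  current→never transitions, an artificial flow that the validation is
  designed to expose;
* **no mortality adjustment**: with risk-dependent mortality on, simulated
  prevalence drifts from the schedule at high ages.  This drift is part of
  what the consistency experiment measures and must not be corrected.

## Simulation engine

Within a year of age, all rates are constant and the disease/death process
of each dependency-connected disease cluster advances by the exact matrix
exponential of its continuous-time generator (joint cluster states plus an
absorbing dead channel).  This replaces any sequential update order
(risk draw, then disease, then mortality) by simultaneous competing risks
within the year, with the risk state frozen at its start-of-year value —
rates are given, so the exact exponential removes step-size ambiguity.

Because hazards are additive and clusters share no rates, the process
factorizes exactly given the risk path: overall survival is
`exp(−∫ M0_OC·RR_OC)` times the product of cluster alive-masses, with the
shared other-cause baseline kept outside the clusters so it is counted
exactly once.  The Monte-Carlo cohort (`simulate_newborn_cohort`) draws
risk biographies stochastically and carries cluster probability masses per
individual (partial micro-simulation); `forward_expectation` evolves the
full joint distribution (risk × all disease combinations ∪ dead)
deterministically and is the exact expectation of the cohort.  Its state
space grows as `n_risk · Π levels`, so it refuses scenarios above a
configurable limit (default 2048 alive states) and directs users to the
factorized cohort engine; the 8-disease scenarios are therefore compared
against Monte-Carlo cohorts, the 1–2-disease toys against the dense
recursion.

Baseline incidence is calibrated against the constructed joint
distribution: `I0 = I_pop / ⟨RR product⟩`, the average taken over the
joint mass renormalized among those currently without the disease, so the
first simulated year reproduces the input population incidence exactly.

Randomness: one master seed; replicate k derives its stream from
`SeedSequence([master, k])` (reduced to 31 bits), so every replicate is
individually reproducible; within a run, each sex gets an independent
substream `SeedSequence([seed, sex_index])`.

## Consistency metrics

* Within-disease risk distribution: `P(risk state | disease, alive)`;
  rows sum to 1; zero-prevalence cells are reported as missing, never as 0
  (avoiding silent bias at young ages with no disease).
* Comorbidity ratio `P_AB/(P_A·P_B)` per sex, age and pair; undefined when
  a marginal is zero.  Monte-Carlo standard errors for ratios use a
  delta-method influence decomposition over individuals.
* Difference tables: (initial − newborn) × 100 percent points for
  proportions, plain differences for ratios, at report ages {50, 65, 75,
  85} by default.  The "initial" side is always the exact joint
  distribution, never a sampled population, so all Monte-Carlo error is
  attributable to the cohorts.
* Replicate summary: mean and normal-approximation CI
  (`mean ± z·sd/√k`, default level 95%, protocol default k = 100
  replicates), computed on unrounded differences.
* Independence baseline: the plain product of all marginals — the
  comparator the approximate construction is expected to beat.

## Synthetic scenarios

The generator provides the study conditions; its defaults are fixed, not
tuning knobs.

* `smoking_like` — 3 ordered states with a generational profile: male
  never share falls until ~60 then recovers; female never share rises
  steeply with age (older cohorts largely never smoked), which is what
  forces the current→never net-transition artifact.  Eight diseases: a
  diabetes-like disease unaffected by the exposure but causal (declining
  RR 3→1.5) for two acutely-fatal cardiovascular diseases and heart
  failure (declining RRs, peaks 2.5–3.2), plus COPD-like (rising-then-
  falling RR, peak 9) and three cured-fraction cancers (peaks 6–12).
  Former-smoker RRs carry 35% of the current-smoker excess.
* `bmi_like` — 3 adiposity bands whose top band rises with age
  (physiology, not generation); diabetes-like disease with high declining
  RR (8→2), cardiovascular diseases, five modest-RR cancers, two of them
  sex-specific (zero incidence for the other sex, exercising the
  undefined-cell paths).
* `pearce_ideal` — the steady-state textbook case: age-constant RR
  (default 3), zero attributable mortality, risk-independent other-cause
  mortality, age-constant exposure, cumulative population incidence ≤ 2%.
  Marginal prevalence is derived *analytically* from the incidence so the
  inputs are exactly coherent; here construction and equilibrium should
  agree to within a percentage point.
* `causal_pair` / `independent_pair` — two-disease toys isolating the
  causal-comorbidity channel (constant causal RR, default 4) and the
  null case (no shared risk effect, no link).

Disease marginal prevalence for the epidemiological presets is derived
from incidence and excess mortality by a one-dimensional illness-death
recursion (other-cause mortality cancels from the proportion), giving
coherent but not exactly-equilibrium inputs — matching the realistic
situation where input prevalence reflects history, not the model's own
steady state.  Age curves are smooth parametric forms (logistics,
Gaussian bumps, Gompertz other-cause mortality with base 4e-5 and slope
0.09 per year); small seed-controlled lognormal jitters (σ ≈ 4–8%) vary
rates between seeds.  Incidence is zero below age 20 by default
(configurable) since the diseases modelled are adult-onset.

What the generator does *not* emulate: real registry noise, calendar
trends, migration, or nationally calibrated rate levels.  In particular
the synthetic disease burden is heavier, relative to other-cause
mortality, than typical national data, so the selective-mortality drift
of the risk-factor distribution at ages 80+ is more pronounced here than
a real-data application would show.  Passing tests therefore demonstrate
the internal consistency machinery and the direction and ordering of the
method's biases — not the magnitude such biases would take on any specific
national dataset.

## Numerical choices and degenerate inputs

* Baseline-odds residual tolerance 1e-12; joint cell masses conserve to
  1e-12 per (sex, age); generator exponentials conserve mass to 1e-10.
* Probabilities are renormalized per transition row only to repair
  floating-point rounding (relative 1e-16 level).
* Zero-prevalence or zero-incidence cells propagate as exact zeros
  (`b = 0`, `I0 = 0`); impossible demands (positive incidence with no
  disease-free mass at positive RR) raise errors naming disease, sex, age.
* Ties in quota sampling: the remainder is drawn from the fractional-part
  distribution; if all fractional parts are zero, nothing remains to draw.

## Known limitations

* Comorbidity between a causal disease and its consequence is
  overestimated by construction (the RR is applied to prevalent pairs
  regardless of acquisition order).  A weighted-average-RR correction has
  been suggested in the literature but no precise weighting rule is
  established; it is left as an extension point.
* Whether acute fatality also applies to prevalent cases is not decidable
  from the model description; the incident-only reading is implemented.
* The cured/not-cured split for prevalent cases uses the current-age cured
  fraction (see above).
* Problem sizes: the packaged experiments use cohorts of 500–2000 per
  one-year age/sex group and 2–100 replicates; the dense recursion is for
  toy scenarios only.
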