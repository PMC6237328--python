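"""Synthetic scenario generator.

Real scenario bundles for this kind of model are assembled from registry
and survey data that cannot be redistributed.  The generator below
produces fully self-contained scenarios that emulate the qualitative
structure of such inputs, so that every downstream stage (initial
population construction, net transitions, cohort simulation, consistency
metrics) is testable without any external data.

Presets
-------
``pearce_ideal``
    The textbook steady-state setting in which the prevalence odds ratio
    equals the incidence rate ratio: age-constant relative risks, zero
    attributable mortality, risk-independent other-cause mortality,
    age-constant exposure prevalence, and rare disease (cumulative
    incidence at most 2%).  Marginal prevalence is derived analytically
    from incidence, so inputs are exactly coherent.
``smoking_like``
    Three ordered exposure states (never/current/former), a generational
    prevalence profile (the never share rises steeply with age for
    women), and eight diseases: a diabetes-like disease unaffected by
    the exposure but causal for three cardiovascular diseases, two
    acutely fatal cardiovascular diseases with relative risks declining
    in age, and COPD-like plus three cancer-like diseases with
    rising-then-falling relative risks and (for the cancers) a cured
    fraction.
``bmi_like``
    Three ordered adiposity categories whose high category rises with
    age (physiology of aging), a diabetes-like disease with a high,
    declining relative risk, cardiovascular diseases, and five
    cancer-like diseases with modest relative risks, two of them
    sex-specific.
``causal_pair``
    Two diseases where A is causal for B with a constant relative risk;
    the risk factor has no direct effect on either.  Isolates the
    causal-comorbidity channel.
``independent_pair``
    Two diseases with no shared risk-factor effect and no causal link;
    their comorbidity ratio should be exactly 1 at equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ratetable import SEXES, RateTable
from .scenario import (
    KIND_ACUTE,
    KIND_CHRONIC,
    KIND_CURED,
    Disease,
    RiskFactor,
    Scenario,
    validate_scenario,
)

PRESETS = ("pearce_ideal", "smoking_like", "bmi_like", "causal_pair", "independent_pair")


@dataclass(frozen=True)
class ScenarioSpec:
    """Knobs for the synthetic generator.  Deterministic given ``seed``."""

    preset: str = "smoking_like"
    n_diseases: int | None = None
    rr_magnitude: float | None = None  # headline RR (peak for shaped curves)
    incidence_scale: float = 1.0
    excess_mortality_scale: float = 1.0
    a_max: int = 95
    #: Diseases emit zero incidence below this age (disease realism for
    #: adult chronic disease; set 0 for analytically clean toys).
    min_incidence_age: int = 20
    seed: int = 0


# ---------------------------------------------------------------------------
# curve helpers
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def shape_constant(peak: float):
    def fn(sex, ages):
        return np.full(len(ages), float(peak))
    return fn


def shape_declining(peak: float, floor: float = 1.0, a_mid: float = 60.0, width: float = 14.0):
    """RR high at young ages, declining toward ``floor`` in old age
    (cardiovascular pattern: equal absolute risk differences shrink the
    ratio as baseline risk grows)."""
    def fn(sex, ages):
        return floor + (peak - floor) * _sigmoid((a_mid - ages) / width)
    return fn


def shape_rising_falling(peak: float, a_peak: float = 62.0, width: float = 19.0):
    """RR near 1 in youth, peaking in late middle age, falling after
    (cumulative-exposure pattern of smoking on lung cancer and COPD)."""
    def fn(sex, ages):
        return 1.0 + (peak - 1.0) * np.exp(-0.5 * ((ages - a_peak) / width) ** 2)
    return fn


def _gompertz_mortality(a_max: int, base: float = 4e-5, slope: float = 0.09) -> RateTable:
    return RateTable.from_function(
        "other_cause_mortality", lambda s, a: base * np.exp(slope * a), a_max
    )


def _incidence_curve(base: float, growth: float, min_age: int, a_max: int,
                     sex_factor: dict[str, float] | None = None) -> RateTable:
    sf = sex_factor or {}
    def fn(sex, ages):
        ramp = np.clip((ages - min_age) / 10.0, 0.0, 1.0) if min_age > 0 else 1.0
        return sf.get(sex, 1.0) * base * np.exp(growth * (ages - 40.0)) * ramp
    return RateTable.from_function("incidence", fn, a_max)


def derive_prevalence_from_rates(
    incidence: np.ndarray, attributable_mortality: np.ndarray
) -> np.ndarray:
    """Marginal prevalence implied by incidence and excess mortality.

    One-dimensional illness-death recursion per sex: starting disease
    free, each year the diseased survive their attributable mortality
    while the disease-free acquire the disease at the population
    incidence rate; other-cause mortality hits both groups equally and
    cancels from the proportion.  This yields input prevalence curves
    that are epidemiologically coherent with the hazard inputs without
    requiring them to be the exact multistate equilibrium.
    """
    inc = np.asarray(incidence, dtype=float)
    am = np.asarray(attributable_mortality, dtype=float)
    p = np.zeros_like(inc)
    for a in range(inc.shape[1] - 1):
        surv_d = p[:, a] * np.exp(-am[:, a])
        new_d = (1.0 - p[:, a]) * (1.0 - np.exp(-inc[:, a]))
        alive = surv_d + (1.0 - p[:, a])
        p[:, a + 1] = (surv_d + new_d) / alive
    return np.clip(p, 0.0, 1.0 - 1e-9)


def _rr_tables(states, name, current_fn, former_frac, a_max, jitter=1.0):
    """Per-state RR tables: reference exactly 1; intermediate states
    interpolated at ``former_frac`` of the top state's excess."""
    tables = {states[0]: RateTable.constant(f"rr:{name}:{states[0]}", 1.0, a_max)}
    top = RateTable.from_function(
        f"rr:{name}:{states[-1]}",
        lambda s, a: 1.0 + (current_fn(s, a) - 1.0) * jitter,
        a_max,
    )
    if len(states) == 3:
        mid = RateTable(
            f"rr:{name}:{states[1]}", 1.0 + former_frac * (top.values - 1.0)
        )
        tables[states[1]] = mid
    if len(states) >= 2:
        tables[states[-1]] = top
    return tables


# ---------------------------------------------------------------------------
# risk-factor prevalence profiles
# ---------------------------------------------------------------------------

def _constant_risk_factor(name, states, shares, a_max) -> RiskFactor:
    prev = {
        s: RateTable.constant(f"prev:{name}:{s}", w, a_max)
        for s, w in zip(states, shares)
    }
    return RiskFactor(name, tuple(states), prev)


def _smoking_risk_factor(a_max: int) -> RiskFactor:
    """Generational profile: male never share falls until ~60 then rises;
    female never share rises steeply with age (older generations of
    women largely never smoked)."""
    def current(sex, a):
        if sex == "male":
            return 0.38 * _sigmoid((a - 17) / 3.0) * _sigmoid((75 - a) / 8.0)
        return 0.30 * _sigmoid((a - 17) / 3.0) * _sigmoid((55 - a) / 9.0)

    def former(sex, a):
        gate = _sigmoid((a - 20) / 3.0)  # former smokers lag uptake
        if sex == "male":
            return 0.45 * gate * _sigmoid((a - 30) / 8.0)
        return 0.25 * gate * _sigmoid((a - 30) / 8.0) * _sigmoid((70 - a) / 10.0)

    states = ("never", "current", "former")
    cur = RateTable.from_function("prev:smoking:current", current, a_max)
    fmr = RateTable.from_function("prev:smoking:former", former, a_max)
    nvr = RateTable("prev:smoking:never", 1.0 - cur.values - fmr.values)
    return RiskFactor("smoking", states, {"never": nvr, "current": cur, "former": fmr})


def _bmi_risk_factor(a_max: int) -> RiskFactor:
    def lt25(sex, a):
        return 0.75 - 0.35 * _sigmoid((a - 45) / 15.0)

    def over30(sex, a):
        return 0.10 + 0.15 * _sigmoid((a - 50) / 15.0)

    states = ("bmi_lt25", "bmi_25_30", "bmi_30plus")
    lo = RateTable.from_function("prev:bmi:bmi_lt25", lt25, a_max)
    hi = RateTable.from_function("prev:bmi:bmi_30plus", over30, a_max)
    mid = RateTable("prev:bmi:bmi_25_30", 1.0 - lo.values - hi.values)
    return RiskFactor("bmi", states, {"bmi_lt25": lo, "bmi_25_30": mid, "bmi_30plus": hi})


# ---------------------------------------------------------------------------
# disease assembly
# ---------------------------------------------------------------------------

def _build_disease(
    name, kind, states, rr_shape, former_frac, inc_base, inc_growth,
    am_base, spec, rng, *, cured_frac=None, fatality_frac=None,
    causal_rrs=None, sex_factor=None, min_age=None,
):
    a_max = spec.a_max
    jit_i = float(np.exp(rng.normal(0.0, 0.08)))
    jit_rr = float(np.exp(rng.normal(0.0, 0.04)))
    incidence = _incidence_curve(
        inc_base * spec.incidence_scale * jit_i, inc_growth,
        spec.min_incidence_age if min_age is None else min_age, a_max, sex_factor,
    )
    am = RateTable.from_function(
        "attributable_mortality",
        lambda s, a: am_base * spec.excess_mortality_scale * np.exp(0.02 * np.maximum(a - 40, 0)),
        a_max,
    )
    acute = None
    if kind == KIND_ACUTE:
        acute = RateTable(f"acute_fatality:{name}", fatality_frac * incidence.values)
    cured = None
    eff_am = am.values
    if kind == KIND_CURED:
        cured = RateTable.constant(f"cured_fraction:{name}", cured_frac, a_max)
        eff_am = am.values * (1.0 - cured_frac)  # population-average excess mortality
    total_inc = incidence.values + (acute.values if acute is not None else 0.0)
    prev = RateTable(f"prevalence:{name}", derive_prevalence_from_rates(total_inc, eff_am))
    rr_risk = _rr_tables(states, name, rr_shape, former_frac, a_max, jitter=jit_rr)
    return Disease(
        name=name, kind=kind, prevalence=prev, incidence=incidence,
        attributable_mortality=am, rr_from_risk=rr_risk,
        rr_from_causes=causal_rrs or {}, acute_fatality=acute, cured_fraction=cured,
    )


def _diabetes_causal_rr(a_max: int) -> RateTable:
    return RateTable.from_function(
        "rr_cause:diabetes", lambda s, a: shape_declining(3.0, 1.5)(s, a), a_max
    )


_SMOKING_DISEASES = [
    # name, kind, rr peak, shape, inc_base, growth, am_base, extra
    ("diabetes", KIND_CHRONIC, None, None, 2.0e-3, 0.045, 0.005, {}),
    ("chd", KIND_ACUTE, 3.0, "declining", 1.5e-3, 0.070, 0.006, {"fatality_frac": 0.12}),
    ("stroke", KIND_ACUTE, 3.2, "declining", 8.0e-4, 0.080, 0.008, {"fatality_frac": 0.15}),
    ("heart_failure", KIND_CHRONIC, 2.5, "declining", 5.0e-4, 0.100, 0.040, {}),
    ("copd", KIND_CHRONIC, 9.0, "rising_falling", 8.0e-4, 0.060, 0.012, {}),
    ("lung_cancer", KIND_CURED, 12.0, "rising_falling", 6.0e-4, 0.070, 0.120, {"cured_frac": 0.15}),
    ("oral_cavity_cancer", KIND_CURED, 6.0, "rising_falling", 1.0e-4, 0.050, 0.050, {"cured_frac": 0.40}),
    ("larynx_cancer", KIND_CURED, 8.0, "rising_falling", 6.0e-5, 0.050, 0.040, {"cured_frac": 0.35}),
]

_BMI_DISEASES = [
    ("diabetes", KIND_CHRONIC, 8.0, "declining_deep", 2.0e-3, 0.045, 0.010, {}),
    ("chd", KIND_ACUTE, 2.0, "declining", 1.5e-3, 0.075, 0.015, {"fatality_frac": 0.25}),
    ("stroke", KIND_ACUTE, 1.8, "declining", 1.0e-3, 0.085, 0.020, {"fatality_frac": 0.30}),
    ("heart_failure", KIND_CHRONIC, 2.2, "declining", 5.0e-4, 0.100, 0.080, {}),
    ("colorectal_cancer", KIND_CURED, 1.3, "constant", 5.0e-4, 0.060, 0.080, {"cured_frac": 0.45}),
    ("breast_cancer", KIND_CURED, 1.25, "constant", 9.0e-4, 0.040, 0.040,
     {"cured_frac": 0.60, "sex_factor": {"male": 0.0}}),
    ("prostate_cancer", KIND_CURED, 1.05, "constant", 8.0e-4, 0.070, 0.040,
     {"cured_frac": 0.55, "sex_factor": {"female": 0.0}}),
    ("kidney_cancer", KIND_CURED, 1.6, "constant", 1.2e-4, 0.055, 0.100, {"cured_frac": 0.40}),
    ("endometrial_cancer", KIND_CURED, 2.5, "constant", 2.0e-4, 0.050, 0.050,
     {"cured_frac": 0.65, "sex_factor": {"male": 0.0}}),
]

_CAUSAL_TARGETS = ("chd", "stroke", "heart_failure")


def _shape(tag: str | None, peak: float | None, override: float | None):
    peak = override if override is not None else peak
    if tag is None or peak is None:
        return shape_constant(1.0)
    if tag == "constant":
        return shape_constant(peak)
    if tag == "declining":
        return shape_declining(peak, floor=1.0 + 0.1 * (peak - 1.0))
    if tag == "declining_deep":
        return shape_declining(peak, floor=2.0)
    if tag == "rising_falling":
        return shape_rising_falling(peak)
    raise ValueError(f"unknown RR age-shape {tag!r}")


def _epi_preset(spec: ScenarioSpec, risk_factor: RiskFactor, table, former_frac) -> Scenario:
    rng = np.random.default_rng(spec.seed)
    n = spec.n_diseases or len(table)
    if not 1 <= n <= len(table):
        raise ValueError(f"n_diseases must be in 1..{len(table)}")
    rows = table[:n]
    states = risk_factor.states
    diseases = []
    have_diabetes = any(r[0] == "diabetes" for r in rows)
    for name, kind, peak, shape_tag, inc_b, growth, am_b, extra in rows:
        causal = {}
        if have_diabetes and name in _CAUSAL_TARGETS:
            causal = {"diabetes": _diabetes_causal_rr(spec.a_max)}
        rr_fn = _shape(shape_tag, peak, spec.rr_magnitude if shape_tag else None)
        diseases.append(
            _build_disease(
                name, kind, states, rr_fn, former_frac, inc_b, growth, am_b,
                spec, rng, causal_rrs=causal, **extra,
            )
        )
    from .scenario import DEFAULT_CAP_AGE

    sc = Scenario(
        name=f"{spec.preset}(seed={spec.seed})",
        risk_factor=risk_factor,
        diseases=tuple(diseases),
        other_cause_mortality=_gompertz_mortality(spec.a_max),
        a_max=spec.a_max,
        cap_age=min(DEFAULT_CAP_AGE, spec.a_max),
    )
    return sc.apply_age_cap()


# ---------------------------------------------------------------------------
# toy presets
# ---------------------------------------------------------------------------

def _pearce_ideal(spec: ScenarioSpec) -> Scenario:
    a_max = spec.a_max
    rr = spec.rr_magnitude if spec.rr_magnitude is not None else 3.0
    n = spec.n_diseases or 1
    states = ("unexposed", "exposed")
    w = np.array([0.5, 0.5])
    rf = _constant_risk_factor("exposure", states, w, a_max)
    rrs = np.array([1.0, rr])
    diseases = []
    for j in range(n):
        scale = 1.0 - 0.3 * j / max(1, n - 1) if n > 1 else 1.0
        # Baseline hazard chosen so cumulative population incidence stays <= 2%.
        i0 = scale * 0.018 / ((a_max + 1) * float(w @ rrs))
        ages = np.arange(a_max + 1)
        lam = rrs[:, None] * i0 * ages[None, :]  # cumulative hazard per stratum
        p_r = 1.0 - np.exp(-lam)
        prev = (w[:, None] * p_r).sum(axis=0)
        alive_free = (w[:, None] * (1.0 - p_r)).sum(axis=0)
        i_pop = i0 * (w[:, None] * (1.0 - p_r) * rrs[:, None]).sum(axis=0) / alive_free
        name = f"disease_{chr(ord('a') + j)}"
        diseases.append(
            Disease(
                name=name,
                kind=KIND_CHRONIC,
                prevalence=RateTable(f"prevalence:{name}", np.tile(prev, (2, 1))),
                incidence=RateTable(f"incidence:{name}", np.tile(i_pop, (2, 1))),
                attributable_mortality=RateTable.constant("attributable_mortality", 0.0, a_max),
                rr_from_risk={
                    states[0]: RateTable.constant("rr:ref", 1.0, a_max),
                    states[1]: RateTable.constant("rr:exposed", rr, a_max),
                },
            )
        )
    return Scenario(
        name=f"pearce_ideal(seed={spec.seed})",
        risk_factor=rf,
        diseases=tuple(diseases),
        other_cause_mortality=RateTable.constant("other_cause_mortality", 0.002, a_max),
        a_max=a_max,
        cap_age=a_max,
    )


def _simple_chronic(name, inc, am, spec, rr_cause=None, states=("low", "high")):
    a_max = spec.a_max
    incidence = _incidence_curve(inc * spec.incidence_scale, 0.0, spec.min_incidence_age, a_max)
    am_t = RateTable.constant("attributable_mortality", am * spec.excess_mortality_scale, a_max)
    prev = RateTable(
        f"prevalence:{name}", derive_prevalence_from_rates(incidence.values, am_t.values)
    )
    return Disease(
        name=name, kind=KIND_CHRONIC, prevalence=prev, incidence=incidence,
        attributable_mortality=am_t,
        rr_from_risk={s: RateTable.constant(f"rr:{name}:{s}", 1.0, a_max) for s in states},
        rr_from_causes=rr_cause or {},
    )


def _causal_pair(spec: ScenarioSpec) -> Scenario:
    a_max = spec.a_max
    rr = spec.rr_magnitude if spec.rr_magnitude is not None else 4.0
    states = ("low", "high")
    rf = _constant_risk_factor("exposure", states, (0.5, 0.5), a_max)
    d_a = _simple_chronic("disease_a", 4e-3, 0.010, spec, states=states)
    d_b = _simple_chronic(
        "disease_b", 2e-3, 0.020, spec,
        rr_cause={"disease_a": RateTable.constant("rr_cause:disease_a", rr, a_max)},
        states=states,
    )
    return Scenario(
        name=f"causal_pair(seed={spec.seed})",
        risk_factor=rf, diseases=(d_a, d_b),
        other_cause_mortality=_gompertz_mortality(a_max),
        a_max=a_max, cap_age=a_max,
    )


def _independent_pair(spec: ScenarioSpec) -> Scenario:
    a_max = spec.a_max
    states = ("low", "high")
    rf = _constant_risk_factor("exposure", states, (0.6, 0.4), a_max)
    d_a = _simple_chronic("disease_a", 3e-3, 0.010, spec, states=states)
    d_b = _simple_chronic("disease_b", 2e-3, 0.020, spec, states=states)
    return Scenario(
        name=f"independent_pair(seed={spec.seed})",
        risk_factor=rf, diseases=(d_a, d_b),
        other_cause_mortality=_gompertz_mortality(a_max),
        a_max=a_max, cap_age=a_max,
    )


def make_synthetic_scenario(spec: ScenarioSpec) -> Scenario:
    """Build a synthetic :class:`Scenario` from a preset spec.

    Deterministic given ``spec.seed``; every generated scenario passes
    :func:`~dynapop.scenario.validate_scenario`.
    """
    if spec.preset == "pearce_ideal":
        sc = _pearce_ideal(spec)
    elif spec.preset == "smoking_like":
        sc = _epi_preset(spec, _smoking_risk_factor(spec.a_max), _SMOKING_DISEASES, 0.35)
    elif spec.preset == "bmi_like":
        sc = _epi_preset(spec, _bmi_risk_factor(spec.a_max), _BMI_DISEASES, 0.40)
    elif spec.preset == "causal_pair":
        sc = _causal_pair(spec)
    elif spec.preset == "independent_pair":
        sc = _independent_pair(spec)
    else:
        raise ValueError(f"unknown preset {spec.preset!r}; expected one of {PRESETS}")
    problems = validate_scenario(sc)
    if problems:  # pragma: no cover - generator bug guard
        raise AssertionError(f"generator produced invalid scenario: {problems}")
    return sc
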