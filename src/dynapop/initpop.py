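"""Construction of the initial joint distribution from marginal inputs.

The construction answers: given only *marginal* inputs — the age/sex
prevalence of each risk-factor state and of each disease — what joint
distribution of risk-factor and disease states should the starting
population have?  The constitutive assumption is that the prevalence
odds ratio (POR) of a disease between a risk stratum and the reference
stratum equals the incidence rate ratio (RR) observed in epidemiological
studies.  Per (sex, age) and disease this leaves one free parameter, the
baseline odds ``b`` (the disease odds in the stratum where all RRs are
1), pinned down by requiring the mixture to reproduce the marginal
prevalence ``p``:

    sum_r  w_r * (rr_r * b) / (rr_r * b + 1)  =  p

The left side is strictly increasing in ``b``, so the solution is
unique and found by bracketed root-finding.

Diseases that are caused by other diseases are handled in a second
stage: the strata become the composite states r* = (risk state x joint
state of the causal diseases), with stratum RR equal to the product of
the risk-state RR and the RRs of the causal diseases present.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .ratetable import SEXES, sex_index
from .scenario import KIND_CURED, Scenario, validate_scenario

_RESIDUAL_TOL = 1e-12


def conditional_disease_probability(baseline_odds: float, rr) -> float | np.ndarray:
    """Disease probability in a stratum with relative risk ``rr``:
    ``rr*b / (rr*b + 1)``, always in [0, 1)."""
    x = np.multiply(rr, baseline_odds)
    return x / (x + 1.0)


def solve_baseline_odds(p: float, weights, rr, tol: float = _RESIDUAL_TOL) -> float:
    """Solve the baseline disease odds from marginal prevalence.

    Parameters
    ----------
    p:
        Marginal disease prevalence, ``0 <= p < 1``.
    weights:
        Stratum probabilities (non-negative, summing to 1).
    rr:
        Per-stratum relative risks (non-negative, reference 1).

    Returns
    -------
    The unique ``b >= 0`` with ``|sum_r w_r*(rr_r*b)/(rr_r*b+1) - p| <= tol``.
    """
    w = np.asarray(weights, dtype=float)
    r = np.asarray(rr, dtype=float)
    if not 0.0 <= p < 1.0:
        raise ValueError(f"prevalence must be < 1 (and >= 0), got {p}")
    if p == 0.0:
        return 0.0
    reach = w[r > 0].sum()  # attainable prevalence as b -> infinity
    if reach == 0.0 or p >= reach:
        raise ValueError(
            f"unattainable prevalence {p}: strata with positive weight*RR "
            f"cover at most {reach:g}"
        )

    def f(b):
        return float((w * conditional_disease_probability(b, r)).sum() - p)

    # Bracket: the all-RR-1 solution p/(1-p) scaled by the smallest positive RR
    # bounds b from above; expand defensively if rounding bites.
    hi = (p / (1.0 - p)) / max(r[r > 0].min(), 1e-300)
    while f(hi) < 0.0:  # pragma: no cover - only for extreme inputs
        hi *= 2.0
    b = brentq(f, 0.0, hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    assert abs(f(b)) <= max(tol, 1e-10), "baseline-odds solver failed to converge"
    return float(b)


@dataclass
class JointDistribution:
    """Exact joint distribution over (risk state x disease-state vector),
    per sex and age.

    ``mass`` has shape ``(2, a_max+1, n_risk, n_combo)`` where the combo
    axis enumerates joint disease-state vectors (``combos[c, i]`` is the
    level of disease ``i``: 0 absent, 1 present/not-cured, 2 cured).
    """

    risk_states: tuple[str, ...]
    disease_names: tuple[str, ...]
    disease_levels: tuple[int, ...]
    combos: np.ndarray  # (n_combo, n_diseases) int
    mass: np.ndarray  # (2, a_max+1, n_risk, n_combo)
    scenario_name: str = ""

    @property
    def a_max(self) -> int:
        return self.mass.shape[1] - 1

    @property
    def n_risk(self) -> int:
        return len(self.risk_states)

    # -- marginals ----------------------------------------------------
    def risk_marginal(self) -> np.ndarray:
        """(2, a_max+1, n_risk)"""
        return self.mass.sum(axis=3)

    def disease_marginal(self, name: str) -> np.ndarray:
        """P(disease present), any level >= 1.  Shape (2, a_max+1)."""
        i = self.disease_names.index(name)
        sel = self.combos[:, i] >= 1
        return self.mass[:, :, :, sel].sum(axis=(2, 3))

    def risk_disease_joint(self) -> np.ndarray:
        """P(risk state r & disease i present): (2, a_max+1, n_risk, n_d)."""
        out = np.empty(self.mass.shape[:3] + (len(self.disease_names),))
        for i in range(len(self.disease_names)):
            sel = self.combos[:, i] >= 1
            out[..., i] = self.mass[:, :, :, sel].sum(axis=3)
        return out

    def pair_prevalence(self) -> np.ndarray:
        """P(disease i present & disease j present): (2, a_max+1, n_d, n_d)."""
        nd = len(self.disease_names)
        pres = (self.combos >= 1)  # (n_combo, n_d)
        out = np.empty(self.mass.shape[:2] + (nd, nd))
        total = self.mass.sum(axis=2)  # (2, A+1, n_combo)
        for i in range(nd):
            for j in range(nd):
                sel = pres[:, i] & pres[:, j]
                out[:, :, i, j] = total[:, :, sel].sum(axis=2)
        return out

    # -- export -------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long format: sex, age, risk_state, one column per disease, mass."""
        nsex, na, nr, nc = self.mass.shape
        idx = pd.MultiIndex.from_product(
            [SEXES, range(na), self.risk_states, range(nc)],
            names=["sex", "age", "risk_state", "_combo"],
        )
        df = pd.DataFrame({"mass": self.mass.ravel()}, index=idx).reset_index()
        for i, name in enumerate(self.disease_names):
            df[name] = self.combos[df["_combo"].to_numpy(), i]
        cols = ["sex", "age", "risk_state", *self.disease_names, "mass"]
        return df[cols]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def enumerate_combos(levels: tuple[int, ...]) -> np.ndarray:
    """All joint disease-state vectors for the given per-disease levels."""
    if not levels:
        return np.zeros((1, 0), dtype=int)
    return np.array(list(itertools.product(*[range(k) for k in levels])), dtype=int)


def joint_cell_masses(scenario: Scenario, sex: str, age: int) -> np.ndarray:
    """Cell masses over (risk state x disease combo) for one (sex, age).

    Convenience wrapper around :func:`build_joint_distribution` internals;
    returns shape ``(n_risk, n_combo)``.
    """
    jd = build_joint_distribution(scenario, _only=(sex, age))
    return jd.mass[sex_index(sex), age]


def build_joint_distribution(scenario: Scenario, _only=None) -> JointDistribution:
    """Two-stage construction of the exact joint distribution.

    Stage 1 assigns each disease without causal parents its per-risk-state
    prevalence by solving the baseline odds against the risk strata;
    diseases are combined by conditional independence given the risk
    state.  Stage 2 forms composite strata (risk state x causal-disease
    states) and repeats the procedure for each dependent disease with
    stratum RR equal to the product of its risk-state RR and the RRs of
    the causal diseases present.  Cured-fraction diseases split their
    present mass into not-cured/cured by the age-specific cured fraction.

    Risk-state marginals are reproduced exactly, disease marginals to
    solver tolerance, and every within-stratum POR equals the input RR
    product by construction.
    """
    problems = validate_scenario(scenario)
    if problems:
        raise ValueError("invalid scenario: " + "; ".join(problems))

    rf = scenario.risk_factor
    diseases = scenario.diseases
    names = scenario.disease_names
    levels = tuple(d.n_levels for d in diseases)
    combos = enumerate_combos(levels)
    n_combo = combos.shape[0]
    nr = rf.n_states
    a_max = scenario.a_max

    w_all = rf.prevalence_array()  # (nr, 2, A+1)
    rr_risk = {
        d.name: np.stack([d.rr_from_risk[s].values for s in rf.states])
        for d in diseases
    }  # (nr, 2, A+1)

    cells = (
        [(sex_index(_only[0]), _only[1])]
        if _only is not None
        else [(si, a) for si in range(2) for a in range(a_max + 1)]
    )
    mass = np.zeros((2, a_max + 1, nr, n_combo))

    parents = {d.name: tuple(d.rr_from_causes) for d in diseases}
    name_idx = {n: i for i, n in enumerate(names)}

    for si, age in cells:
        sex = SEXES[si]
        w = w_all[:, si, age]
        # per-disease present-probability per (risk state, combo)
        prob_present = np.empty((len(diseases), nr, n_combo))
        # stage 1: diseases without causal parents
        for i, d in enumerate(diseases):
            if parents[d.name]:
                continue
            p = d.prevalence.value(sex, age)
            rr = rr_risk[d.name][:, si, age]
            try:
                b = solve_baseline_odds(p, w, rr)
            except ValueError as e:
                raise ValueError(f"disease {d.name!r} at ({sex}, {age}): {e}") from e
            prob_present[i] = conditional_disease_probability(b, rr)[:, None]
        # stage 2: dependent diseases against composite strata r*
        for i, d in enumerate(diseases):
            if not parents[d.name]:
                continue
            par_idx = [name_idx[c] for c in parents[d.name]]
            rr_cause = np.array(
                [d.rr_from_causes[c].values[si, age] for c in parents[d.name]]
            )
            # stratum weights: joint mass of (r, parent presence) from stage 1
            par_present = combos[:, par_idx] >= 1  # (n_combo, n_par)
            # collapse combos to distinct parent patterns
            patterns = [np.array(t) for t in itertools.product([False, True], repeat=len(par_idx))]
            strata_w, strata_rr = [], []
            rr_r = rr_risk[d.name][:, si, age]
            for pat in patterns:
                # P(parents in pattern | r) = prod over parents of p or 1-p
                pr = np.ones(nr)
                for k, pi in enumerate(par_idx):
                    pp = prob_present[pi, :, 0]  # parent is stage-1: combo-independent
                    pr *= pp if pat[k] else (1.0 - pp)
                strata_w.append(w * pr)
                strata_rr.append(rr_r * np.prod(np.where(pat, rr_cause, 1.0)))
            sw = np.concatenate(strata_w)
            sr = np.concatenate(strata_rr)
            p = d.prevalence.value(sex, age)
            try:
                b = solve_baseline_odds(p, sw, sr)
            except ValueError as e:
                raise ValueError(f"disease {d.name!r} at ({sex}, {age}): {e}") from e
            # per (r, combo): RR from risk state and the parents present in c
            rr_prod = rr_r[:, None] * np.prod(
                np.where(par_present[None, :, :], rr_cause[None, None, :], 1.0), axis=2
            )
            prob_present[i] = conditional_disease_probability(b, rr_prod)
        # assemble joint mass: w_r * prod_i P(level_i | r, parents(combo))
        m = np.tile(w[:, None], (1, n_combo))
        for i, d in enumerate(diseases):
            pp = prob_present[i]  # (nr, n_combo)
            lev = combos[:, i]
            if d.n_levels == 3:
                cf = d.cured_fraction.value(sex, age)
                factor = np.where(
                    lev == 0, 1.0 - pp,
                    np.where(lev == 1, pp * (1.0 - cf), pp * cf),
                )
            else:
                factor = np.where(lev == 0, 1.0 - pp, pp)
            m = m * factor
        mass[si, age] = m

    return JointDistribution(
        risk_states=rf.states,
        disease_names=names,
        disease_levels=levels,
        combos=combos,
        mass=mass,
        scenario_name=scenario.name,
    )


def sample_initial_population(
    joint: JointDistribution, n_per_cell: int, seed: int
) -> pd.DataFrame:
    """Sample a discrete population of ``n_per_cell`` individuals per
    (sex, age) from the joint distribution.

    Risk states are assigned by quota first — ``floor(n * mass)``
    individuals per state — with the remainder drawn from the residual
    (fractional-part) distribution; disease states are then drawn from
    the conditional distribution given the assigned risk state.
    Deterministic given ``seed``.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    sex_col, age_col, risk_col, combo_col = [], [], [], []
    nsex, na, nr, nc = joint.mass.shape
    for si in range(nsex):
        for age in range(na):
            w = joint.mass[si, age].sum(axis=1)  # risk marginal
            base = np.floor(n_per_cell * w).astype(int)
            short = n_per_cell - base.sum()
            counts = base.copy()
            if short > 0:
                resid = n_per_cell * w - base
                tot = resid.sum()
                probs = resid / tot if tot > 0 else np.full(nr, 1.0 / nr)
                counts += rng.multinomial(short, probs)
            for r in range(nr):
                if counts[r] == 0:
                    continue
                cond = joint.mass[si, age, r]
                s = cond.sum()
                if s <= 0:
                    continue
                combo_counts = rng.multinomial(counts[r], cond / s)
                n_r = int(combo_counts.sum())
                sex_col.append(np.full(n_r, SEXES[si], dtype=object))
                age_col.append(np.full(n_r, age))
                risk_col.append(np.full(n_r, joint.risk_states[r], dtype=object))
                combo_col.append(np.repeat(np.arange(nc), combo_counts))
    df = pd.DataFrame(
        {
            "sex": np.concatenate(sex_col),
            "age": np.concatenate(age_col),
            "risk_state": np.concatenate(risk_col),
            "_combo": np.concatenate(combo_col),
        }
    )
    for i, name in enumerate(joint.disease_names):
        df[name] = joint.combos[df["_combo"].to_numpy(), i]
    df["alive"] = True
    return df.drop(columns="_combo")
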