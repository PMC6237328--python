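"""Partial micro-simulation core.

The simulation is "partial": risk-factor biographies are drawn
stochastically per individual, while disease and survival states are
carried as probability masses conditional on the biography.  Within a
year of age all rates are constant, and the state advances by the exact
exponential of a continuous-time generator built from:

* incidence rates ``I0_i * RR_{r->i} * prod_j RR_{cj->i}`` (baseline
  incidence times the risk-state RR times the RRs of causal diseases
  currently present);
* a constant attributable mortality rate ``Am_i`` for each present,
  not-cured disease, additive across diseases;
* for acutely fatal diseases, an extra fatality hazard
  ``M0_CF,i * RR_{r->i} * prod_j RR_{cj->i}`` applied to individuals
  currently *without* the disease (it models instantly fatal incident
  cases);
* cured-fraction diseases split incident mass at diagnosis into
  not-cured/cured by the age-specific cured fraction;
* baseline other-cause mortality ``M0_OC`` (optionally multiplied by a
  risk-state RR), shared by everyone.

Because all hazards are additive and disease clusters (connected
components of the causal graph) share no rates, the joint process
factorizes exactly: each cluster evolves independently given the risk
path, and overall survival is the product of cluster alive-masses times
the other-cause survival factor, the latter counted exactly once.
A fully deterministic forward recursion over the complete joint state
space (:func:`forward_expectation`) serves as the exact expectation of
the Monte-Carlo cohort for scenarios small enough to enumerate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .initpop import JointDistribution, enumerate_combos
from .ratetable import SEXES, sex_index
from .scenario import KIND_ACUTE, KIND_CURED, Disease, Scenario
from .transitions import TransitionSchedule

__all__ = [
    "CalibratedParameters",
    "CohortResult",
    "calibrate_baseline_incidence",
    "incidence_rate",
    "mortality_rate",
    "evolve_cluster_year",
    "simulate_risk_path",
    "simulate_newborn_cohort",
    "forward_expectation",
]


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibratedParameters:
    """Baseline incidence per disease plus pass-through of the scenario.

    ``baseline_incidence[name]`` has shape ``(2, a_max+1)`` and holds
    ``I0_i``: the incidence in the stratum where all relative risks are 1.
    """

    scenario: Scenario
    baseline_incidence: dict[str, np.ndarray]
    include_oc_risk_effect: bool = False

    def rr_other_cause_array(self) -> np.ndarray:
        """(n_risk, 2, a_max+1); all ones unless the optional risk-factor
        effect on other-cause mortality is switched on."""
        rf = self.scenario.risk_factor
        if self.include_oc_risk_effect and rf.rr_other_cause is not None:
            return rf.rr_other_cause_array(self.scenario.a_max)
        return np.ones((rf.n_states, 2, self.scenario.a_max + 1))


def _rr_risk_array(scenario: Scenario, d: Disease) -> np.ndarray:
    """(n_risk, 2, a_max+1)"""
    return np.stack([d.rr_from_risk[s].values for s in scenario.risk_factor.states])


def calibrate_baseline_incidence(
    scenario: Scenario,
    joint: JointDistribution,
    include_oc_risk_effect: bool = False,
) -> CalibratedParameters:
    """Calibrate each disease's baseline incidence against the initial
    population so that the first simulated year reproduces the input
    population incidence.

    For disease i at (sex, age), the population incidence among those
    currently without the disease is ``I0_i`` times the average RR
    product over the joint distribution restricted to (and renormalized
    among) the disease-free; hence ``I0_i = I_pop,i / <RR product>``.
    """
    name_idx = {n: i for i, n in enumerate(joint.disease_names)}
    baseline: dict[str, np.ndarray] = {}
    for d in scenario.diseases:
        i = name_idx[d.name]
        rr_r = _rr_risk_array(scenario, d)  # (nr, 2, A+1)
        free = joint.combos[:, i] == 0  # combos without disease i
        # RR product per (sex, age, r, combo): risk RR times causal RRs present
        rr_prod = np.transpose(rr_r, (1, 2, 0))[:, :, :, None] * np.ones(
            joint.combos.shape[0]
        )
        for cause, table in d.rr_from_causes.items():
            present = joint.combos[:, name_idx[cause]] >= 1
            rr_prod = rr_prod * np.where(
                present[None, None, None, :], table.values[:, :, None, None], 1.0
            )
        m_free = joint.mass[:, :, :, free]
        denom_mass = m_free.sum(axis=(2, 3))
        weighted = (m_free * rr_prod[:, :, :, free]).sum(axis=(2, 3))
        i_pop = d.incidence.values
        i0 = np.zeros_like(i_pop)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_rr = weighted / denom_mass
        attainable = (denom_mass > 0) & (mean_rr > 0)
        bad = (i_pop > 0) & ~attainable
        if np.any(bad):
            si, age = np.argwhere(bad)[0]
            raise ValueError(
                f"incidence unattainable for disease {d.name!r} at "
                f"({SEXES[si]}, {int(age)}): no disease-free mass with positive RR"
            )
        i0[attainable] = i_pop[attainable] / mean_rr[attainable]
        baseline[d.name] = i0
    return CalibratedParameters(scenario, baseline, include_oc_risk_effect)


# ---------------------------------------------------------------------------
# per-state rates
# ---------------------------------------------------------------------------

def incidence_rate(
    cp: CalibratedParameters, disease: str, risk_state: str,
    causal_present, sex: str, age: int,
) -> float:
    """Nonfatal incidence rate of a disease given the current state:
    ``I0 * RR_{r->i} * prod_{j present} RR_{cj->i}``."""
    d = cp.scenario.disease(disease)
    si = sex_index(sex)
    rate = float(cp.baseline_incidence[disease][si, age])
    rate *= d.rr_from_risk[risk_state].values[si, age]
    for cause, table in d.rr_from_causes.items():
        if cause in causal_present:
            rate *= table.values[si, age]
    return rate


def mortality_rate(
    cp: CalibratedParameters, risk_state: str,
    disease_state: dict[str, int], sex: str, age: int,
) -> float:
    """Total mortality rate given risk state and disease-state vector.

    ``M0_OC * RR_{r->OC}`` plus the attributable mortality ``Am_i`` of
    every present not-cured disease (level 1; cured copies contribute
    0), plus — for each acutely fatal disease *not* currently present —
    its acute fatality hazard ``M0_CF * RR`` product.
    """
    sc = cp.scenario
    si = sex_index(sex)
    r_idx = sc.risk_factor.states.index(risk_state)
    rate = float(sc.other_cause_mortality.values[si, age]) * float(
        cp.rr_other_cause_array()[r_idx, si, age]
    )
    present = {n for n, lev in disease_state.items() if lev >= 1}
    for d in sc.diseases:
        lev = disease_state.get(d.name, 0)
        if lev == 1:
            rate += float(d.attributable_mortality.values[si, age])
        if d.kind == KIND_ACUTE and lev == 0:
            cf = float(d.acute_fatality.values[si, age])
            cf *= d.rr_from_risk[risk_state].values[si, age]
            for cause, table in d.rr_from_causes.items():
                if cause in present:
                    cf *= table.values[si, age]
            rate += cf
    return rate


# ---------------------------------------------------------------------------
# cluster machinery
# ---------------------------------------------------------------------------

@dataclass
class DiseaseCluster:
    """A dependency-connected set of diseases evolved as one joint chain.

    States are joint level-vectors of the member diseases plus one
    absorbing "dead from cluster-coupled hazards" channel (the last
    index).  Total mass is conserved by construction.
    """

    disease_names: tuple[str, ...]
    diseases: tuple[Disease, ...]
    levels: tuple[int, ...]
    combos: np.ndarray  # (n_states, k)

    @classmethod
    def from_scenario(cls, scenario: Scenario, names: tuple[str, ...]) -> "DiseaseCluster":
        ds = tuple(scenario.disease(n) for n in names)
        levels = tuple(d.n_levels for d in ds)
        return cls(names, ds, levels, enumerate_combos(levels))

    @property
    def n_states(self) -> int:
        return self.combos.shape[0]


def clusters_of(scenario: Scenario) -> list[DiseaseCluster]:
    return [DiseaseCluster.from_scenario(scenario, c) for c in scenario.clusters()]


def _generator(
    cluster: DiseaseCluster, cp: CalibratedParameters,
    si: int, age: int, r_idx: int, oc_rate: float = 0.0,
) -> np.ndarray:
    """Continuous-time generator over cluster states + dead for one year."""
    sc = cp.scenario
    combos = cluster.combos
    nS = cluster.n_states
    idx = {tuple(c): k for k, c in enumerate(combos)}
    local = {n: k for k, n in enumerate(cluster.disease_names)}
    r_state = sc.risk_factor.states[r_idx]
    Q = np.zeros((nS + 1, nS + 1))
    for s_i in range(nS):
        lev = combos[s_i]
        death = oc_rate
        for k, d in enumerate(cluster.diseases):
            if lev[k] == 1:
                death += d.attributable_mortality.values[si, age]
        for k, d in enumerate(cluster.diseases):
            if lev[k] != 0:
                continue
            rr = d.rr_from_risk[r_state].values[si, age]
            for cause, table in d.rr_from_causes.items():
                if lev[local[cause]] >= 1:
                    rr *= table.values[si, age]
            inc = cp.baseline_incidence[d.name][si, age] * rr
            if inc < 0:
                raise ValueError(f"negative incidence rate for {d.name}")
            if d.kind == KIND_CURED:
                cf = d.cured_fraction.values[si, age]
                t1 = list(lev); t1[k] = 1
                t2 = list(lev); t2[k] = 2
                Q[s_i, idx[tuple(t1)]] += inc * (1.0 - cf)
                Q[s_i, idx[tuple(t2)]] += inc * cf
            else:
                t1 = list(lev); t1[k] = 1
                Q[s_i, idx[tuple(t1)]] += inc
                if d.kind == KIND_ACUTE:
                    death += d.acute_fatality.values[si, age] * rr
        if death < 0:
            raise ValueError("negative mortality rate")
        Q[s_i, nS] += death
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


def evolve_cluster_year(
    state: np.ndarray, cluster: DiseaseCluster, cp: CalibratedParameters,
    risk_state: str, sex: str, age: int, oc_rate: float = 0.0,
) -> np.ndarray:
    """Advance one cluster state-mass vector by one year of age.

    ``state`` has length ``cluster.n_states + 1`` (last entry: dead).
    Uses the exact matrix exponential of the piecewise-constant
    generator, so total mass is conserved to rounding.
    """
    sc = cp.scenario
    r_idx = sc.risk_factor.states.index(risk_state)
    Q = _generator(cluster, cp, sex_index(sex), age, r_idx, oc_rate)
    return np.asarray(state, dtype=float) @ expm(Q)


def _year_matrices(
    cluster: DiseaseCluster, cp: CalibratedParameters, oc_rate: float = 0.0
) -> np.ndarray:
    """expm of the year generator for every (sex, age, risk state):
    shape (2, a_max+1, n_risk, S+1, S+1)."""
    sc = cp.scenario
    nr = sc.risk_factor.n_states
    a_max = sc.a_max
    S1 = cluster.n_states + 1
    out = np.empty((2, a_max + 1, nr, S1, S1))
    for si in range(2):
        for age in range(a_max + 1):
            for r in range(nr):
                out[si, age, r] = expm(_generator(cluster, cp, si, age, r, oc_rate))
    return out


# ---------------------------------------------------------------------------
# risk-factor biographies
# ---------------------------------------------------------------------------

def simulate_risk_path(
    schedule: TransitionSchedule, sex: str, rng: np.random.Generator,
    p0: np.ndarray, n: int = 1,
) -> np.ndarray:
    """Draw ``n`` risk-state paths (state indices per age).

    ``r(0)`` is drawn from ``p0`` (the age-0 prevalence); ``r(a+1)``
    from row ``T(a)[r(a)]``.  Returns shape ``(n, a_max+1)``.
    """
    si = sex_index(sex)
    a_max = schedule.a_max
    nr = len(schedule.states)
    paths = np.empty((n, a_max + 1), dtype=np.int64)
    cum0 = np.cumsum(p0)
    paths[:, 0] = np.searchsorted(cum0, rng.random(n) * cum0[-1], side="right")
    for a in range(a_max):
        u = rng.random(n)
        nxt = np.empty(n, dtype=np.int64)
        T = schedule.matrices[si, a]
        for r in range(nr):
            mask = paths[:, a] == r
            if not mask.any():
                continue
            cum = np.cumsum(T[r])
            nxt[mask] = np.minimum(
                np.searchsorted(cum, u[mask] * cum[-1], side="right"), nr - 1
            )
        paths[:, a + 1] = nxt
    return paths


# ---------------------------------------------------------------------------
# cohort results
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    """Per (sex, age) aggregates of a cohort run (or of an exact joint).

    All prevalence arrays are conditional on being alive.  ``*_se``
    arrays hold Monte-Carlo standard errors of the corresponding
    estimates (zero for deterministic results).
    """

    risk_states: tuple[str, ...]
    disease_names: tuple[str, ...]
    disease_levels: tuple[int, ...]
    alive: np.ndarray  # (2, A+1) expected alive mass per newborn
    risk_marginal: np.ndarray  # (2, A+1, nr)
    disease_prev: np.ndarray  # (2, A+1, nd)
    pair_prev: np.ndarray  # (2, A+1, nd, nd)
    risk_disease: np.ndarray  # (2, A+1, nr, nd) = P(r & disease | alive)
    disease_prev_se: np.ndarray | None = None
    comorbidity_se: np.ndarray | None = None  # (2, A+1, nd, nd)
    full_joint: np.ndarray | None = None  # (2, A+1, nr, n_combo), alive-normalized
    combos: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def a_max(self) -> int:
        return self.alive.shape[1] - 1

    def to_frame(self) -> pd.DataFrame:
        """Wide per-(sex, age) table: alive mass, per-disease prevalence,
        pairwise ``prev_<A>_<B>`` columns."""
        nd = len(self.disease_names)
        recs = {}
        na = self.a_max + 1
        recs["sex"] = np.repeat(SEXES, na)
        recs["age"] = np.tile(np.arange(na), 2)
        recs["alive_mass"] = self.alive.ravel()
        for i, n in enumerate(self.disease_names):
            recs[f"prev_{n}"] = self.disease_prev[:, :, i].ravel()
        for i in range(nd):
            for j in range(i + 1, nd):
                recs[f"prev_{self.disease_names[i]}_{self.disease_names[j]}"] = (
                    self.pair_prev[:, :, i, j].ravel()
                )
        return pd.DataFrame(recs)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def aggregates_from_joint(joint: JointDistribution) -> CohortResult:
    """View an exact joint distribution through the CohortResult lens
    (alive mass 1, zero Monte-Carlo error)."""
    shape = joint.mass.shape
    nd = len(joint.disease_names)
    disease_prev = np.stack(
        [joint.disease_marginal(n) for n in joint.disease_names], axis=-1
    )
    return CohortResult(
        risk_states=joint.risk_states,
        disease_names=joint.disease_names,
        disease_levels=joint.disease_levels,
        alive=np.ones(shape[:2]),
        risk_marginal=joint.risk_marginal(),
        disease_prev=disease_prev,
        pair_prev=joint.pair_prevalence(),
        risk_disease=joint.risk_disease_joint(),
        full_joint=joint.mass,
        combos=joint.combos,
        meta={"source": "joint", "scenario": joint.scenario_name},
    )


# ---------------------------------------------------------------------------
# Monte-Carlo newborn cohort
# ---------------------------------------------------------------------------

def simulate_newborn_cohort(
    scenario: Scenario,
    cp: CalibratedParameters,
    schedule: TransitionSchedule,
    n_per_sex: int,
    seed: int,
    store_full_joint: bool = False,
) -> CohortResult:
    """Simulate ``n_per_sex`` disease-free newborns per sex to ``a_max``.

    Each individual gets a stochastic risk-factor biography; disease and
    survival states are deterministic probability masses given the
    biography (partial micro-simulation).  Deterministic given ``seed``;
    replicate streams should derive their own seeds (see
    :func:`replicate_seeds`).
    """
    if n_per_sex < 1:
        raise ValueError("n_per_sex must be >= 1")
    clusters = clusters_of(scenario)
    mats = [_year_matrices(c, cp) for c in clusters]
    rf = scenario.risk_factor
    nr, a_max = rf.n_states, scenario.a_max
    nd = len(scenario.diseases)
    name_loc = {}  # disease name -> (cluster index, local index)
    for ci, c in enumerate(clusters):
        for k, n in enumerate(c.disease_names):
            name_loc[n] = (ci, k)
    order = [name_loc[n] for n in scenario.disease_names]

    oc = scenario.other_cause_mortality.values  # (2, A+1)
    rr_oc = cp.rr_other_cause_array()  # (nr, 2, A+1)
    prev0 = rf.prevalence_array()[:, :, 0]  # (nr, 2)

    alive = np.zeros((2, a_max + 1))
    risk_marg = np.zeros((2, a_max + 1, nr))
    dis_prev = np.zeros((2, a_max + 1, nd))
    dis_se = np.zeros((2, a_max + 1, nd))
    pair_prev = np.zeros((2, a_max + 1, nd, nd))
    com_se = np.zeros((2, a_max + 1, nd, nd))
    risk_dis = np.zeros((2, a_max + 1, nr, nd))
    full = None
    if store_full_joint:
        combos_all = enumerate_combos(tuple(d.n_levels for d in scenario.diseases))
        full = np.zeros((2, a_max + 1, nr, combos_all.shape[0]))

    for si, sex in enumerate(SEXES):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), si]))
        paths = simulate_risk_path(schedule, sex, rng, prev0[:, si], n_per_sex)
        # other-cause survival along each path
        haz = oc[si][None, :] * np.take_along_axis(rr_oc[:, si, :], paths, axis=0)
        surv_oc = np.exp(-np.concatenate(
            [np.zeros((n_per_sex, 1)), np.cumsum(haz[:, :-1], axis=1)], axis=1
        ))
        states = [np.zeros((n_per_sex, c.n_states + 1)) for c in clusters]
        for st in states:
            st[:, 0] = 1.0

        for a in range(a_max + 1):
            alive_c = [1.0 - st[:, -1] for st in states]
            w = surv_oc[:, a] * np.prod(alive_c, axis=0)
            W = w.sum()
            alive[si, a] = W / n_per_sex
            # per-individual conditional presence probabilities
            p_ind = np.zeros((n_per_sex, nd))
            for di, (ci, k) in enumerate(order):
                sel = clusters[ci].combos[:, k] >= 1
                with np.errstate(invalid="ignore", divide="ignore"):
                    p = states[ci][:, :-1][:, sel].sum(axis=1) / alive_c[ci]
                p_ind[:, di] = np.nan_to_num(p)
            if W > 0:
                wn = w / W
                dis_prev[si, a] = wn @ p_ind
                dis_se[si, a] = np.sqrt(
                    ((wn[:, None] * (p_ind - dis_prev[si, a])) ** 2).sum(axis=0)
                )
                for r in range(nr):
                    mask = paths[:, a] == r
                    risk_marg[si, a, r] = wn[mask].sum()
                    risk_dis[si, a, r] = wn[mask] @ p_ind[mask]
                # pairwise prevalence
                p_pair = np.empty((n_per_sex, nd, nd))
                for i in range(nd):
                    for j in range(nd):
                        ci, ki = order[i]
                        cj, kj = order[j]
                        if ci == cj:
                            sel = (clusters[ci].combos[:, ki] >= 1) & (
                                clusters[ci].combos[:, kj] >= 1
                            )
                            with np.errstate(invalid="ignore", divide="ignore"):
                                pij = states[ci][:, :-1][:, sel].sum(axis=1) / alive_c[ci]
                            p_pair[:, i, j] = np.nan_to_num(pij)
                        else:
                            p_pair[:, i, j] = p_ind[:, i] * p_ind[:, j]
                pair_prev[si, a] = np.einsum("n,nij->ij", wn, p_pair)
                _comorbidity_se(
                    wn, p_ind, p_pair, dis_prev[si, a], pair_prev[si, a], com_se[si, a]
                )
                if store_full_joint:
                    _accumulate_full_joint(
                        full[si, a], wn, paths[:, a], states, alive_c, clusters,
                        order, scenario, combos_all,
                    )
            # evolve to next age: disease year with risk frozen at r(a)
            if a < a_max:
                for ci, c in enumerate(clusters):
                    for r in range(nr):
                        mask = paths[:, a] == r
                        if mask.any():
                            states[ci][mask] = states[ci][mask] @ mats[ci][si, a, r]
    return CohortResult(
        risk_states=rf.states,
        disease_names=scenario.disease_names,
        disease_levels=tuple(d.n_levels for d in scenario.diseases),
        alive=alive, risk_marginal=risk_marg, disease_prev=dis_prev,
        pair_prev=pair_prev, risk_disease=risk_dis,
        disease_prev_se=dis_se, comorbidity_se=com_se,
        full_joint=full,
        combos=enumerate_combos(tuple(d.n_levels for d in scenario.diseases))
        if store_full_joint else None,
        meta={"source": "cohort", "scenario": scenario.name,
              "n_per_sex": n_per_sex, "seed": int(seed)},
    )


def _comorbidity_se(wn, p_ind, p_pair, pa, pab, out) -> None:
    """Delta-method SE of the comorbidity ratio P_AB/(P_A*P_B) from
    per-individual influence contributions."""
    nd = p_ind.shape[1]
    for i in range(nd):
        for j in range(nd):
            if pa[i] <= 0 or pa[j] <= 0 or pab[i, j] <= 0:
                out[i, j] = 0.0
                continue
            ratio = pab[i, j] / (pa[i] * pa[j])
            infl = (
                (p_pair[:, i, j] - pab[i, j]) / (pa[i] * pa[j])
                - ratio * (p_ind[:, i] - pa[i]) / pa[i]
                - ratio * (p_ind[:, j] - pa[j]) / pa[j]
            )
            out[i, j] = np.sqrt(((wn * infl) ** 2).sum())


def _accumulate_full_joint(
    target, wn, r_at_age, states, alive_c, clusters, order, scenario, combos_all
) -> None:
    """Alive-normalized joint over (risk state x all-disease combos) via
    the product of per-cluster conditional distributions."""
    conds = []
    for ci, c in enumerate(clusters):
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = states[ci][:, :-1] / alive_c[ci][:, None]
        conds.append(np.nan_to_num(cond))
    # map all-disease combo -> per-cluster state index
    cluster_state_idx = []
    for ci, c in enumerate(clusters):
        pos = [scenario.disease_names.index(n) for n in c.disease_names]
        key = {tuple(s): k for k, s in enumerate(c.combos)}
        cluster_state_idx.append(
            np.array([key[tuple(cmb[pos])] for cmb in combos_all])
        )
    for r in range(target.shape[0]):
        mask = r_at_age == r
        if not mask.any():
            continue
        prod = np.ones((mask.sum(), combos_all.shape[0]))
        for ci in range(len(clusters)):
            prod *= conds[ci][mask][:, cluster_state_idx[ci]]
        target[r] += wn[mask] @ prod


# ---------------------------------------------------------------------------
# deterministic forward recursion (exact expectation)
# ---------------------------------------------------------------------------

def forward_expectation(
    scenario: Scenario,
    cp: CalibratedParameters,
    schedule: TransitionSchedule,
    max_states: int = 2048,
) -> CohortResult:
    """Deterministic twin of the newborn cohort.

    Evolves the full joint distribution over (risk state x all-disease
    combination, plus dead) per sex from birth, composing the exact
    year-evolution exponentials with the net-transition matrices.  Exact
    because incidence and mortality depend only on the current (r, D)
    state, so the expectation over risk paths is a linear recursion.
    """
    rf = scenario.risk_factor
    nr, a_max = rf.n_states, scenario.a_max
    nd = len(scenario.diseases)
    all_cluster = DiseaseCluster.from_scenario(scenario, scenario.disease_names)
    n_combo = all_cluster.n_states
    if nr * n_combo > max_states:
        raise ValueError(
            f"joint state space {nr}x{n_combo} exceeds max_states={max_states}; "
            f"use simulate_newborn_cohort, which factorizes by disease cluster"
        )
    combos = all_cluster.combos
    oc = scenario.other_cause_mortality.values
    rr_oc = cp.rr_other_cause_array()
    pres = combos >= 1

    alive = np.zeros((2, a_max + 1))
    risk_marg = np.zeros((2, a_max + 1, nr))
    dis_prev = np.zeros((2, a_max + 1, nd))
    pair_prev = np.zeros((2, a_max + 1, nd, nd))
    risk_dis = np.zeros((2, a_max + 1, nr, nd))
    full = np.zeros((2, a_max + 1, nr, n_combo))

    for si in range(2):
        v = np.zeros((nr, n_combo))
        v[:, 0] = rf.prevalence_array()[:, si, 0]
        dead = 0.0
        for a in range(a_max + 1):
            W = v.sum()
            if abs(W + dead - 1.0) > 1e-10:
                raise AssertionError("mass not conserved in forward recursion")
            alive[si, a] = W
            if W > 0:
                j = v / W
                full[si, a] = j
                risk_marg[si, a] = j.sum(axis=1)
                tot = j.sum(axis=0)
                for di in range(nd):
                    dis_prev[si, a, di] = tot[pres[:, di]].sum()
                    risk_dis[si, a, :, di] = j[:, pres[:, di]].sum(axis=1)
                for i in range(nd):
                    for jx in range(nd):
                        pair_prev[si, a, i, jx] = tot[pres[:, i] & pres[:, jx]].sum()
            if a < a_max:
                new_v = np.zeros_like(v)
                for r in range(nr):
                    oc_rate = oc[si, a] * rr_oc[r, si, a]
                    P = expm(_generator(all_cluster, cp, si, a, r, oc_rate))
                    x = v[r] @ P[:-1, :-1]
                    dead += float(v[r] @ P[:-1, -1])
                    new_v += schedule.matrices[si, a][r][:, None] * x[None, :]
                v = new_v
    return CohortResult(
        risk_states=rf.states,
        disease_names=scenario.disease_names,
        disease_levels=tuple(d.n_levels for d in scenario.diseases),
        alive=alive, risk_marginal=risk_marg, disease_prev=dis_prev,
        pair_prev=pair_prev, risk_disease=risk_dis,
        full_joint=full, combos=combos,
        meta={"source": "forward_expectation", "scenario": scenario.name},
    )


def replicate_seeds(master_seed: int, n_replicates: int) -> list[int]:
    """Derive one reproducible child seed per replicate from the master
    seed via a counter-based spawn: replicate k uses
    ``SeedSequence([master_seed, k])`` reduced to a 31-bit integer."""
    return [
        int(np.random.SeedSequence([int(master_seed), k]).generate_state(1)[0] % (2**31))
        for k in range(n_replicates)
    ]
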