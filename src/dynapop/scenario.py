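"""Scenario domain model: risk factor, diseases, dependency graph, validation.

A :class:`Scenario` is the full specification of one simulation setting:
a single categorical risk factor (e.g. never/current/former smoker),
a set of diseases with their hazard parameters, the one-layer causal
dependency graph between diseases (e.g. diabetes raising the incidence
of coronary heart disease), and all relative-risk tables.  All
quantities are age- and sex-specific :class:`~dynapop.ratetable.RateTable`
objects on a common integer age grid ``0..a_max``.

Three disease mortality processes are supported:

``chronic-constant``
    once acquired, the disease confers a constant (age/sex-specific)
    attributable mortality rate ``Am``.
``acutely-fatal``
    in addition to ``Am`` for survivors, incident cases face an acute
    fatality hazard with baseline rate ``M0_CF`` multiplied by the same
    relative risks as incidence.
``cured-fraction``
    incident cases split at diagnosis into a "not cured" copy carrying
    ``Am`` and a "cured" copy with zero attributable mortality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .ratetable import SEXES, RateTable, sex_index

KIND_CHRONIC = "chronic-constant"
KIND_ACUTE = "acutely-fatal"
KIND_CURED = "cured-fraction"
DISEASE_KINDS = (KIND_CHRONIC, KIND_ACUTE, KIND_CURED)

#: Default age above which sparse epidemiological inputs are held constant.
DEFAULT_CAP_AGE = 87


def cap_rates_above_age(table: RateTable, cap: int) -> RateTable:
    """Hold a rate table constant above age ``cap``.

    Disease data become sparse at very high ages, so incidence, prevalence
    and excess-mortality inputs above the cap age are kept equal to their
    value at the cap age (87 by default).  Idempotent; identity when
    ``cap == a_max``.
    """
    return table.capped(cap)


@dataclass(frozen=True)
class RiskFactor:
    """A categorical risk factor with ordered states.

    The first listed state is the reference state: all relative-risk
    tables are expressed relative to it.
    """

    name: str
    states: tuple[str, ...]
    prevalence: dict[str, RateTable]
    #: Optional relative risk of each state on other-cause mortality
    #: (all 1 when absent — the risk factor then affects mortality only
    #: through disease incidence).
    rr_other_cause: dict[str, RateTable] | None = None

    @property
    def n_states(self) -> int:
        return len(self.states)

    def prevalence_array(self) -> np.ndarray:
        """Shape ``(n_states, 2, a_max+1)`` in state order."""
        return np.stack([self.prevalence[s].values for s in self.states])

    def rr_other_cause_array(self, a_max: int) -> np.ndarray:
        if self.rr_other_cause is None:
            return np.ones((self.n_states, 2, a_max + 1))
        return np.stack([self.rr_other_cause[s].values for s in self.states])


@dataclass(frozen=True)
class Disease:
    """One disease with its hazard parameters and relative-risk tables."""

    name: str
    kind: str
    prevalence: RateTable
    incidence: RateTable  # population incidence, per person-year
    attributable_mortality: RateTable
    rr_from_risk: dict[str, RateTable]  # keyed by risk-factor state
    rr_from_causes: dict[str, RateTable] = field(default_factory=dict)
    acute_fatality: RateTable | None = None  # baseline M0_CF, acutely-fatal only
    cured_fraction: RateTable | None = None  # cured-fraction kind only

    @property
    def n_levels(self) -> int:
        """Number of within-disease states: absent/present, or
        absent/not-cured/cured for cured-fraction diseases."""
        return 3 if self.kind == KIND_CURED else 2


@dataclass(frozen=True)
class Scenario:
    """Full model specification for one simulation setting."""

    name: str
    risk_factor: RiskFactor
    diseases: tuple[Disease, ...]
    other_cause_mortality: RateTable  # baseline M0_OC
    a_max: int = 95
    cap_age: int = DEFAULT_CAP_AGE

    def disease(self, name: str) -> Disease:
        for d in self.diseases:
            if d.name == name:
                return d
        raise KeyError(name)

    @property
    def disease_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.diseases)

    def causal_graph(self) -> nx.DiGraph:
        """Directed graph with an edge cause -> effect per declared RR."""
        g = nx.DiGraph()
        g.add_nodes_from(self.disease_names)
        for d in self.diseases:
            for cause in d.rr_from_causes:
                g.add_edge(cause, d.name)
        return g

    def independent_diseases(self) -> tuple[Disease, ...]:
        return tuple(d for d in self.diseases if not d.rr_from_causes)

    def dependent_diseases(self) -> tuple[Disease, ...]:
        return tuple(d for d in self.diseases if d.rr_from_causes)

    def clusters(self) -> list[tuple[str, ...]]:
        """Dependency-connected components, each in scenario disease order."""
        und = self.causal_graph().to_undirected()
        order = {n: i for i, n in enumerate(self.disease_names)}
        comps = [tuple(sorted(c, key=order.get)) for c in nx.connected_components(und)]
        return sorted(comps, key=lambda c: order[c[0]])

    def apply_age_cap(self) -> "Scenario":
        """Hold disease prevalence/incidence/excess-mortality inputs constant
        above ``cap_age``."""
        cap = self.cap_age
        new = []
        for d in self.diseases:
            new.append(
                replace(
                    d,
                    prevalence=d.prevalence.capped(cap),
                    incidence=d.incidence.capped(cap),
                    attributable_mortality=d.attributable_mortality.capped(cap),
                    acute_fatality=None
                    if d.acute_fatality is None
                    else d.acute_fatality.capped(cap),
                )
            )
        return replace(self, diseases=tuple(new))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

_PREV_SUM_TOL = 1e-9


def _check_table(
    out: list[str], owner: str, table: RateTable | None, a_max: int,
    *, lo: float | None = 0.0, hi: float | None = None, strict_hi: bool = False,
) -> None:
    if table is None:
        return
    if table.a_max != a_max:
        out.append(f"{owner}: table '{table.name}' covers ages 0..{table.a_max}, expected 0..{a_max}")
        return
    v = table.values
    if not np.all(np.isfinite(v)):
        sex, age = _first_bad(~np.isfinite(v))
        out.append(f"{owner}: '{table.name}' non-finite at ({sex}, {age})")
        return
    if lo is not None and np.any(v < lo):
        sex, age = _first_bad(v < lo)
        out.append(f"{owner}: '{table.name}' value {v[sex_index(sex), age]:g} < {lo} at ({sex}, {age})")
    if hi is not None:
        bad = v >= hi if strict_hi else v > hi
        if np.any(bad):
            sex, age = _first_bad(bad)
            cmp = "<" if strict_hi else "<="
            out.append(
                f"{owner}: '{table.name}' value {v[sex_index(sex), age]:g} violates {cmp} {hi} at ({sex}, {age})"
            )


def _first_bad(mask: np.ndarray) -> tuple[str, int]:
    si, age = np.argwhere(mask)[0]
    return SEXES[si], int(age)


def validate_scenario(scenario: Scenario) -> list[str]:
    """Check every domain invariant; return a list of violation messages.

    An empty list means the scenario is well formed.  Each message names
    the offending field, the (sex, age) location where relevant, and the
    rule broken.  Callers should treat a non-empty result as fatal.
    """
    out: list[str] = []
    a_max = scenario.a_max
    rf = scenario.risk_factor

    if a_max < 1:
        out.append(f"scenario: a_max must be >= 1, got {a_max}")
        return out
    if scenario.cap_age > a_max:
        out.append(f"scenario: cap_age {scenario.cap_age} beyond a_max {a_max}")

    # risk factor -----------------------------------------------------
    if rf.n_states < 1:
        out.append("risk_factor: needs at least one state")
        return out
    if set(rf.prevalence) != set(rf.states):
        out.append("risk_factor: prevalence keys must match states")
        return out
    for s in rf.states:
        _check_table(out, f"risk_factor[{s}]", rf.prevalence[s], a_max, hi=1.0)
    prev = rf.prevalence_array()
    sums = prev.sum(axis=0)
    bad = np.abs(sums - 1.0) > _PREV_SUM_TOL
    if np.any(bad):
        sex, age = _first_bad(bad)
        out.append(
            f"risk_factor: state prevalences sum to {sums[sex_index(sex), age]:.12g} "
            f"at ({sex}, {age}); must sum to 1"
        )
    if rf.rr_other_cause is not None:
        if set(rf.rr_other_cause) != set(rf.states):
            out.append("risk_factor: rr_other_cause keys must match states")
        else:
            for s in rf.states:
                _check_table(out, f"risk_factor.rr_other_cause[{s}]", rf.rr_other_cause[s], a_max)
            ref = rf.rr_other_cause[rf.states[0]].values
            if np.any(ref != 1.0):
                sex, age = _first_bad(ref != 1.0)
                out.append(
                    f"risk_factor: reference state '{rf.states[0]}' must have "
                    f"other-cause RR 1 at all ages (violated at ({sex}, {age}))"
                )

    # diseases --------------------------------------------------------
    names = [d.name for d in scenario.diseases]
    if len(set(names)) != len(names):
        out.append("diseases: names must be unique")
    for d in scenario.diseases:
        who = f"disease[{d.name}]"
        if d.kind not in DISEASE_KINDS:
            out.append(f"{who}: unknown kind {d.kind!r}")
            continue
        _check_table(out, who, d.prevalence, a_max, hi=1.0, strict_hi=True)
        _check_table(out, who, d.incidence, a_max)
        _check_table(out, who, d.attributable_mortality, a_max)
        if d.kind == KIND_ACUTE:
            if d.acute_fatality is None:
                out.append(f"{who}: acutely-fatal disease needs an acute_fatality table")
            else:
                _check_table(out, who, d.acute_fatality, a_max)
        elif d.acute_fatality is not None:
            out.append(f"{who}: acute_fatality defined but kind is {d.kind}")
        if d.kind == KIND_CURED:
            if d.cured_fraction is None:
                out.append(f"{who}: cured-fraction disease needs a cured_fraction table")
            else:
                _check_table(out, who, d.cured_fraction, a_max, hi=1.0)
        elif d.cured_fraction is not None:
            out.append(f"{who}: cured_fraction defined but kind is {d.kind}")
        if set(d.rr_from_risk) != set(rf.states):
            out.append(f"{who}: rr_from_risk keys must match risk-factor states")
        else:
            for s in rf.states:
                _check_table(out, f"{who}.rr_from_risk[{s}]", d.rr_from_risk[s], a_max)
            ref = d.rr_from_risk[rf.states[0]].values
            if np.any(ref != 1.0):
                sex, age = _first_bad(ref != 1.0)
                out.append(
                    f"{who}: reference risk state '{rf.states[0]}' must have RR 1 "
                    f"at all ages (violated at ({sex}, {age}))"
                )
        for cause, table in d.rr_from_causes.items():
            if cause not in names:
                out.append(f"{who}: causal disease {cause!r} not in scenario")
            elif cause == d.name:
                out.append(f"{who}: disease cannot cause itself")
            _check_table(out, f"{who}.rr_from_causes[{cause}]", table, a_max)

    # other-cause mortality -------------------------------------------
    _check_table(out, "other_cause_mortality", scenario.other_cause_mortality, a_max)

    # dependency graph: acyclic, at most one layer deep ----------------
    g = scenario.causal_graph()
    if not nx.is_directed_acyclic_graph(g):
        out.append("diseases: causal dependency graph has a cycle")
    for d in scenario.diseases:
        if d.rr_from_causes and g.out_degree(d.name) > 0:
            out.append(
                f"disease[{d.name}]: dependency depth > 1 (has both incoming and "
                f"outgoing causal edges; only a single layer of dependent diseases "
                f"is supported)"
            )
    return out
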