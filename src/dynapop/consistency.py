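"""Consistency metrics: within-disease risk distributions, comorbidity
ratios, difference tables and replicate confidence intervals.

The validation question is whether the constructed initial population is
the one that would emerge from simulating disease-free newborns to old
age under stationary risk-factor prevalence.  Two views are compared:

* the distribution of risk-factor states *within* each disease — of the
  people with the disease, what proportion sits in each risk class;
* the comorbidity ratio ``P_AB / (P_A * P_B)`` per disease pair, which
  equals 1 under independence.

Differences are tabulated at selected report ages in percent points
(proportions) or as plain differences (ratios), with confidence
intervals of the mean over Monte-Carlo replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import CohortResult, aggregates_from_joint
from .initpop import JointDistribution, build_joint_distribution, enumerate_combos
from .ratetable import SEXES
from .scenario import KIND_CURED, Scenario

DEFAULT_REPORT_AGES = (50, 65, 75, 85)
DEFAULT_REPLICATES = 100  # replicate protocol for the confidence intervals


def _agg(res) -> CohortResult:
    if isinstance(res, JointDistribution):
        return aggregates_from_joint(res)
    return res


def risk_within_disease(res) -> pd.DataFrame:
    """Distribution of risk-factor states among the diseased.

    Returns a long table ``sex, age, disease, risk_state, proportion``
    where ``proportion`` is P(risk state | disease present, alive).
    Rows sum to 1 over risk states; cells where the disease has zero
    prevalence are NaN (undefined, never 0).
    """
    res = _agg(res)
    recs = []
    nd = len(res.disease_names)
    nr = len(res.risk_states)
    for si, sex in enumerate(SEXES):
        for a in range(res.a_max + 1):
            for di in range(nd):
                denom = res.disease_prev[si, a, di]
                for r in range(nr):
                    prop = (
                        res.risk_disease[si, a, r, di] / denom if denom > 0 else np.nan
                    )
                    recs.append((sex, a, res.disease_names[di], res.risk_states[r], prop))
    return pd.DataFrame(
        recs, columns=["sex", "age", "disease", "risk_state", "proportion"]
    )


def comorbidity_ratios(res) -> pd.DataFrame:
    """Comorbidity ratio ``P_AB/(P_A*P_B)`` per (sex, age, disease pair).

    Cells where either marginal prevalence is zero are NaN (undefined).
    """
    res = _agg(res)
    recs = []
    nd = len(res.disease_names)
    for si, sex in enumerate(SEXES):
        for a in range(res.a_max + 1):
            for i in range(nd):
                for j in range(i + 1, nd):
                    pa = res.disease_prev[si, a, i]
                    pb = res.disease_prev[si, a, j]
                    ratio = res.pair_prev[si, a, i, j] / (pa * pb) if pa * pb > 0 else np.nan
                    recs.append(
                        (sex, a, res.disease_names[i], res.disease_names[j], ratio)
                    )
    return pd.DataFrame(
        recs, columns=["sex", "age", "disease_a", "disease_b", "ratio"]
    )


def compare_populations(
    initial, cohort, report_ages=DEFAULT_REPORT_AGES
) -> pd.DataFrame:
    """Single-replicate differences (initial minus newborn cohort).

    Proportions are reported in percent points (x100); comorbidity
    ratios as plain differences.  Returns a long table with a ``block``
    column (``risk_within_disease`` / ``comorbidity``).
    """
    ini, coh = _agg(initial), _agg(cohort)
    if ini.risk_states != coh.risk_states or ini.disease_names != coh.disease_names:
        raise ValueError("mismatched strata: initial and cohort results differ")
    ages = list(report_ages)
    if max(ages) > ini.a_max:
        raise ValueError("report age beyond table range")

    rw_i = risk_within_disease(ini).rename(columns={"proportion": "initial"})
    rw_c = risk_within_disease(coh).rename(columns={"proportion": "newborn"})
    rw = rw_i.merge(rw_c, on=["sex", "age", "disease", "risk_state"])
    rw = rw[rw["age"].isin(ages)].copy()
    rw["difference"] = (rw["initial"] - rw["newborn"]) * 100.0
    rw["block"] = "risk_within_disease"
    rw["cell"] = (
        rw["sex"] + "|" + rw["age"].astype(str) + "|" + rw["disease"] + "|" + rw["risk_state"]
    )

    cm_i = comorbidity_ratios(ini).rename(columns={"ratio": "initial"})
    cm_c = comorbidity_ratios(coh).rename(columns={"ratio": "newborn"})
    cm = cm_i.merge(cm_c, on=["sex", "age", "disease_a", "disease_b"])
    cm = cm[cm["age"].isin(ages)].copy()
    cm["difference"] = cm["initial"] - cm["newborn"]
    cm["block"] = "comorbidity"
    cm["cell"] = (
        cm["sex"] + "|" + cm["age"].astype(str) + "|" + cm["disease_a"] + "&" + cm["disease_b"]
    )

    cols = ["block", "cell", "sex", "age", "initial", "newborn", "difference"]
    rw_part = rw[cols + ["disease", "risk_state"]].copy()
    rw_part[["disease_a", "disease_b"]] = pd.NA
    cm_part = cm[cols + ["disease_a", "disease_b"]].copy()
    cm_part[["disease", "risk_state"]] = pd.NA
    order = cols + ["disease", "risk_state", "disease_a", "disease_b"]
    parts = [p[order] for p in (rw_part, cm_part) if not p.empty]
    if len(parts) == 1:
        return parts[0].reset_index(drop=True)
    return pd.concat(parts, ignore_index=True)


def replicate_summary(diffs: list[pd.DataFrame], level: float = 0.95) -> pd.DataFrame:
    """Mean difference and normal-approximation CI over replicates.

    Each element of ``diffs`` is a table from :func:`compare_populations`
    for one replicate (differing only in the Monte-Carlo seed of the
    newborn cohort).  Per cell: mean, and ``mean ± z * sd / sqrt(k)``.
    """
    if len(diffs) < 2:
        raise ValueError("need at least 2 replicates for a confidence interval")
    z = stats.norm.ppf(0.5 + level / 2.0)
    k = len(diffs)
    stacked = pd.concat(diffs, ignore_index=True)
    keys = [c for c in ["block", "cell", "sex", "age", "disease", "risk_state",
                        "disease_a", "disease_b"] if c in stacked.columns]
    g = stacked.groupby(keys, dropna=False, sort=False)["difference"]
    out = g.agg(mean="mean", sd="std", n_replicates="count").reset_index()
    half = z * out["sd"] / np.sqrt(out["n_replicates"])
    out["ci_lower"] = out["mean"] - half
    out["ci_upper"] = out["mean"] + half
    out.attrs["level"] = level
    out.attrs["n_replicates"] = k
    return out


def independence_baseline(scenario: Scenario) -> JointDistribution:
    """Comparator construction that assumes full independence: the joint
    is the plain product of all marginals (risk-factor and each
    disease), with cured-fraction diseases split proportionally."""
    jd = build_joint_distribution(scenario)  # for shapes/levels
    rf = scenario.risk_factor
    w = rf.prevalence_array()  # (nr, 2, A+1)
    mass = np.transpose(w, (1, 2, 0))[:, :, :, None] * np.ones(jd.combos.shape[0])
    for i, d in enumerate(scenario.diseases):
        p = d.prevalence.values  # (2, A+1)
        lev = jd.combos[:, i]
        if d.n_levels == 3:
            cf = d.cured_fraction.values
            factor = np.where(
                lev[None, None, :] == 0, (1.0 - p)[:, :, None],
                np.where(lev[None, None, :] == 1,
                         (p * (1.0 - cf))[:, :, None], (p * cf)[:, :, None]),
            )
        else:
            factor = np.where(
                lev[None, None, :] == 0, (1.0 - p)[:, :, None], p[:, :, None]
            )
        mass = mass * factor[:, :, None, :]
    return JointDistribution(
        risk_states=jd.risk_states,
        disease_names=jd.disease_names,
        disease_levels=jd.disease_levels,
        combos=jd.combos,
        mass=mass,
        scenario_name=f"{scenario.name}|independence",
    )


def max_abs_difference(diff: pd.DataFrame, block: str | None = None) -> float:
    """Largest absolute difference in a comparison table, ignoring
    undefined cells."""
    d = diff if block is None else diff[diff["block"] == block]
    return float(np.nanmax(np.abs(d["difference"].to_numpy(dtype=float))))
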