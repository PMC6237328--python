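"""End-to-end orchestration of the consistency experiment.

Pipeline: build the exact initial joint distribution, calibrate baseline
incidence against it, estimate net transitions, run replicated newborn
cohorts with derived seeds, compute the difference tables, and summarize
with replicate confidence intervals.  The "initial" side of every
comparison is the exact joint distribution (not a sampled population),
so all Monte-Carlo error is attributable to the newborn cohorts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .consistency import (
    DEFAULT_REPLICATES,
    DEFAULT_REPORT_AGES,
    compare_populations,
    comorbidity_ratios,
    independence_baseline,
    replicate_summary,
    risk_within_disease,
)
from .engine import (
    calibrate_baseline_incidence,
    replicate_seeds,
    simulate_newborn_cohort,
)
from .initpop import build_joint_distribution
from .scenario import Scenario
from .transitions import estimate_net_transitions

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one validation run.

    ``n_per_sex`` defaults to 2000 individuals per one-year age/sex
    group for risk-factor comparisons; comorbidity-focused runs use 500.
    """

    n_per_sex: int = 2000
    replicates: int = DEFAULT_REPLICATES
    report_ages: tuple[int, ...] = DEFAULT_REPORT_AGES
    seed: int = 0
    include_oc_risk_effect: bool = False
    compare_independence: bool = True
    max_joint_states: int = 2048

    def validated(self, scenario: Scenario) -> "RunConfig":
        if self.n_per_sex < 1:
            raise ValueError("n_per_sex must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(a < 0 or a > scenario.a_max for a in self.report_ages):
            raise ValueError(f"report ages must lie in 0..{scenario.a_max}")
        return self


def validate_consistency(scenario: Scenario, config: RunConfig, out_dir=None) -> dict:
    """Run the full experiment; optionally write reports under ``out_dir``.

    Returns a dict with the replicate summary table, the per-block
    maximum absolute mean differences, and (when enabled) the same
    for the independence-baseline comparator.
    """
    config = config.validated(scenario)
    t0 = time.time()

    def stage(name):
        log.info("stage: %s (t=%.1fs)", name, time.time() - t0)

    stage("build joint distribution")
    try:
        joint = build_joint_distribution(scenario)
    except Exception as e:
        raise RuntimeError(f"stage 'build joint distribution' failed: {e}") from e

    stage("calibrate baseline incidence")
    try:
        cp = calibrate_baseline_incidence(
            scenario, joint, include_oc_risk_effect=config.include_oc_risk_effect
        )
    except Exception as e:
        raise RuntimeError(f"stage 'calibrate' failed: {e}") from e

    stage("estimate net transitions")
    try:
        schedule = estimate_net_transitions(scenario.risk_factor)
    except Exception as e:
        raise RuntimeError(f"stage 'net transitions' failed: {e}") from e

    stage(f"simulate {config.replicates} newborn cohorts")
    seeds = replicate_seeds(config.seed, config.replicates)
    diffs, diffs_indep = [], []
    indep = independence_baseline(scenario) if config.compare_independence else None
    cohorts = []
    for k, s in enumerate(seeds):
        cohort = simulate_newborn_cohort(scenario, cp, schedule, config.n_per_sex, s)
        cohorts.append(cohort)
        diffs.append(compare_populations(joint, cohort, config.report_ages))
        if indep is not None:
            diffs_indep.append(compare_populations(indep, cohort, config.report_ages))
        log.debug("replicate %d/%d done (seed %d)", k + 1, config.replicates, s)

    stage("summarize")
    result: dict = {
        "scenario": scenario.name,
        "seeds": seeds,
        "version": __version__,
        "config": asdict(config),
    }
    try:
        summary = replicate_summary(diffs)
    except Exception as e:
        raise RuntimeError(f"stage 'replicate summary' failed: {e}") from e
    result["summary"] = summary
    result["max_abs_mean_difference"] = {
        block: float(np.nanmax(np.abs(summary.loc[summary["block"] == block, "mean"])))
        for block in summary["block"].unique()
    }
    if indep is not None:
        s_ind = replicate_summary(diffs_indep)
        result["independence_max_abs_difference"] = {
            block: float(np.nanmax(np.abs(s_ind.loc[s_ind["block"] == block, "mean"])))
            for block in s_ind["block"].unique()
        }
    result["cohorts"] = cohorts
    result["joint"] = joint
    result["duration_s"] = time.time() - t0

    if out_dir is not None:
        _write_reports(result, scenario, config, Path(out_dir))
    return result


def _write_reports(result, scenario, config, out: Path) -> None:
    from .plots import plot_comorbidity, plot_risk_within_disease

    out.mkdir(parents=True, exist_ok=True)
    result["summary"].to_csv(out / "difference_report.csv", index=False)
    machine = {
        "scenario": result["scenario"],
        "version": result["version"],
        "seed": config.seed,
        "replicate_seeds": result["seeds"],
        "n_per_sex": config.n_per_sex,
        "replicates": config.replicates,
        "report_ages": list(config.report_ages),
        "max_abs_mean_difference": result["max_abs_mean_difference"],
        "duration_s": result["duration_s"],
    }
    if "independence_max_abs_difference" in result:
        machine["independence_max_abs_difference"] = result[
            "independence_max_abs_difference"
        ]
    with open(out / "summary.json", "w") as fh:
        json.dump(machine, fh, indent=2)
    # single-replicate metric tables and plots
    joint = result["joint"]
    cohort = result["cohorts"][0]
    rw_i, rw_c = risk_within_disease(joint), risk_within_disease(cohort)
    cm_i, cm_c = comorbidity_ratios(joint), comorbidity_ratios(cohort)
    rw_i.to_csv(out / "risk_within_disease_initial.csv", index=False)
    rw_c.to_csv(out / "risk_within_disease_newborn.csv", index=False)
    cm_i.to_csv(out / "comorbidity_initial.csv", index=False)
    cm_c.to_csv(out / "comorbidity_newborn.csv", index=False)
    plots = out / "plots"
    plots.mkdir(exist_ok=True)
    for d in scenario.disease_names:
        plot_risk_within_disease(rw_i, rw_c, d, plots / f"risk_within_{d}.png")
    names = scenario.disease_names
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            plot_comorbidity(cm_i, cm_c, (names[i], names[j]),
                             plots / f"comorbidity_{names[i]}_{names[j]}.png")
    log.info("reports written to %s", out)
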