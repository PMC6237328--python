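"""Scenario bundles on disk: a YAML manifest plus long-format rate CSVs.

Layout of a bundle directory::

    manifest.yaml          # states, diseases, kinds, causal edges, file paths
    rates/*.csv            # one file per quantity, columns sex,age,value

Values round-trip bit-identically (CSV floats are written with
repr-level precision).
"""

from __future__ import annotations

import logging
from pathlib import Path

import yaml

from .ratetable import RateTable
from .scenario import Disease, RiskFactor, Scenario, validate_scenario

log = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.yaml"


def _write_table(table: RateTable, rates_dir: Path, stem: str) -> str:
    path = rates_dir / f"{stem}.csv"
    table.to_frame().to_csv(path, index=False, float_format="%.17g")
    return f"rates/{stem}.csv"


def save_scenario(scenario: Scenario, out_dir) -> Path:
    """Write a scenario bundle; returns the bundle directory."""
    out = Path(out_dir)
    rates = out / "rates"
    rates.mkdir(parents=True, exist_ok=True)
    rf = scenario.risk_factor
    manifest: dict = {
        "name": scenario.name,
        "a_max": scenario.a_max,
        "cap_age": scenario.cap_age,
        "risk_factor": {
            "name": rf.name,
            "states": list(rf.states),
            "prevalence": {
                s: _write_table(rf.prevalence[s], rates, f"risk_prevalence_{s}")
                for s in rf.states
            },
        },
        "other_cause_mortality": _write_table(
            scenario.other_cause_mortality, rates, "other_cause_mortality"
        ),
        "diseases": [],
    }
    if rf.rr_other_cause is not None:
        manifest["risk_factor"]["rr_other_cause"] = {
            s: _write_table(rf.rr_other_cause[s], rates, f"rr_other_cause_{s}")
            for s in rf.states
        }
    for d in scenario.diseases:
        entry = {
            "name": d.name,
            "kind": d.kind,
            "prevalence": _write_table(d.prevalence, rates, f"{d.name}_prevalence"),
            "incidence": _write_table(d.incidence, rates, f"{d.name}_incidence"),
            "attributable_mortality": _write_table(
                d.attributable_mortality, rates, f"{d.name}_attributable_mortality"
            ),
            "rr_from_risk": {
                s: _write_table(d.rr_from_risk[s], rates, f"{d.name}_rr_risk_{s}")
                for s in rf.states
            },
        }
        if d.rr_from_causes:
            entry["rr_from_causes"] = {
                c: _write_table(t, rates, f"{d.name}_rr_cause_{c}")
                for c, t in d.rr_from_causes.items()
            }
        if d.acute_fatality is not None:
            entry["acute_fatality"] = _write_table(
                d.acute_fatality, rates, f"{d.name}_acute_fatality"
            )
        if d.cured_fraction is not None:
            entry["cured_fraction"] = _write_table(
                d.cured_fraction, rates, f"{d.name}_cured_fraction"
            )
        manifest["diseases"].append(entry)
    with open(out / MANIFEST_NAME, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    log.info("wrote scenario bundle to %s", out)
    return out


def _read_table(bundle: Path, rel: str, name: str) -> RateTable:
    path = bundle / rel
    if not path.exists():
        raise FileNotFoundError(f"scenario bundle missing rate file {rel}")
    return RateTable.read_csv(path, name=name)


def load_scenario(bundle_dir) -> Scenario:
    """Load a scenario bundle written by :func:`save_scenario`."""
    bundle = Path(bundle_dir)
    with open(bundle / MANIFEST_NAME) as fh:
        man = yaml.safe_load(fh)
    rf_m = man["risk_factor"]
    states = tuple(rf_m["states"])
    prevalence = {
        s: _read_table(bundle, rf_m["prevalence"][s], f"prev:{s}") for s in states
    }
    rr_oc = None
    if "rr_other_cause" in rf_m:
        rr_oc = {
            s: _read_table(bundle, rf_m["rr_other_cause"][s], f"rr_oc:{s}")
            for s in states
        }
    rf = RiskFactor(rf_m["name"], states, prevalence, rr_oc)
    diseases = []
    for e in man["diseases"]:
        diseases.append(
            Disease(
                name=e["name"],
                kind=e["kind"],
                prevalence=_read_table(bundle, e["prevalence"], f"prevalence:{e['name']}"),
                incidence=_read_table(bundle, e["incidence"], f"incidence:{e['name']}"),
                attributable_mortality=_read_table(
                    bundle, e["attributable_mortality"], f"am:{e['name']}"
                ),
                rr_from_risk={
                    s: _read_table(bundle, e["rr_from_risk"][s], f"rr:{e['name']}:{s}")
                    for s in states
                },
                rr_from_causes={
                    c: _read_table(bundle, rel, f"rr_cause:{e['name']}:{c}")
                    for c, rel in e.get("rr_from_causes", {}).items()
                },
                acute_fatality=_read_table(bundle, e["acute_fatality"], "acute")
                if "acute_fatality" in e else None,
                cured_fraction=_read_table(bundle, e["cured_fraction"], "cured")
                if "cured_fraction" in e else None,
            )
        )
    scenario = Scenario(
        name=man["name"],
        risk_factor=rf,
        diseases=tuple(diseases),
        other_cause_mortality=_read_table(
            bundle, man["other_cause_mortality"], "other_cause_mortality"
        ),
        a_max=int(man["a_max"]),
        cap_age=int(man["cap_age"]),
    )
    problems = validate_scenario(scenario)
    if problems:
        raise ValueError("invalid scenario bundle: " + "; ".join(problems))
    return scenario
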