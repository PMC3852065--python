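"""Scenario configuration: YAML loading/validation and packaged scenarios.

A scenario file bundles the dosing constants, the parameter catalogue
(name, unit, bounds, fixed values) and the observed objective values for one
patient group.  The packaged ``oc.yaml`` and ``bdc.yaml`` encode the study's
other-cancer and bile-duct-cancer settings; ``load_scenario("oc")`` /
``load_scenario("bdc")`` return them as typed objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .pbpk import DosingConfig
from .space import ConfigurationError, ObjectiveSpec, ParameterSpace

__all__ = ["Scenario", "load_scenario", "dump_scenario"]

_TOP_KEYS = {"schema_version", "group", "dosing", "parameters", "objectives"}
_DOSING_KEYS = {"dose", "infusion_duration", "q_liver", "v_liver", "t_end",
                "n_bile_transit"}
_PARAM_KEYS = {"id", "name", "unit", "min", "max", "fixed", "value"}
_OBJ_KEYS = {"id", "name", "value", "unit", "weight"}


@dataclass
class Scenario:
    """Typed scenario: patient group, parameter space, targets, dosing."""

    group: str
    space: ParameterSpace
    objectives: ObjectiveSpec
    dosing: DosingConfig

    def to_dict(self) -> dict:
        params = []
        for i, name in enumerate(self.space.names):
            entry = {"id": i + 1, "name": name, "unit": self.space.units[i],
                     "min": float(self.space.lower[i]),
                     "max": float(self.space.upper[i])}
            if self.space.fixed_mask[i]:
                entry["fixed"] = True
                entry["value"] = float(self.space.fixed_values[i])
            params.append(entry)
        objs = [{"id": j + 1, "name": n, "value": float(v), "unit": "ug/kg"}
                for j, (n, v) in enumerate(zip(self.objectives.names,
                                               self.objectives.observed))]
        d = self.dosing
        return {"schema_version": 1, "group": self.group,
                "dosing": {"dose": d.dose,
                           "infusion_duration": d.infusion_duration,
                           "q_liver": d.q_liver, "v_liver": d.v_liver,
                           "t_end": d.t_end,
                           "n_bile_transit": d.n_bile_transit},
                "parameters": params, "objectives": objs}


def _reject_unknown(mapping: dict, allowed: set, where: str):
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigurationError(
            f"{where}: unknown key(s) {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}")


def _parse(doc: dict, origin: str) -> Scenario:
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{origin}: top level must be a mapping")
    _reject_unknown(doc, _TOP_KEYS, origin)
    for key in ("group", "parameters", "objectives"):
        if key not in doc:
            raise ConfigurationError(f"{origin}: missing required key {key!r}")
    group = str(doc["group"]).upper()
    dosing_raw = doc.get("dosing", {}) or {}
    _reject_unknown(dosing_raw, _DOSING_KEYS, f"{origin}: dosing")
    dosing = DosingConfig(group=group, **dosing_raw)

    names, units, lower, upper, fmask, fvals = [], [], [], [], [], []
    for k, p in enumerate(doc["parameters"]):
        where = f"{origin}: parameters[{k}]"
        _reject_unknown(p, _PARAM_KEYS, where)
        if "name" not in p:
            raise ConfigurationError(f"{where}: missing 'name'")
        names.append(str(p["name"]))
        units.append(str(p.get("unit", "-")))
        fixed = bool(p.get("fixed", False))
        lo, hi = float(p.get("min", np.nan)), float(p.get("max", np.nan))
        if not fixed and not (0.0 < lo < hi):
            raise ConfigurationError(
                f"{where} ({p['name']}): requires 0 < min < max, "
                f"got min={p.get('min')}, max={p.get('max')}")
        lower.append(lo)
        upper.append(hi)
        fmask.append(fixed)
        if fixed:
            if "value" not in p:
                raise ConfigurationError(f"{where} ({p['name']}): fixed "
                                         "parameter needs 'value'")
            fvals.append(float(p["value"]))
        else:
            fvals.append(np.nan)
    space = ParameterSpace(names, lower, upper, units=units,
                           fixed_mask=np.array(fmask),
                           fixed_values=np.array(fvals))

    onames, ovals, oweights = [], [], []
    for k, o in enumerate(doc["objectives"]):
        where = f"{origin}: objectives[{k}]"
        _reject_unknown(o, _OBJ_KEYS, where)
        for key in ("name", "value"):
            if key not in o:
                raise ConfigurationError(f"{where}: missing {key!r}")
        onames.append(str(o["name"]))
        ovals.append(float(o["value"]))
        oweights.append(float(o.get("weight", 1.0)))
    spec = ObjectiveSpec(onames, np.array(ovals), weights=np.array(oweights))
    return Scenario(group=group, space=space, objectives=spec, dosing=dosing)


def load_scenario(source) -> Scenario:
    """Load a scenario from a packaged name ("oc"/"bdc") or a YAML path."""
    name = str(source).lower()
    if name in ("oc", "bdc"):
        text = (resources.files("clusternewton") / "data" /
                f"{name}.yaml").read_text()
        return _parse(yaml.safe_load(text), f"builtin:{name}")
    path = Path(source)
    if not path.exists():
        raise ConfigurationError(f"scenario file not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _parse(doc, str(path))


def dump_scenario(scenario: Scenario, path) -> Path:
    """Write a scenario back to YAML (round-trips through load_scenario)."""
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(scenario.to_dict(), fh, sort_keys=False)
    return path
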