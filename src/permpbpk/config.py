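"""Run configuration: flat YAML overriding the built-in study defaults.

A configuration file has up to five sections, each optional; the defaults
reproduce the study's physiology, parameter tables and design exactly.

.. code-block:: yaml

    physiology:            # GestationalPhysiology field overrides
      n_fetuses: 12
    chemical:
      mode: gd15_20        # which posterior-mean set seeds the parameters
      cis:                 # per-isomer value overrides
        cl_liv: 2.4
    schedule:              # DoseSchedule overrides
      dose_per_kg: 50.0
    design:                # StudyDesign overrides (n_per_group, times, ...)
      n_per_group: 4
    solver:
      rtol: 1.0e-8
      atol: 1.0e-10
      output_dt: 0.25      # h
    seed: 0

Unknown keys anywhere are rejected with an error naming the key; chemical
overrides are checked against their prior bounds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .parameters import PRIORS, ChemicalParams, posterior_mean_params
from .physiology import GestationalPhysiology
from .simulate import DoseSchedule
from .study import StudyDesign

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid run configuration (names the offending key)."""


_SECTIONS = ("physiology", "chemical", "schedule", "design", "solver", "seed")
_SOLVER_KEYS = {"rtol": 1e-8, "atol": 1e-10, "output_dt": 0.25}


def _check_keys(section: str, given: Mapping[str, Any], allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {section!r}; "
            f"allowed: {sorted(allowed)}"
        )


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration; defaults reproduce the study tables."""

    physiology_overrides: Mapping[str, Any] = field(default_factory=dict)
    chemical_mode: str = "gd15_20"
    chemical_overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    schedule_overrides: Mapping[str, Any] = field(default_factory=dict)
    design_overrides: Mapping[str, Any] = field(default_factory=dict)
    solver: Mapping[str, float] = field(default_factory=lambda: dict(_SOLVER_KEYS))
    seed: int = 0

    def physiology(self) -> GestationalPhysiology:
        return GestationalPhysiology(**self.physiology_overrides)

    def chem(self, isomer: str) -> ChemicalParams:
        base = posterior_mean_params(isomer, self.chemical_mode)
        overrides = dict(self.chemical_overrides.get(isomer, {}))
        for name, value in overrides.items():
            spec = PRIORS[isomer].get(name)
            if spec is not None and spec.family != "fixed":
                if not (spec.lower <= value <= spec.upper):
                    raise ConfigError(
                        f"chemical.{isomer}.{name} = {value} outside its prior "
                        f"bounds [{spec.lower}, {spec.upper}]"
                    )
        return base.with_values(**overrides)

    def schedule(self, isomer: str = "cis", gd: int | None = None) -> DoseSchedule:
        kw = dict(self.schedule_overrides)
        kw.setdefault("isomer_fraction", 0.40 if isomer == "cis" else 0.60)
        if "times" in kw:
            kw["times"] = tuple(float(t) for t in kw["times"])
        elif gd is not None:
            kw["times"] = tuple(float(d) for d in range(1, gd + 1))
        return DoseSchedule(**kw)

    def design(self) -> StudyDesign:
        kw = dict(self.design_overrides)
        for key in ("gestational_days", "sample_times", "feces_days"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return StudyDesign(**kw)


def load_config(path: str | Path | None) -> RunConfig:
    """Parse and validate a YAML run configuration (None -> all defaults)."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    _check_keys("<root>", raw, set(_SECTIONS))

    phys_fields = {f.name for f in dataclasses.fields(GestationalPhysiology)}
    phys = raw.get("physiology", {}) or {}
    _check_keys("physiology", phys, phys_fields)

    chem = dict(raw.get("chemical", {}) or {})
    mode = chem.pop("mode", "gd15_20")
    if mode not in ("gd1", "gd15_20"):
        raise ConfigError(f"chemical.mode must be 'gd1' or 'gd15_20', got {mode!r}")
    _check_keys("chemical", chem, {"cis", "trans"})
    chem_fields = {f.name for f in dataclasses.fields(ChemicalParams)}
    for iso, over in chem.items():
        _check_keys(f"chemical.{iso}", over or {}, chem_fields)

    sched_fields = {f.name for f in dataclasses.fields(DoseSchedule)}
    sched = raw.get("schedule", {}) or {}
    _check_keys("schedule", sched, sched_fields)

    design_fields = {f.name for f in dataclasses.fields(StudyDesign)} - {"dose_schedule"}
    design = raw.get("design", {}) or {}
    _check_keys("design", design, design_fields)

    solver = dict(_SOLVER_KEYS)
    given_solver = raw.get("solver", {}) or {}
    _check_keys("solver", given_solver, set(_SOLVER_KEYS))
    solver.update(given_solver)

    cfg = RunConfig(
        physiology_overrides=phys,
        chemical_mode=mode,
        chemical_overrides={k: dict(v or {}) for k, v in chem.items()},
        schedule_overrides=sched,
        design_overrides=design,
        solver=solver,
        seed=int(raw.get("seed", 0)),
    )
    # eager validation of every section
    cfg.physiology()
    for iso in ("cis", "trans"):
        cfg.chem(iso)
    cfg.schedule()
    cfg.design()
    return cfg
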