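"""Censoring-aware synthetic toxicokinetic studies.

The in-vivo study design: pregnant rats gavaged daily with 50 mg/kg
permethrin (40:60 cis/trans) from GD1, groups of four sacrificed at 1, 2,
3, 4, 6, 10 and 24 h after the dose on GD1, GD15 or GD20 (destructive
sampling — each animal yields one time point).  Feces were collected over
24 h in metabolic cages at GD1 and GD15; placenta from GD15; fetal blood,
liver and brain (litter-pooled) at GD20.

The generator simulates the true model through the full dosing history,
perturbs each record with multiplicative lognormal measurement error (the
sole stochastic term, matching the calibration likelihood) and applies
matrix-specific limit-of-quantification censoring with the study's LOQ/2
substitution.  Latent values below ``loq x not_detected_fraction`` are
flagged not-detected and carry no value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import ChemicalParams
from .physiology import GestationalPhysiology
from .simulate import DoseSchedule, run
from .studydata import LOQ_MG_PER_L

__all__ = ["StudyDesign", "TKDataset", "generate_study", "CENSOR_STATES"]

CENSOR_STATES = ("quantified", "below_loq_detected", "not_detected")

_BASE_MATRICES = ("blood", "liver", "brain", "kidney", "fat", "mammary")

#: nominal fecal mass excreted per 24 h (g), used to express the per-gram
#: feces LOQ as an amount threshold for the cumulative feces records
FECAL_MASS_G = 10.0


@dataclass(frozen=True)
class StudyDesign:
    """Design of a (real or synthetic) gestational toxicokinetic study."""

    gestational_days: tuple[int, ...] = (1, 15, 20)
    sample_times: tuple[float, ...] = (1, 2, 3, 4, 6, 10, 24)
    n_per_group: int = 4
    feces_days: tuple[int, ...] = (1, 15)
    dose_schedule: DoseSchedule = field(default_factory=DoseSchedule)
    loq_table: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(LOQ_MG_PER_L)
    )
    #: latent values below loq x this fraction are reported not-detected
    not_detected_fraction: float = 0.1

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.loq_table.values()):
            raise ValueError("LOQs must be positive")
        if any(not 0 <= t <= 24 for t in self.sample_times):
            raise ValueError("sample times must lie within 0-24 h post-dose")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")

    def matrices_for(self, gd: int) -> tuple[str, ...]:
        mats = list(_BASE_MATRICES)
        if gd in self.feces_days:
            mats.append("feces")
        if gd >= 15:
            mats.append("placenta")
        if gd >= 20:
            mats += ["fetal_blood", "fetal_liver", "fetal_brain"]
        return tuple(mats)

    def loq(self, isomer: str, matrix: str) -> float:
        loq = self.loq_table[(isomer, matrix)]
        if matrix == "feces":
            # per-gram LOQ (ug/g) -> amount threshold (mg) over a 24-h collection
            return loq * FECAL_MASS_G / 1000.0
        return loq


_COLUMNS = ["gd", "time_h", "matrix", "isomer", "animal_id", "concentration", "censor", "loq"]


@dataclass
class TKDataset:
    """Censoring-aware concentration records of a toxicokinetic study.

    One row per (animal, matrix, isomer): gestational day of sacrifice,
    time post-dose (h), concentration in mg/L (feces: cumulative mg over
    24 h), censor state and the applicable LOQ.  Below-LOQ-detected rows
    carry the LOQ/2-substituted value; not-detected rows carry NaN.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"dataset is missing columns {missing}")
        bad = set(self.records["censor"]) - set(CENSOR_STATES)
        if bad:
            raise ValueError(f"unknown censor states {sorted(bad)}")
        q = self.records[self.records["censor"] == "quantified"]
        if len(q) and (q["concentration"] < q["loq"] - 1e-12).any():
            raise ValueError("quantified records must be >= their LOQ")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, gds: Iterable[int] | None = None, isomer: str | None = None) -> "TKDataset":
        df = self.records
        if gds is not None:
            df = df[df["gd"].isin(list(gds))]
        if isomer is not None:
            df = df[df["isomer"] == isomer]
        return TKDataset(df.reset_index(drop=True))

    @property
    def usable(self) -> pd.DataFrame:
        """Rows entering a likelihood: quantified + LOQ/2-substituted."""
        return self.records[self.records["censor"] != "not_detected"]

    def write_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path: str | Path) -> "TKDataset":
        df = pd.read_csv(path)
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        bad = df.index[~df["censor"].isin(CENSOR_STATES)]
        if len(bad):
            # +2: header line and 1-based numbering
            raise ValueError(
                f"{path}: unknown censor state {df.loc[bad[0], 'censor']!r} on line {bad[0] + 2}"
            )
        return cls(df)


def _predict_group(
    chem: ChemicalParams,
    phys: GestationalPhysiology,
    design: StudyDesign,
    gd: int,
    rtol: float = 1e-8,
) -> dict[str, dict[float, float]]:
    """Model predictions {matrix: {time_h_post_dose: value}} for one group."""
    sched = replace(design.dose_schedule, times=tuple(float(d) for d in range(1, gd + 1)))
    res = run(chem, phys, sched, t_end=gd + 24.0 / 24.0, output_dt=0.25, rtol=rtol)
    t_dose_h = gd * 24.0
    out: dict[str, dict[float, float]] = {}
    for mat in design.matrices_for(gd):
        if mat == "feces":
            base = res.amount_at(t_dose_h, "a_feces")
            out[mat] = {24.0: res.amount_at(t_dose_h + 24.0, "a_feces") - base}
            continue
        out[mat] = {
            float(tt): res.concentration_at(t_dose_h + tt, mat) for tt in design.sample_times
        }
    return out


def generate_study(
    true_params: Mapping[str, ChemicalParams],
    phys: GestationalPhysiology,
    design: StudyDesign | None = None,
    sigma_log: float = 0.15,
    seed: int = 0,
    gestational_days: Sequence[int] | None = None,
) -> TKDataset:
    """Simulate a full synthetic study from known ("true") parameters.

    ``true_params`` maps isomer name -> ChemicalParams; each requested
    isomer/GD group is simulated through its complete dosing history, read
    at the design's sampling times and perturbed record-wise with
    ``exp(eps)``, ``eps ~ Normal(0, sigma_log^2)``.  Deterministic for a
    fixed seed.
    """
    if sigma_log < 0:
        raise ValueError("sigma_log must be >= 0")
    design = design or StudyDesign()
    gds = tuple(gestational_days) if gestational_days is not None else design.gestational_days
    unknown = set(gds) - set(design.gestational_days)
    if unknown:
        raise ValueError(f"gestational days {sorted(unknown)} not part of the design")
    rng = np.random.default_rng(seed)
    rows = []
    for isomer, chem in sorted(true_params.items()):
        frac = 0.40 if isomer == "cis" else 0.60
        d = replace(design, dose_schedule=replace(design.dose_schedule, isomer_fraction=frac))
        for gd in gds:
            preds = _predict_group(chem, phys, d, gd)
            for mat in d.matrices_for(gd):
                loq = d.loq(isomer, mat)
                # guard inf * 0 when detection is unconditional
                nd_threshold = loq * d.not_detected_fraction if d.not_detected_fraction else 0.0
                for t_h, pred in preds[mat].items():
                    n_rep = 1 if mat == "feces" else d.n_per_group
                    for rep in range(n_rep):
                        latent = pred * float(np.exp(rng.normal(0.0, sigma_log))) if sigma_log > 0 else pred
                        if latent >= loq:
                            value, state = latent, "quantified"
                        elif latent >= nd_threshold:
                            value, state = loq / 2.0, "below_loq_detected"
                        else:
                            value, state = np.nan, "not_detected"
                        rows.append(
                            {
                                "gd": gd,
                                "time_h": t_h,
                                "matrix": mat,
                                "isomer": isomer,
                                "animal_id": f"gd{gd}_t{t_h:g}_a{rep + 1}",
                                "concentration": value,
                                "censor": state,
                                "loq": loq,
                            }
                        )
    return TKDataset(pd.DataFrame(rows, columns=_COLUMNS))
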