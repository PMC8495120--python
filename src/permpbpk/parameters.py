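"""Chemical-specific parameters of the permethrin pregnancy PBPK model.

One :class:`ChemicalParams` instance holds the full parameter vector for one
isomer (cis or trans): tissue:blood partition coefficients (PC, unitless),
permeability coefficients (PS, L/h), gastro-intestinal rate constants (1/h),
metabolic clearances (L/h/kg body weight), allometrically scaled placental
transfer constants (L/h/kg^0.75) and the fetal partition/permeability set.

The module also ships the study's prior specification (truncated normals
with CV 50% where an adult-rat value exists, uniforms elsewhere, fixed
values where the parameter was not estimated) and the posterior-mean
parameter sets of the two separate calibrations: GD1 (single dose,
essentially non-pregnant physiology) and GD15/20 (repeated dosing during
late gestation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Literal

import numpy as np
from scipy import stats

__all__ = [
    "ChemicalParams",
    "PriorSpec",
    "PRIORS",
    "posterior_mean_params",
    "prior_mean_params",
    "GSA_PARAMS",
    "GD1_ESTIMATED",
    "GD15_20_MATERNAL_ESTIMATED",
    "SHARED_FETAL_ESTIMATED",
]

Isomer = Literal["cis", "trans"]
Mode = Literal["gd1", "gd15_20"]


@dataclass(frozen=True)
class ChemicalParams:
    """Full chemical parameter vector for one permethrin isomer."""

    # maternal partition coefficients (tissue:blood, unitless)
    pc_liv: float
    pc_fat: float
    pc_mam: float
    pc_musc: float
    pc_brain: float
    pc_kid: float
    pc_pla: float
    pc_sp: float
    pc_rp: float
    # maternal permeability coefficients (L/h)
    ps_brain: float
    ps_kid: float
    ps_fat: float
    ps_mam: float
    ps_musc: float
    ps_sp: float
    # gastro-intestinal rate constants (1/h)
    k_si: float  # stomach -> intestinal lumen transfer
    k_ai: float  # intestinal absorption into GI tissue
    k_fec: float  # fecal excretion from the lumen
    # metabolic clearances (L/h/kg BW)
    cl_gi: float
    cl_blood: float
    cl_liv: float
    # placental transfer constants (L/h/kg^0.75, scaled by maternal BW^0.75)
    sc_ktrans1: float  # dam -> fetus
    sc_ktrans2: float  # fetus -> dam
    # fetal parameters
    pc_liv_f: float
    pc_brain_f: float
    pc_rb_f: float
    ps_brain_f: float  # L/h

    @property
    def pc_gi(self) -> float:
        """GI:blood partition coefficient, tied to the kidney value."""
        return self.pc_kid

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and v > 0 and math.isfinite(v)):
                raise ValueError(f"chemical parameter {f.name!r} must be finite and > 0, got {v!r}")

    def with_values(self, **updates: float) -> "ChemicalParams":
        return replace(self, **updates)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class PriorSpec:
    """Prior of one chemical parameter.

    family: 'truncnorm' (mean, sd, bounds), 'uniform' (bounds only) or
    'fixed' (parameter not sampled).
    """

    family: Literal["truncnorm", "uniform", "fixed"]
    mean: float | None = None
    sd: float | None = None
    lower: float | None = None
    upper: float | None = None
    value: float | None = None

    def __post_init__(self) -> None:
        if self.family == "fixed":
            if self.value is None:
                raise ValueError("fixed prior needs a value")
            return
        if self.lower is None or self.upper is None or not self.lower < self.upper:
            raise ValueError("sampled prior needs ordered finite bounds")
        if self.family == "truncnorm" and (self.mean is None or self.sd is None or self.sd <= 0):
            raise ValueError("truncated-normal prior needs mean and sd > 0")

    def frozen_dist(self):
        """The scipy frozen distribution (sampled priors only; cached)."""
        cached = getattr(self, "_dist", None)
        if cached is not None:
            return cached
        if self.family == "uniform":
            dist = stats.uniform(self.lower, self.upper - self.lower)
        elif self.family == "truncnorm":
            a = (self.lower - self.mean) / self.sd
            b = (self.upper - self.mean) / self.sd
            dist = stats.truncnorm(a, b, loc=self.mean, scale=self.sd)
        else:
            raise ValueError("fixed parameters have no sampling distribution")
        object.__setattr__(self, "_dist", dist)
        return dist

    def logpdf(self, x: float) -> float:
        """Analytic log prior density; -inf outside the bounds."""
        if self.family == "fixed":
            raise ValueError("fixed parameters have no prior density")
        if not (self.lower <= x <= self.upper):
            return -np.inf
        if self.family == "uniform":
            return -math.log(self.upper - self.lower)
        const = getattr(self, "_tn_const", None)
        if const is None:
            a = (self.lower - self.mean) / self.sd
            b = (self.upper - self.mean) / self.sd
            z = stats.norm.cdf(b) - stats.norm.cdf(a)
            const = -math.log(self.sd) - 0.5 * math.log(2 * math.pi) - math.log(z)
            object.__setattr__(self, "_tn_const", const)
        return const - 0.5 * ((x - self.mean) / self.sd) ** 2

    def sample(self, rng: np.random.Generator, size: int | None = None):
        d = self.frozen_dist()
        return d.rvs(size=size, random_state=rng)

    @property
    def central(self) -> float:
        """A representative central value (fixed value, mean, or interval midpoint)."""
        if self.family == "fixed":
            return self.value
        if self.family == "truncnorm":
            return self.mean
        return math.sqrt(self.lower * self.upper) if self.lower > 0 else 0.5 * (self.lower + self.upper)


def _tn(mean: float, sd: float, lo: float, hi: float) -> PriorSpec:
    return PriorSpec("truncnorm", mean=mean, sd=sd, lower=lo, upper=hi)


def _u(lo: float, hi: float) -> PriorSpec:
    return PriorSpec("uniform", lower=lo, upper=hi)


def _fx(v: float) -> PriorSpec:
    return PriorSpec("fixed", value=v)


# Prior specification per isomer.  pc_gi is tied to pc_kid and has no prior
# of its own.  Truncated normals carry a CV of 50% (one printed exception in
# the slowly perfused permeability, kept as printed).
PRIORS: dict[str, dict[str, PriorSpec]] = {
    "cis": {
        "pc_liv": _tn(0.89, 0.445, 1e-3, 20),
        "pc_fat": _tn(225, 112.5, 5, 900),
        "pc_mam": _tn(225, 112.5, 5, 900),
        "pc_musc": _fx(1.2),
        "pc_brain": _tn(1.60, 0.80, 1e-3, 20),
        "pc_kid": _tn(1.10, 0.55, 1e-3, 20),
        "pc_pla": _u(1e-3, 20),
        "pc_sp": _tn(19, 9.50, 1e-3, 20),
        "pc_rp": _fx(1.1),
        "ps_brain": _tn(1.0e-3, 0.5e-3, 1e-5, 1),
        "ps_kid": _u(1e-5, 1),
        "ps_fat": _tn(4.8e-2, 2.4e-2, 1e-5, 1),
        "ps_mam": _u(1e-5, 1),
        "ps_musc": _fx(0.32),
        "ps_sp": _tn(0.31, 0.055, 1e-5, 1),
        "k_si": _tn(0.35, 0.175, 0, 2),
        "k_ai": _fx(0.52),
        "k_fec": _tn(0.39, 0.195, 0, 2),
        "cl_gi": _fx(0.04),
        "cl_blood": _fx(0.07),
        "cl_liv": _tn(6.20, 3.10, 1, 15),
        "sc_ktrans1": _u(0, 6),
        "sc_ktrans2": _u(0, 6),
        "pc_liv_f": _u(1e-3, 20),
        "pc_brain_f": _u(1e-3, 20),
        "pc_rb_f": _u(1e-3, 900),
        "ps_brain_f": _u(1e-5, 1),
    },
    "trans": {
        "pc_liv": _u(1e-3, 20),
        "pc_fat": _tn(76, 38, 5, 900),
        "pc_mam": _tn(76, 38, 5, 900),
        "pc_musc": _fx(0.82),
        "pc_brain": _tn(0.57, 0.285, 1e-3, 20),
        "pc_kid": _fx(0.21),
        "pc_pla": _u(1e-3, 20),
        "pc_sp": _tn(8.4, 4.20, 1e-3, 20),
        "pc_rp": _fx(0.21),
        "ps_brain": _tn(1.2e-3, 0.6e-3, 1e-5, 1),
        "ps_kid": _u(1e-5, 1),
        "ps_fat": _tn(0.11, 0.055, 1e-5, 1),
        "ps_mam": _u(1e-5, 1),
        "ps_musc": _fx(0.48),
        "ps_sp": _tn(0.065, 0.032, 1e-5, 1),
        "k_si": _tn(0.20, 0.10, 0, 2),
        "k_ai": _fx(1.30),
        "k_fec": _tn(0.85, 0.42, 0, 2),
        "cl_gi": _fx(0.3),
        "cl_blood": _fx(0.29),
        "cl_liv": _tn(24.30, 12.15, 1, 50),
        "sc_ktrans1": _u(0, 6),
        "sc_ktrans2": _u(0, 6),
        "pc_liv_f": _u(1e-3, 20),
        "pc_brain_f": _u(1e-3, 20),
        "pc_rb_f": _u(1e-3, 900),
        "ps_brain_f": _u(1e-5, 1),
    },
}

# Posterior means of the two separate calibrations.  Placental/fetal
# parameters were only informed by late-gestation data and are shared across
# isomers; GD1 sets carry them too (the conceptus is inactive at GD1).
_SHARED_FETAL = {
    "sc_ktrans1": 1.91,
    "sc_ktrans2": 2.52,
    "pc_liv_f": 5.41,
    "pc_brain_f": 2.01,
    "pc_rb_f": 57.20,
    "ps_brain_f": 7.9e-3,
}

_POSTERIOR_MEANS: dict[tuple[str, str], dict[str, float]] = {
    ("cis", "gd1"): {
        "pc_liv": 2.33,
        "pc_fat": 345,
        "pc_mam": 212,
        "pc_brain": 2.67,
        "pc_kid": 5.61,
        "pc_pla": 3.52,
        "pc_sp": 14.7,
        "ps_brain": 5.6e-3,
        "ps_kid": 1.3e-2,
        "ps_fat": 0.10,
        "ps_mam": 0.252,
        "ps_sp": 0.20,
        "k_si": 0.15,
        "k_fec": 0.07,
        "cl_liv": 8.44,
        **_SHARED_FETAL,
    },
    ("cis", "gd15_20"): {
        "pc_liv": 1.48,
        "pc_fat": 545,
        "pc_mam": 436,
        "pc_brain": 1.15,
        "pc_kid": 3.00,
        "pc_pla": 3.52,
        "pc_sp": 4.55,
        "ps_brain": 3.5e-3,
        "ps_kid": 0.24,
        "ps_fat": 4.5e-2,
        "ps_mam": 0.125,
        "ps_sp": 0.79,
        "k_si": 0.18,
        "k_fec": 0.020,
        "cl_liv": 2.40,
        **_SHARED_FETAL,
    },
    # the trans GD1 calibration left the liver and placenta partition
    # coefficients uninformed; the late-gestation values stand in
    ("trans", "gd1"): {
        "pc_liv": 1.36,
        "pc_fat": 60.5,
        "pc_mam": 5.09,
        "pc_brain": 0.72,
        "pc_pla": 3.00,
        "pc_sp": 9.5,
        "ps_brain": 1.6e-3,
        "ps_kid": 1.3e-2,
        "ps_fat": 0.07,
        "ps_mam": 0.522,
        "ps_sp": 0.07,
        "k_si": 0.058,
        "k_fec": 0.09,
        "cl_liv": 19.4,
        **_SHARED_FETAL,
    },
    ("trans", "gd15_20"): {
        "pc_liv": 1.36,
        "pc_fat": 165,
        "pc_mam": 46.7,
        "pc_brain": 0.64,
        "pc_pla": 3.00,
        "pc_sp": 1.55,
        "ps_brain": 2.2e-3,
        "ps_kid": 0.24,
        "ps_fat": 9.2e-3,
        "ps_mam": 0.253,
        "ps_sp": 0.11,
        "k_si": 0.084,
        "k_fec": 0.033,
        "cl_liv": 20.5,
        **_SHARED_FETAL,
    },
}

#: parameters estimated by the GD1 (maternal-only) calibration, per isomer
GD1_ESTIMATED: dict[str, tuple[str, ...]] = {
    "cis": (
        "pc_liv", "pc_fat", "pc_mam", "pc_brain", "pc_kid", "pc_sp",
        "ps_brain", "ps_kid", "ps_fat", "ps_mam", "ps_sp",
        "k_si", "k_fec", "cl_liv",
    ),
    "trans": (
        "pc_liv", "pc_fat", "pc_mam", "pc_brain", "pc_sp",
        "ps_brain", "ps_kid", "ps_fat", "ps_mam", "ps_sp",
        "k_si", "k_fec", "cl_liv",
    ),
}

#: maternal parameters estimated by the GD15/20 calibration (adds placenta)
GD15_20_MATERNAL_ESTIMATED: dict[str, tuple[str, ...]] = {
    iso: GD1_ESTIMATED[iso] + ("pc_pla",) for iso in ("cis", "trans")
}

#: placental-transfer and fetal parameters, shared across isomers
SHARED_FETAL_ESTIMATED: tuple[str, ...] = (
    "sc_ktrans1", "sc_ktrans2", "pc_liv_f", "pc_brain_f", "pc_rb_f", "ps_brain_f",
)

#: parameter set perturbed by the global sensitivity analysis (cis, late gestation)
GSA_PARAMS: tuple[str, ...] = GD15_20_MATERNAL_ESTIMATED["cis"] + SHARED_FETAL_ESTIMATED


def _fixed_values(isomer: str) -> dict[str, float]:
    return {k: p.value for k, p in PRIORS[isomer].items() if p.family == "fixed"}


def posterior_mean_params(isomer: Isomer, mode: Mode = "gd15_20") -> ChemicalParams:
    """The posterior-mean :class:`ChemicalParams` of one calibration."""
    vals = dict(_POSTERIOR_MEANS[(isomer, mode)])
    vals.update(_fixed_values(isomer))
    if isomer == "trans":
        vals["pc_kid"] = PRIORS["trans"]["pc_kid"].value
    return ChemicalParams(**vals)


def prior_mean_params(isomer: Isomer) -> ChemicalParams:
    """Central prior values (fixed values, TN means, log-mid of uniforms)."""
    vals = {k: p.central for k, p in PRIORS[isomer].items()}
    # guard the zero-lower-bound uniforms/TNs: central of U(0, b) is b/2 > 0
    for k, v in vals.items():
        if v <= 0:
            vals[k] = PRIORS[isomer][k].upper / 2
    return ChemicalParams(**vals)
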