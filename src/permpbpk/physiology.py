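"""Gestational physiology of the pregnant Sprague-Dawley rat.

All physiological inputs of the pregnancy PBPK model live here: maternal
body weight and cardiac output over gestation, constant-fraction tissue
volumes and blood flows, the gestation-varying tissues (mammary gland, fat,
placenta), and the growth of the fetal litter (modelled as one lumped
litter).

Conventions
-----------
* Time is measured in gestational days (GD), GD0 = day of the positive
  vaginal smear; the valid domain is [0, 20].
* Volumes are litres (tissue density 1 g/ml), flows L/h, body weight kg.
* Constant-fraction tissue volumes are fractions of the *initial* body
  weight and constant-fraction flows are fractions of the *initial* cardiac
  output: those tissues do not grow during gestation.  Only the tissues
  with printed gestational ranges (mammary, fat, placenta, fetal tissues)
  change with time.
* The conceptus (placenta + fetuses) activates at implantation
  (``conceptus_onset``, default GD6); before onset its volumes and flows
  are exactly zero.  Placental and fetal growth follows a logistic curve
  anchored at (onset, 0) and (GD20, endpoint) with midpoint GD15,
  reflecting the exponential growth of placental and conceptus weight over
  the last week of gestation.  Maternal body weight is piecewise-linear
  through (GD0, 0.277), (GD15, 0.356), (GD20, 0.422) kg; the cardiac output
  index and the fat/mammary volumes and flows interpolate linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.special import expit

__all__ = [
    "GestationalPhysiology",
    "FetalPhysiology",
    "DIFFUSION_LIMITED_TISSUES",
    "FLOW_LIMITED_TISSUES",
]

#: maternal tissues whose uptake is permeability (diffusion) limited and which
#: are therefore split into a tissue-blood and a cellular sub-compartment
DIFFUSION_LIMITED_TISSUES = ("brain", "muscle", "kidney", "fat", "mammary", "slowly_perfused")

#: maternal flow-limited tissues (instant equilibrium with venous blood)
FLOW_LIMITED_TISSUES = ("gi", "liver", "rapidly_perfused", "placenta")

_REF_LITTER = 13.5  # litter size at which the printed litter organ volumes apply


def _check_domain(t_gd: float) -> None:
    # the GD20 group is sampled up to 24 h post-dose, so the laws must
    # evaluate (by extension of the gestational trends) up to GD21
    if not (-1e-9 <= t_gd <= 21.0 + 1e-9):
        raise ValueError(f"gestational time {t_gd!r} outside the model domain [0, 21] days")


@dataclass(frozen=True)
class FetalPhysiology:
    """Litter-level fetal volumes (L) and blood flows (L/h) at one instant."""

    per_fetus_bw: float  # kg
    litter_bw: float  # kg
    volumes: Mapping[str, float]  # keys: blood, brain, liver, rest
    flows: Mapping[str, float]  # keys: cardiac_output, brain, liver, rest


@dataclass(frozen=True)
class GestationalPhysiology:
    """Physiological parameter set of the pregnant dam and her litter.

    Defaults reproduce the study's reference physiology exactly; every field
    can be overridden through the run configuration.
    """

    # maternal body weight anchors (kg)
    bw0: float = 0.277
    bw_mid: float = 0.356
    bw20: float = 0.422
    gd_mid: float = 15.0

    # cardiac output index (L/h/kg), linear over gestation
    qci0: float = 24.56
    qci20: float = 21.6

    # tissue volumes as fractions of the initial body weight
    frac_volumes: Mapping[str, float] = field(
        default_factory=lambda: {
            "blood": 0.06,
            "gi": 0.027,
            "liver": 0.0351,
            "muscle": 0.404,
            "brain": 0.0073,
            "kidney": 0.0076,
            "non_perfused": 0.05,
            "rapidly_perfused": 0.046,
        }
    )
    # gestation-varying volumes, (GD0, GD20) endpoints in L
    var_volumes: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "mammary": (0.0024, 0.013),
            "fat": (0.017, 0.024),
            "placenta": (0.0, 0.167),
        }
    )
    # whole-body adipose baseline (fraction of initial BW) on top of which the
    # gestation-varying fat depot grows; total fat = baseline + depot
    fat_baseline_frac: float = 0.07
    # blood flows as fractions of the initial cardiac output
    frac_flows: Mapping[str, float] = field(
        default_factory=lambda: {
            "liver_total": 0.174,  # liver venous outflow (portal + arterial)
            "gi": 0.151,  # portal inflow to the GI tissue
            "liver": 0.024,  # hepatic arterial inflow
            "muscle": 0.278,
            "brain": 0.02,
            "kidney": 0.141,
            "slowly_perfused": 0.063,
        }
    )
    # gestation-varying flows, (GD0, GD20) endpoints in L/h
    var_flows: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "mammary": (0.012, 0.064),
            "fat": (0.21, 0.29),
            "placenta": (0.0, 1.42),
        }
    )
    # residual blood volume, as a fraction of tissue volume, of the
    # diffusion-limited tissues (slowly perfused assimilated to muscle)
    bv_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "brain": 0.03,
            "muscle": 0.04,
            "kidney": 0.16,
            "fat": 0.02,
            "mammary": 0.02,
            "slowly_perfused": 0.04,
        }
    )

    # fetal block (litter lumped into one compartment set)
    fetal_bw_end: float = 0.0068  # kg per fetus at GD20
    fetal_qci: float = 22.8  # L/h/kg litter body weight
    fetal_blood_frac: float = 0.0676  # fraction of litter BW
    fetal_brain_end: float = 0.0034  # L, litter total at the reference litter size
    fetal_liver_end: float = 0.0044  # L, litter total at the reference litter size
    fetal_flow_fracs: Mapping[str, float] = field(
        default_factory=lambda: {"brain": 0.1055, "liver": 0.061}
    )
    fetal_bv_brain: float = 0.03
    fetal_bv_rest: float = 0.05
    n_fetuses: float = 13.5

    # conceptus growth law
    conceptus_onset: float = 6.0  # GD of implantation; zero before
    growth_midpoint: float = 15.0  # logistic midpoint (GD)
    growth_scale: float = 1.5  # logistic time scale (days)
    volume_floor: float = 1e-9  # L, guards divisions in tiny compartments

    # freeze physiology at a fixed GD (static configuration for LTI checks)
    freeze_at: float | None = None

    # ------------------------------------------------------------------ laws
    def _t(self, t_gd: float) -> float:
        _check_domain(t_gd)
        return self.freeze_at if self.freeze_at is not None else t_gd

    def maternal_body_weight(self, t_gd: float) -> float:
        """Maternal body weight (kg), piecewise-linear through the anchors."""
        t = self._t(t_gd)
        if t <= self.gd_mid:
            return self.bw0 + (self.bw_mid - self.bw0) * t / self.gd_mid
        return self.bw_mid + (self.bw20 - self.bw_mid) * (t - self.gd_mid) / (20.0 - self.gd_mid)

    def cardiac_output_index(self, t_gd: float) -> float:
        t = self._t(t_gd)
        return self.qci0 + (self.qci20 - self.qci0) * t / 20.0

    def cardiac_output(self, t_gd: float) -> float:
        """Total maternal cardiac output (L/h) = QCI(t) x BW(t)."""
        return self.cardiac_output_index(t_gd) * self.maternal_body_weight(t_gd)

    def _linear(self, endpoints: tuple[float, float], t: float) -> float:
        lo, hi = endpoints
        return lo + (hi - lo) * t / 20.0

    def conceptus_fraction(self, t_gd: float) -> float:
        """Logistic growth fraction in [0, 1]: 0 at implantation, 1 at GD20."""
        t = self._t(t_gd)
        if t <= self.conceptus_onset:
            return 0.0
        s, m = self.growth_scale, self.growth_midpoint
        lo = expit((self.conceptus_onset - m) / s)
        hi = expit((20.0 - m) / s)
        return float((expit((t - m) / s) - lo) / (hi - lo))

    @property
    def slowly_perfused_fraction(self) -> float:
        """Volume balance: 1 - all constant-fraction organs - non-perfused."""
        organs = sum(v for k, v in self.frac_volumes.items() if k != "non_perfused")
        return 1.0 - organs - self.frac_volumes["non_perfused"]

    # --------------------------------------------------------------- volumes
    def volumes_at(self, t_gd: float) -> dict[str, float]:
        """Tissue volumes (L) at ``t_gd``.

        Constant-fraction tissues are fraction x initial BW; mammary/fat
        interpolate linearly; the placenta follows the conceptus logistic.
        """
        t = self._t(t_gd)
        v = {k: f * self.bw0 for k, f in self.frac_volumes.items()}
        v["slowly_perfused"] = self.slowly_perfused_fraction * self.bw0
        v["mammary"] = self._linear(self.var_volumes["mammary"], t)
        v["fat"] = self.fat_baseline_frac * self.bw0 + self._linear(self.var_volumes["fat"], t)
        v["placenta"] = self.var_volumes["placenta"][1] * self.conceptus_fraction(t)
        for name, vol in v.items():
            if vol < 0:
                raise RuntimeError(f"internal error: negative volume for {name!r}: {vol}")
        return v

    def split_volume(self, tissue: str, total: float) -> tuple[float, float]:
        """Split a diffusion-limited tissue volume into (tissue-blood, tissue)."""
        bv = self.bv_fractions[tissue]
        return bv * total, (1.0 - bv) * total

    # ----------------------------------------------------------------- flows
    def flows_at(self, t_gd: float) -> dict[str, float]:
        """Blood flows (L/h) at ``t_gd``, including the total cardiac output.

        Rapidly perfused flow is the balance: cardiac output minus every
        other tissue flow, and must remain non-negative.
        """
        t = self._t(t_gd)
        co0 = self.qci0 * self.bw0
        q = {k: f * co0 for k, f in self.frac_flows.items()}
        q["mammary"] = self._linear(self.var_flows["mammary"], t)
        q["fat"] = self._linear(self.var_flows["fat"], t)
        q["placenta"] = self.var_flows["placenta"][1] * self.conceptus_fraction(t)
        co = self.cardiac_output(t_gd)
        arterial = (
            q["gi"]
            + q["liver"]
            + q["muscle"]
            + q["brain"]
            + q["kidney"]
            + q["slowly_perfused"]
            + q["mammary"]
            + q["fat"]
            + q["placenta"]
        )
        q["rapidly_perfused"] = co - arterial
        if q["rapidly_perfused"] < 0:
            raise RuntimeError(
                "configuration error: rapidly perfused flow balance is negative "
                f"at GD{t_gd:g} ({q['rapidly_perfused']:.4g} L/h)"
            )
        q["cardiac_output"] = co
        return q

    # ----------------------------------------------------------------- fetal
    def fetal_physiology_at(self, t_gd: float, n_fetuses: float | None = None) -> FetalPhysiology:
        """Fetal litter volumes and flows at ``t_gd``.

        The litter is lumped: litter BW = n x per-fetus BW; brain and liver
        are litter-lumped volumes scaled linearly in litter size from their
        reference-litter endpoints; rest-of-body closes the volume balance
        and the rest-of-body flow closes the fetal cardiac output.
        """
        n = self.n_fetuses if n_fetuses is None else n_fetuses
        if n <= 0:
            raise ValueError("n_fetuses must be > 0")
        frac = self.conceptus_fraction(t_gd)
        per_bw = self.fetal_bw_end * frac
        litter_bw = n * per_bw
        scale = n / _REF_LITTER
        v_brain = self.fetal_brain_end * frac * scale
        v_liver = self.fetal_liver_end * frac * scale
        v_blood = self.fetal_blood_frac * litter_bw
        v_rest = litter_bw - v_blood - v_brain - v_liver
        if litter_bw > 0 and v_rest < 0:
            raise RuntimeError("internal error: negative fetal rest-of-body volume")
        qc = self.fetal_qci * litter_bw
        q_brain = self.fetal_flow_fracs["brain"] * qc
        q_liver = self.fetal_flow_fracs["liver"] * qc
        return FetalPhysiology(
            per_fetus_bw=per_bw,
            litter_bw=litter_bw,
            volumes={"blood": v_blood, "brain": v_brain, "liver": v_liver, "rest": v_rest},
            flows={
                "cardiac_output": qc,
                "brain": q_brain,
                "liver": q_liver,
                "rest": qc - q_brain - q_liver,
            },
        )

    def conceptus_active(self, t_gd: float) -> bool:
        """True once the placenta volume exceeds the numerical floor."""
        return self.volumes_at(t_gd)["placenta"] > self.volume_floor

    def frozen(self, t_gd: float) -> "GestationalPhysiology":
        """A static copy evaluated at ``t_gd`` for all times."""
        return replace(self, freeze_at=t_gd)
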