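"""Mass-balance core of the maternal + fetal permethrin PBPK model.

The model tracks amounts (mg) of one isomer.  The maternal sub-model has a
two-compartment gut (stomach lumen, intestinal lumen), flow-limited GI
tissue, liver, rapidly perfused tissue and placenta, diffusion-limited
brain, muscle, kidney, fat, mammary gland and slowly perfused tissue (each
split into a residual tissue-blood and a cellular sub-compartment), and a
single well-mixed blood compartment.  The fetal sub-model (litter lumped)
has blood, flow-limited liver and rest-of-body, and a diffusion-limited
brain.  Metabolism occurs in maternal liver, blood and GI tissue; the fetus
does not metabolize.  Cumulative metabolism and fecal excretion are tracked
as sink slots so the system is exactly mass conservative between doses.

The whole system is linear in the state: ``dx/dt = M(t) x`` where the rate
matrix ``M`` depends on time only through gestational physiology.  The
matrix form is used both to feed the stiff integrator an analytic Jacobian
and as a fast day-frozen matrix-exponential propagator for calibration and
sensitivity analysis.

Placental exchange is bidirectional diffusion: the dam-to-fetus flux is
``Ktrans1 * C_Pla / PC_Pla`` and the return flux ``Ktrans2 * C_Art,F``,
with ``Ktrans_i = sc_ktrans_i * BW(t)^0.75`` (maternal body weight).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import eig, expm, solve

from .parameters import ChemicalParams
from .physiology import DIFFUSION_LIMITED_TISSUES, GestationalPhysiology

__all__ = [
    "STATE_SLOTS",
    "N_STATE",
    "IDX",
    "MATRICES",
    "InactiveCompartmentError",
    "build_rate_matrix",
    "derivatives",
    "concentrations",
    "concentration",
    "total_mass",
    "PregnancyPBPK",
]

#: fixed, documented slot order of the state vector (amounts in mg)
STATE_SLOTS: tuple[str, ...] = (
    "a_stomach",        # 0  stomach lumen
    "a_int_lumen",      # 1  intestinal lumen
    "a_gi",             # 2  GI tissue (flow-limited)
    "a_liver",          # 3  liver (flow-limited)
    "a_rapid",          # 4  rapidly perfused (flow-limited)
    "a_brain_b",        # 5  brain residual blood
    "a_brain",          # 6  brain tissue
    "a_muscle_b",       # 7
    "a_muscle",         # 8
    "a_kidney_b",       # 9
    "a_kidney",         # 10
    "a_fat_b",          # 11
    "a_fat",            # 12
    "a_mammary_b",      # 13
    "a_mammary",        # 14
    "a_slow_b",         # 15 slowly perfused residual blood
    "a_slow",           # 16 slowly perfused tissue
    "a_placenta",       # 17 placenta (flow-limited)
    "a_blood",          # 18 maternal blood (well mixed)
    "a_fblood",         # 19 fetal blood (litter)
    "a_fliver",         # 20 fetal liver (flow-limited)
    "a_fbrain_b",       # 21 fetal brain residual blood
    "a_fbrain",         # 22 fetal brain tissue
    "a_frest",          # 23 fetal rest of body (flow-limited)
    "m_liver",          # 24 cumulative hepatic metabolism (sink)
    "m_blood",          # 25 cumulative blood metabolism (sink)
    "m_gi",             # 26 cumulative GI metabolism (sink)
    "a_feces",          # 27 cumulative fecal excretion (sink)
)
N_STATE = len(STATE_SLOTS)
IDX: dict[str, int] = {name: i for i, name in enumerate(STATE_SLOTS)}

_DIFF_SLOTS = {
    "brain": ("a_brain_b", "a_brain"),
    "muscle": ("a_muscle_b", "a_muscle"),
    "kidney": ("a_kidney_b", "a_kidney"),
    "fat": ("a_fat_b", "a_fat"),
    "mammary": ("a_mammary_b", "a_mammary"),
    "slowly_perfused": ("a_slow_b", "a_slow"),
}
_PS_NAME = {
    "brain": "ps_brain",
    "muscle": "ps_musc",
    "kidney": "ps_kid",
    "fat": "ps_fat",
    "mammary": "ps_mam",
    "slowly_perfused": "ps_sp",
}
_PC_NAME = {
    "brain": "pc_brain",
    "muscle": "pc_musc",
    "kidney": "pc_kid",
    "fat": "pc_fat",
    "mammary": "pc_mam",
    "slowly_perfused": "pc_sp",
}

#: measurable matrices exposed by :func:`concentrations`
MATRICES: tuple[str, ...] = (
    "blood", "liver", "brain", "kidney", "fat", "mammary", "muscle",
    "gi", "rapidly_perfused", "slowly_perfused", "placenta",
    "fetal_blood", "fetal_liver", "fetal_brain", "fetal_rest", "feces",
)

_CONCEPTUS_MATRICES = frozenset(
    {"placenta", "fetal_blood", "fetal_liver", "fetal_brain", "fetal_rest"}
)


class InactiveCompartmentError(ValueError):
    """Raised when a conceptus matrix is queried before it exists."""


def build_rate_matrix(
    chem: ChemicalParams,
    phys: GestationalPhysiology,
    t_gd: float,
    flow_limited_override: Iterable[str] = (),
) -> np.ndarray:
    """Rate matrix ``M`` (1/h) such that ``dA/dt = M A`` at gestational time ``t_gd``.

    ``flow_limited_override`` names diffusion-limited tissues to treat as
    flow-limited instead (the residual-blood slot then carries the whole
    homogenate at its effective partition); used for limit checks.
    """
    override = frozenset(flow_limited_override)
    unknown = override - set(DIFFUSION_LIMITED_TISSUES)
    if unknown:
        raise ValueError(f"not diffusion-limited tissues: {sorted(unknown)}")

    v = phys.volumes_at(t_gd)
    q = phys.flows_at(t_gd)
    bw = phys.maternal_body_weight(t_gd)
    co = q["cardiac_output"]
    floor = phys.volume_floor

    M = np.zeros((N_STATE, N_STATE))
    i = IDX

    v_blood = v["blood"]
    # gut lumen chain
    M[i["a_stomach"], i["a_stomach"]] = -chem.k_si
    M[i["a_int_lumen"], i["a_stomach"]] = chem.k_si
    M[i["a_int_lumen"], i["a_int_lumen"]] = -(chem.k_ai + chem.k_fec)
    M[i["a_feces"], i["a_int_lumen"]] = chem.k_fec
    M[i["a_gi"], i["a_int_lumen"]] = chem.k_ai

    # GI tissue: portal inflow, venous outflow to liver, intestinal metabolism
    k_gi_out = 1.0 / (chem.pc_gi * v["gi"])
    M[i["a_gi"], i["a_blood"]] += q["gi"] / v_blood
    M[i["a_gi"], i["a_gi"]] += -(q["gi"] + chem.cl_gi * bw) * k_gi_out
    M[i["a_liver"], i["a_gi"]] += q["gi"] * k_gi_out
    M[i["m_gi"], i["a_gi"]] += chem.cl_gi * bw * k_gi_out

    # liver: hepatic arterial + portal inflow, total venous outflow, metabolism
    k_liv_out = 1.0 / (chem.pc_liv * v["liver"])
    M[i["a_liver"], i["a_blood"]] += q["liver"] / v_blood
    M[i["a_liver"], i["a_liver"]] += -(q["liver_total"] + chem.cl_liv * bw) * k_liv_out
    M[i["a_blood"], i["a_liver"]] += q["liver_total"] * k_liv_out
    M[i["m_liver"], i["a_liver"]] += chem.cl_liv * bw * k_liv_out

    # rapidly perfused, flow-limited
    k_rp_out = 1.0 / (chem.pc_rp * v["rapidly_perfused"])
    M[i["a_rapid"], i["a_blood"]] += q["rapidly_perfused"] / v_blood
    M[i["a_rapid"], i["a_rapid"]] += -q["rapidly_perfused"] * k_rp_out
    M[i["a_blood"], i["a_rapid"]] += q["rapidly_perfused"] * k_rp_out

    # diffusion-limited tissues
    for tis in DIFFUSION_LIMITED_TISSUES:
        sb, st = (i[s] for s in _DIFF_SLOTS[tis])
        qt = q[tis]
        pc = getattr(chem, _PC_NAME[tis])
        if tis in override:
            # whole tissue in the *_b slot, flow-limited venous return; the
            # homogenate (residual blood + partitioned cells) equilibrates at
            # the effective partition BV + (1-BV) PC, the exact PS->inf limit
            bv = phys.bv_fractions[tis]
            pc_eff = bv + (1.0 - bv) * pc
            k_out = 1.0 / (pc_eff * v[tis])
            M[sb, i["a_blood"]] += qt / v_blood
            M[sb, sb] += -qt * k_out
            M[i["a_blood"], sb] += qt * k_out
            continue
        ps = getattr(chem, _PS_NAME[tis])
        v_tb, v_t = phys.split_volume(tis, v[tis])
        M[sb, i["a_blood"]] += qt / v_blood
        M[sb, sb] += -(qt + ps) / v_tb
        M[sb, st] += ps / (pc * v_t)
        M[st, sb] += ps / v_tb
        M[st, st] += -ps / (pc * v_t)
        M[i["a_blood"], sb] += qt / v_tb

    # maternal blood: arterial outflow + blood metabolism
    M[i["a_blood"], i["a_blood"]] += -(co + chem.cl_blood * bw) / v_blood
    M[i["m_blood"], i["a_blood"]] += chem.cl_blood * bw / v_blood

    # conceptus
    if v["placenta"] > floor:
        fet = phys.fetal_physiology_at(t_gd)
        ktrans1 = chem.sc_ktrans1 * bw**0.75
        ktrans2 = chem.sc_ktrans2 * bw**0.75
        k_pla_out = 1.0 / (chem.pc_pla * v["placenta"])
        v_fb = max(fet.volumes["blood"], floor)
        qc_f = fet.flows["cardiac_output"]

        M[i["a_placenta"], i["a_blood"]] += q["placenta"] / v_blood
        M[i["a_placenta"], i["a_placenta"]] += -(q["placenta"] + ktrans1) * k_pla_out
        M[i["a_blood"], i["a_placenta"]] += q["placenta"] * k_pla_out
        M[i["a_fblood"], i["a_placenta"]] += ktrans1 * k_pla_out
        M[i["a_placenta"], i["a_fblood"]] += ktrans2 / v_fb
        M[i["a_fblood"], i["a_fblood"]] += -(ktrans2 + qc_f) / v_fb

        # fetal liver (flow-limited)
        k_fliv = 1.0 / (chem.pc_liv_f * max(fet.volumes["liver"], floor))
        M[i["a_fliver"], i["a_fblood"]] += fet.flows["liver"] / v_fb
        M[i["a_fliver"], i["a_fliver"]] += -fet.flows["liver"] * k_fliv
        M[i["a_fblood"], i["a_fliver"]] += fet.flows["liver"] * k_fliv

        # fetal brain (diffusion-limited)
        v_br = max(fet.volumes["brain"], floor)
        v_brb = phys.fetal_bv_brain * v_br
        v_brt = (1.0 - phys.fetal_bv_brain) * v_br
        q_fbr = fet.flows["brain"]
        M[i["a_fbrain_b"], i["a_fblood"]] += q_fbr / v_fb
        M[i["a_fbrain_b"], i["a_fbrain_b"]] += -(q_fbr + chem.ps_brain_f) / v_brb
        M[i["a_fbrain_b"], i["a_fbrain"]] += chem.ps_brain_f / (chem.pc_brain_f * v_brt)
        M[i["a_fbrain"], i["a_fbrain_b"]] += chem.ps_brain_f / v_brb
        M[i["a_fbrain"], i["a_fbrain"]] += -chem.ps_brain_f / (chem.pc_brain_f * v_brt)
        M[i["a_fblood"], i["a_fbrain_b"]] += q_fbr / v_brb

        # fetal rest of body (flow-limited)
        k_frb = 1.0 / (chem.pc_rb_f * max(fet.volumes["rest"], floor))
        M[i["a_frest"], i["a_fblood"]] += fet.flows["rest"] / v_fb
        M[i["a_frest"], i["a_frest"]] += -fet.flows["rest"] * k_frb
        M[i["a_fblood"], i["a_frest"]] += fet.flows["rest"] * k_frb

    return M


def derivatives(
    t_gd: float,
    state: np.ndarray,
    chem: ChemicalParams,
    phys: GestationalPhysiology,
    flow_limited_override: Iterable[str] = (),
) -> np.ndarray:
    """Right-hand side of the mass balance (mg/h per slot)."""
    state = np.asarray(state, dtype=float)
    if state.shape != (N_STATE,):
        raise ValueError(f"state must have {N_STATE} slots, got shape {state.shape}")
    if not np.all(np.isfinite(state)):
        bad = STATE_SLOTS[int(np.flatnonzero(~np.isfinite(state))[0])]
        raise FloatingPointError(f"non-finite amount in compartment {bad!r}")
    M = build_rate_matrix(chem, phys, t_gd, flow_limited_override)
    return M @ state


def total_mass(state: np.ndarray) -> float:
    """Total amount in the system, metabolic/fecal sinks included (mg)."""
    return float(np.sum(state))


def _volumes_by_matrix(phys: GestationalPhysiology, t_gd: float) -> dict[str, float]:
    v = phys.volumes_at(t_gd)
    out = {
        "blood": v["blood"],
        "liver": v["liver"],
        "gi": v["gi"],
        "rapidly_perfused": v["rapidly_perfused"],
        "placenta": v["placenta"],
    }
    for tis in DIFFUSION_LIMITED_TISSUES:
        out[tis] = v[tis]
    fet = phys.fetal_physiology_at(t_gd)
    out["fetal_blood"] = fet.volumes["blood"]
    out["fetal_liver"] = fet.volumes["liver"]
    out["fetal_brain"] = fet.volumes["brain"]
    out["fetal_rest"] = fet.volumes["rest"]
    return out


_MATRIX_SLOTS: dict[str, tuple[str, ...]] = {
    "blood": ("a_blood",),
    "liver": ("a_liver",),
    "gi": ("a_gi",),
    "rapidly_perfused": ("a_rapid",),
    "placenta": ("a_placenta",),
    "brain": ("a_brain_b", "a_brain"),
    "muscle": ("a_muscle_b", "a_muscle"),
    "kidney": ("a_kidney_b", "a_kidney"),
    "fat": ("a_fat_b", "a_fat"),
    "mammary": ("a_mammary_b", "a_mammary"),
    "slowly_perfused": ("a_slow_b", "a_slow"),
    "fetal_blood": ("a_fblood",),
    "fetal_liver": ("a_fliver",),
    "fetal_brain": ("a_fbrain_b", "a_fbrain"),
    "fetal_rest": ("a_frest",),
}


def concentration(
    state: np.ndarray, phys: GestationalPhysiology, t_gd: float, matrix: str
) -> float:
    """Measured-matrix concentration (mg/L = ug/ml = ug/g) at one instant.

    Diffusion-limited tissues report the homogenate concentration
    (tissue + residual blood amounts over the total volume).  ``feces``
    reports the cumulative excreted amount in mg.
    """
    state = np.asarray(state, dtype=float)
    if matrix == "feces":
        return float(state[IDX["a_feces"]])
    if matrix not in _MATRIX_SLOTS:
        raise KeyError(f"unknown matrix {matrix!r}; valid matrices: {sorted(MATRICES)}")
    vols = _volumes_by_matrix(phys, t_gd)
    vol = vols[matrix]
    if matrix in _CONCEPTUS_MATRICES and vol <= phys.volume_floor:
        raise InactiveCompartmentError(
            f"matrix {matrix!r} is inactive at GD{t_gd:g} (conceptus not yet formed)"
        )
    amt = sum(state[IDX[s]] for s in _MATRIX_SLOTS[matrix])
    return float(amt / vol)


def concentrations(
    state: np.ndarray,
    phys: GestationalPhysiology,
    t_gd: float,
    matrices: Sequence[str] | None = None,
) -> dict[str, float]:
    """Concentration map over measurable matrices.

    With ``matrices=None`` only the matrices active at ``t_gd`` are
    returned; explicitly requesting an inactive conceptus matrix raises
    :class:`InactiveCompartmentError`.
    """
    if matrices is None:
        conceptus = phys.conceptus_active(t_gd)
        matrices = [m for m in MATRICES if conceptus or m not in _CONCEPTUS_MATRICES]
    return {m: concentration(state, phys, t_gd, m) for m in matrices}


@dataclass(frozen=True)
class PregnancyPBPK:
    """Forward pregnancy PBPK model for one permethrin isomer.

    Bundles a chemical parameter vector with gestational physiology and
    exposes the rate matrix, the ODE right-hand side and the day-frozen
    matrix-exponential propagator.  Full time-varying simulation lives in
    :mod:`permpbpk.simulate` and takes this object as its model.
    """

    chem: ChemicalParams
    phys: GestationalPhysiology
    flow_limited_override: frozenset[str] = frozenset()

    def rate_matrix(self, t_gd: float) -> np.ndarray:
        return build_rate_matrix(self.chem, self.phys, t_gd, self.flow_limited_override)

    def rhs(self, t_h: float, state: np.ndarray) -> np.ndarray:
        return self.rate_matrix(t_h / 24.0) @ state

    def concentration(self, state: np.ndarray, t_gd: float, matrix: str) -> float:
        return concentration(state, self.phys, t_gd, matrix)

    # ------------------------------------------------- fast linear propagator
    @staticmethod
    def _propagate_offsets(
        M: np.ndarray, x: np.ndarray, dts_h: Sequence[float]
    ) -> list[np.ndarray]:
        """States ``expm(M dt) x`` for several dt from one decomposition.

        Uses the eigendecomposition of ``M`` when it is well conditioned
        (checked by reconstructing the shortest step against ``expm``),
        falling back to sequential matrix exponentials otherwise.
        """
        dts = [float(d) for d in dts_h]
        try:
            lam, V = eig(M)
            Vix = solve(V, x.astype(complex))
            out = [np.real(V @ (np.exp(lam * dt) * Vix)) for dt in dts]
            ref = expm(M * dts[0]) @ x
            scale = max(np.max(np.abs(ref)), 1e-30)
            if np.max(np.abs(out[0] - ref)) / scale < 1e-9:
                return out
        except np.linalg.LinAlgError:
            pass
        out, prev, y = [], 0.0, x
        for dt in sorted(dts):
            y = expm(M * (dt - prev)) @ y
            prev = dt
            out.append(y)
        order = np.argsort(np.argsort(dts))
        return [out[k] for k in order]

    def propagate_dosing(
        self,
        dose_days: Sequence[float],
        dose_mg: Sequence[float] | float,
        sample_offsets_h: Sequence[float],
        sample_day: float | None = None,
    ) -> dict[float, np.ndarray]:
        """Propagate a once-daily bolus schedule with day-frozen physiology.

        Each inter-dose day is advanced with ``expm(M(day + 0.5) * 24 h)``;
        the physiology is frozen at the day midpoint, exact for a static
        physiology and a close approximation to the slow gestational drift.
        Returns the state vector at each requested offset (hours after the
        final dose, which falls on ``sample_day`` = last dose day).

        The offset ``0.0`` (pre-dose trough, before the final bolus is
        added) may be requested and is returned under key ``-0.0``.
        """
        dose_days = sorted(dose_days)
        if sample_day is None:
            sample_day = dose_days[-1]
        if np.isscalar(dose_mg):
            dose_mg = [float(dose_mg)] * len(dose_days)
        if len(dose_mg) != len(dose_days):
            raise ValueError("dose_mg and dose_days length mismatch")
        x = np.zeros(N_STATE)
        out: dict[float, np.ndarray] = {}
        for day, dose in zip(dose_days, dose_mg):
            if day > sample_day:
                break
            if day == sample_day and 0.0 in sample_offsets_h:
                out[0.0] = x.copy()  # pre-dose trough
            x[IDX["a_stomach"]] += dose
            if day < sample_day:
                M = self.rate_matrix(day + 0.5)
                x = self._propagate_offsets(M, x, [24.0])[0]
        # final post-dose window
        offsets = sorted(o for o in sample_offsets_h if o > 0)
        if offsets:
            M = self.rate_matrix(sample_day + 0.5)
            for off, state in zip(offsets, self._propagate_offsets(M, x, offsets)):
                out[off] = state
        return out
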