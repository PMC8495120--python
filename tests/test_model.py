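"""Mass-balance core: rate matrix structure, conservation, limits."""

import numpy as np
import pytest

from permpbpk import GestationalPhysiology, InactiveCompartmentError, PregnancyPBPK
from permpbpk.model import (
    IDX,
    N_STATE,
    STATE_SLOTS,
    build_rate_matrix,
    concentration,
    concentrations,
    derivatives,
)
from permpbpk.physiology import DIFFUSION_LIMITED_TISSUES


class TestDerivatives:
    def test_zero_state_zero_rates(self, phys, chem_cis_gd1):
        rates = derivatives(1.0, np.zeros(N_STATE), chem_cis_gd1, phys)
        assert np.all(rates == 0)

    @pytest.mark.parametrize("t_gd", [0.5, 1.0, 10.0, 16.0, 20.0])
    def test_closed_system_between_doses(self, phys, chem_cis_late, t_gd):
        """Sum of all rate slots (sinks included) vanishes for any state."""
        rng = np.random.default_rng(0)
        state = rng.uniform(0, 1, N_STATE)
        rates = derivatives(t_gd, state, chem_cis_late, phys)
        assert abs(rates.sum()) < 1e-12 * np.abs(rates).sum()

    @pytest.mark.parametrize("t_gd", [1.0, 12.0, 19.0])
    def test_rate_matrix_columns_sum_to_zero(self, phys, chem_cis_late, t_gd):
        M = build_rate_matrix(chem_cis_late, phys, t_gd)
        assert np.max(np.abs(M.sum(axis=0))) < 1e-10 * np.max(np.abs(M))

    def test_nonfinite_state_names_compartment(self, phys, chem_cis_gd1):
        state = np.zeros(N_STATE)
        state[IDX["a_liver"]] = np.nan
        with pytest.raises(FloatingPointError, match="a_liver"):
            derivatives(1.0, state, chem_cis_gd1, phys)

    def test_high_ps_brain_uptake_matches_flow_limited_flux(self, phys, chem_cis_gd1):
        """Mass only in maternal blood, PS -> 1e3 L/h: the brain uptake flux
        equals the flow-limited flux Q_Brain (C_Art - C_Br/PC_Brain) within 1%."""
        chem = chem_cis_gd1.with_values(ps_brain=1e3)
        state = np.zeros(N_STATE)
        state[IDX["a_blood"]] = 1.0
        c_art = 1.0 / phys.volumes_at(1.0)["blood"]
        q_brain = phys.flows_at(1.0)["brain"]

        rates = derivatives(1.0, state, chem, phys)
        uptake = rates[IDX["a_brain_b"]] + rates[IDX["a_brain"]]
        assert uptake == pytest.approx(q_brain * (c_art - 0.0), rel=0.01)

    def test_fetal_compartments_sealed_without_transfer(self, phys, chem_cis_late):
        """sc_ktrans1 = sc_ktrans2 = 0 keeps every fetal slot at zero."""
        chem = chem_cis_late.with_values(sc_ktrans1=1e-300, sc_ktrans2=1e-300)
        M = build_rate_matrix(chem, phys, 18.0)
        state = np.zeros(N_STATE)
        state[IDX["a_blood"]] = 1.0
        state[IDX["a_placenta"]] = 0.5
        rates = M @ state
        for slot in ("a_fblood", "a_fliver", "a_fbrain_b", "a_fbrain", "a_frest"):
            assert abs(rates[IDX[slot]]) < 1e-250

    def test_placental_exchange_conserves_across_barrier(self, phys, chem_cis_late):
        """The Ktrans1/Ktrans2 fluxes leave one side and enter the other."""
        M = build_rate_matrix(chem_cis_late, phys, 18.0)
        i, j = IDX["a_placenta"], IDX["a_fblood"]
        bw = phys.maternal_body_weight(18.0)
        v_pla = phys.volumes_at(18.0)["placenta"]
        v_fb = phys.fetal_physiology_at(18.0).volumes["blood"]
        k1 = chem_cis_late.sc_ktrans1 * bw**0.75
        k2 = chem_cis_late.sc_ktrans2 * bw**0.75
        # dam->fetus flux coefficient appears identically in both rows
        assert M[j, i] == pytest.approx(k1 / (chem_cis_late.pc_pla * v_pla))
        assert M[i, j] == pytest.approx(k2 / v_fb)


class TestConcentrations:
    def test_blood_concentration_definition(self, phys, chem_cis_gd1):
        state = np.zeros(N_STATE)
        state[IDX["a_blood"]] = 1.0
        v_blood = phys.volumes_at(1.0)["blood"]
        assert concentration(state, phys, 1.0, "blood") == pytest.approx(1.0 / v_blood)

    def test_zero_state_all_zero(self, phys):
        out = concentrations(np.zeros(N_STATE), phys, 18.0)
        assert out and all(v == 0 for v in out.values())

    def test_homogenate_includes_residual_blood(self, phys):
        state = np.zeros(N_STATE)
        state[IDX["a_fat_b"]] = 0.2  # all mass in the tissue-blood slot
        v_fat = phys.volumes_at(1.0)["fat"]
        assert concentration(state, phys, 1.0, "fat") == pytest.approx(0.2 / v_fat)

    def test_inactive_conceptus_raises(self, phys):
        with pytest.raises(InactiveCompartmentError, match="placenta"):
            concentration(np.zeros(N_STATE), phys, 1.0, "placenta")
        # and active later in gestation
        assert concentration(np.zeros(N_STATE), phys, 18.0, "placenta") == 0.0

    def test_unknown_matrix_lists_valid_names(self, phys):
        with pytest.raises(KeyError, match="valid matrices"):
            concentration(np.zeros(N_STATE), phys, 1.0, "bone")

    def test_slot_order_is_stable(self):
        # downstream CSVs and draw tables rely on this documented order
        assert STATE_SLOTS[0] == "a_stomach"
        assert STATE_SLOTS[IDX["a_blood"]] == "a_blood"
        assert STATE_SLOTS[-1] == "a_feces"
        assert len(set(STATE_SLOTS)) == N_STATE


class TestFastPropagator:
    def test_matches_full_ode_after_single_dose(self, phys, chem_cis_gd1, gd1_simulation):
        pbpk = PregnancyPBPK(chem_cis_gd1, phys)
        dose = gd1_simulation.dose_log[0][1]
        states = pbpk.propagate_dosing([1.0], [dose], [2.0, 6.0, 24.0])
        for off in (2.0, 6.0, 24.0):
            for mat in ("blood", "liver", "fat"):
                fast = pbpk.concentration(states[off], 1.0 + off / 24.0, mat)
                ode = gd1_simulation.concentration_at(24.0 + off, mat)
                assert fast == pytest.approx(ode, rel=0.02)

    def test_mass_conserved_by_propagator(self, phys, chem_cis_late):
        pbpk = PregnancyPBPK(chem_cis_late, phys)
        states = pbpk.propagate_dosing(
            [float(d) for d in range(1, 16)], 1.0, [1.0, 24.0]
        )
        assert states[24.0].sum() == pytest.approx(15.0, rel=1e-8)
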