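import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from permpbpk import DoseSchedule, GestationalPhysiology
from permpbpk.parameters import posterior_mean_params


@pytest.fixture(scope="session")
def phys():
    return GestationalPhysiology()


@pytest.fixture(scope="session")
def chem_cis_gd1():
    return posterior_mean_params("cis", "gd1")


@pytest.fixture(scope="session")
def chem_cis_late():
    return posterior_mean_params("cis", "gd15_20")


@pytest.fixture(scope="session")
def single_dose_gd1():
    """The study's GD1 scenario: one 20 mg/kg cis dose to a 0.277 kg dam."""
    return DoseSchedule(
        dose_per_kg=50.0, isomer_fraction=0.40, times=(1.0,), scale_to_current_bw=False
    )


@pytest.fixture(scope="session")
def gd1_simulation(phys, chem_cis_gd1, single_dose_gd1):
    """Dense single-dose GD1 cis simulation shared across tests."""
    from permpbpk import run

    return run(chem_cis_gd1, phys, single_dose_gd1, t_end=2.0, output_dt=0.05)


def _auc_post_dose(result, matrix, t_dose_h=24.0, window_h=24.0):
    """Trapezoid AUC of a matrix over (t_dose, t_dose + window]."""
    t, c = result.concentration_series(matrix)
    sel = (t >= t_dose_h) & (t <= t_dose_h + window_h)
    return float(np.trapezoid(c[sel], t[sel] - t_dose_h))


@pytest.fixture(scope="session")
def auc_post_dose():
    """Post-dose 24-h AUC helper shared across test modules."""
    return _auc_post_dose
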