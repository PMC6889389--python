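import numpy as np
import pytest

import leukossm as lk


@pytest.fixture(scope="session")
def tcm_params():
    return lk.default_tcm_parameters()


@pytest.fixture(scope="session")
def crp_params():
    return lk.default_tcm_crp_parameters()


@pytest.fixture(scope="session")
def jm_params():
    return lk.default_jm_parameters()


@pytest.fixture
def toy_record():
    """Tiny hand-built record: three weekly visits, constant dosing."""
    return lk.PatientRecord(
        patient_id="toy",
        dose_times=np.arange(0.0, 21.0), doses=np.full(21, 25.0),
        obs_times=np.array([0.0, 7.0, 14.0]),
        leukocyte=np.array([5.0, 4.0, 3.5]),
        crp=np.array([1.0, np.nan, 12.0]),
        bsa_times=np.array([0.0, 14.0]), bsa=np.array([1.0, 1.0]),
    )


@pytest.fixture(scope="session")
def sim_tcm():
    """One simulated 300-day patient under the TCM generator, with truth."""
    scenario = lk.SimulationScenario(params=lk.default_tcm_parameters(),
                                     n_days=300.0, seed=11)
    return lk.simulate_patient(scenario)


@pytest.fixture(scope="session")
def sim_crp():
    """One simulated 300-day patient under the TCM-CRP generator."""
    scenario = lk.SimulationScenario(n_days=300.0, seed=12)
    return lk.simulate_patient(scenario)
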