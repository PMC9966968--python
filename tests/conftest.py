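import numpy as np
import pytest

from ventpulse.dataio import PatientProfile, Recording
from ventpulse.simulate import EffortParams, MechanicsParams, VentParams, simulate_psv


@pytest.fixture(scope="session")
def std_mech():
    return MechanicsParams(ers=20.0, rrs=10.0, ecw=7.2)


@pytest.fixture(scope="session")
def std_vent():
    return VentParams(ps=10.0, peep=5.0)


@pytest.fixture(scope="session")
def std_profile():
    return PatientProfile(sex="male", age=70.0, height=175.0, pes_endexp=5.0)


@pytest.fixture(scope="session")
def sim_recording(std_mech, std_vent):
    """One noise-free 60 s recording with ~20 breaths and its ground truth."""
    eff = EffortParams(pmax=8.0, t_rise=0.6, t_release=0.3, neural_rr=21.0)
    return simulate_psv(std_mech, std_vent, eff, duration=60.0, fs=100.0, seed=42)


@pytest.fixture
def flat_recording():
    """Apnea at PEEP: constant pressures, zero flow."""
    n = 2000
    return Recording(
        patient_id="flat",
        fs=100.0,
        t=np.arange(n) / 100.0,
        flow=np.zeros(n),
        paw=np.full(n, 7.0),
        pes=np.full(n, 5.0),
        peep=7.0,
    )
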