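import numpy as np
import pytest

import leafphys as lp


@pytest.fixture
def constants():
    return lp.DEFAULT_CONSTANTS


@pytest.fixture
def c3_params():
    return lp.C3TrueParams(Vcmax=100.0, Jmax=180.0, Rd=1.5)


@pytest.fixture
def c4_params():
    return lp.C4TrueParams(Vpmax=110.0, Kp=80.0, Amax=45.0, Rd=2.0)


@pytest.fixture
def noiseless_c3_curve(c3_params):
    return lp.generate_aci_c3(c3_params, noise_sd=0.0, seed=0)


@pytest.fixture
def noiseless_npq_trace():
    return lp.generate_npq_trace(2.5, 0.4, 2.0, 0.5, 0.4, noise_sd=0.0, seed=0)


def make_curve(ci, A, species="maize"):
    """Bare curve wrapper for hand-constructed points."""
    ci = np.asarray(ci, dtype=float)
    return lp.ACiCurve(species=species, treatment="attached", time_of_day="AM",
                       replicate_id="r1", co2_set=ci.copy(), ci=ci,
                       A=np.asarray(A, dtype=float),
                       gs=np.full(len(ci), 0.2))
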