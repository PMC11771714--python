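import numpy as np
import pandas as pd
import pytest

import npqdyn as nd

#: canonical kinetic truth used across tests: amplitudes (2.0, 1.6, 0.5),
#: time constants (1.0, 23.0) minutes
CANON = dict(a_qe=2.0, a_qm=1.6, a_qi=0.5, tau_qe=1.0, tau_qm=23.0)


@pytest.fixture
def canon_truth():
    return nd.KineticsTruth(**CANON, induction_tau=1.5)


@pytest.fixture
def protocol():
    return nd.ProtocolSchedule()


@pytest.fixture
def weather_3wk():
    return nd.generate_weather("2021-06-20", "2021-07-10", seed=3)


@pytest.fixture
def noiseless_series(canon_truth):
    trace = nd.generate_trace(canon_truth, noise_cv=0.0, seed=0)
    return nd.compute_npq(trace)


def two_year_days():
    return ("2021-07-01", "2021-07-08", "2021-07-15", "2022-07-01", "2022-07-08", "2022-07-15")
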