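import numpy as np
import pytest

from etachan import core, synth

# a single agonist truth used across modules: mid-efficacy, tight coupling
TRUTH_KDC = 200e-6
TRUTH_KDO = 100e-9
TRUTH_L0 = 5.2e-7


@pytest.fixture(scope="session")
def truth():
    return synth.TruthRecord.from_kd(TRUTH_KDC, TRUTH_KDO, TRUTH_L0)


@pytest.fixture(scope="session")
def scheme(truth):
    return synth.scheme_from_constants(truth.KdC, truth.KdO, truth.L0)


@pytest.fixture(scope="session")
def ec50(truth):
    return core.ec50_from_constants(truth.KdC, truth.L2)


@pytest.fixture(scope="session")
def simulated_sequence(scheme, ec50):
    """One shared dwell sequence at EC50 (10^4 events) for dwell-chain tests."""
    return synth.simulate_intervals(scheme, ec50, 10_000, seed=71)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
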