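import numpy as np
import pytest

import volley as V


@pytest.fixture(scope="session")
def lif10():
    return V.LIFParams(tau=10.0)


@pytest.fixture(scope="session")
def theta_half():
    return V.ThetaParams(tau=0.5)


@pytest.fixture(scope="session")
def wb():
    return V.HHParams.wb()


@pytest.fixture(scope="session")
def rtm():
    return V.HHParams.rtm()


@pytest.fixture(scope="session")
def wb_rest(wb):
    return V.resting_state(wb)


@pytest.fixture(scope="session")
def baseline_run():
    """Full PING network without tonic inhibition (shared across tests)."""
    cfg = V.baseline_config()
    raster = V.simulate_network(cfg)
    metrics = V.rhythm_metrics(raster, cfg)
    return cfg, raster, metrics


@pytest.fixture(scope="session")
def tonic_run():
    """Full PING network with tonic inhibition 0.2*(-67 - v) on the E-cells."""
    cfg = V.tonic_config()
    raster = V.simulate_network(cfg)
    metrics = V.rhythm_metrics(raster, cfg)
    return cfg, raster, metrics
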