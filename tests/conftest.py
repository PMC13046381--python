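import numpy as np
import pytest
from hypothesis import settings

import polyforce as pf

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wlc_model():
    return pf.WLCModel(persistence_length=0.4, contour_length=100.0)


@pytest.fixture(scope="session")
def specai41_construct():
    return pf.construct_preset("specai41")


@pytest.fixture(scope="session")
def noiseless_protocol():
    return pf.PullingProtocol(speed=1000.0, noise_sigma=0.0, seed=42)


@pytest.fixture(scope="session")
def noiseless_trace(specai41_construct, noiseless_protocol):
    """One noise-free pulling trace of the standard construct."""
    return pf.simulate_trace(specai41_construct, noiseless_protocol)


@pytest.fixture(scope="session")
def analyzed_dataset(specai41_construct):
    """A small analyzed (noisy) dataset at the reference speed, unselected."""
    traces = pf.simulate_dfs_dataset(specai41_construct, [1000.0], 40, base_seed=7)
    return pf.analyze_dataset(traces, select=False)
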