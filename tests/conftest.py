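import numpy as np
import pytest

from cupcov.geometry import MeshQueries
from cupcov.pipeline import RunConfig, process_hip
from cupcov.synthetic import SyntheticHipParams, generate_hip


@pytest.fixture(scope="session")
def default_hip():
    """One synthetic hip with moderate per-quadrant deficiencies."""
    params = SyntheticHipParams(f_as=0.2, f_ai=0.1, f_ps=0.3, f_pi=0.1, seed=7)
    return generate_hip(params)


@pytest.fixture(scope="session")
def default_hip_queries(default_hip):
    return MeshQueries(default_hip.bone.mesh)


@pytest.fixture(scope="session")
def default_hip_result(default_hip, default_hip_queries):
    """Full pipeline output for the default hip."""
    return process_hip(default_hip.bone, RunConfig(), queries=default_hip_queries)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
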