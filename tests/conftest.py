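import numpy as np
import pytest

from chromodecomp.imaging import default_profile
from chromodecomp.optics import default_optics
from chromodecomp.render import ForwardRenderer


@pytest.fixture(scope="session")
def profile():
    return default_profile()


@pytest.fixture(scope="session")
def optics():
    return default_optics()


@pytest.fixture(scope="session")
def renderer(profile, optics):
    return ForwardRenderer(profile, optics)


@pytest.fixture(scope="session")
def benchmark_result(renderer):
    """The desk-scale self-supervised replication run, shared by the
    reconstruction-quality and parameter-recovery tests."""
    from chromodecomp.benchmark import run_benchmark

    return run_benchmark(seed=0, renderer=renderer)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
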