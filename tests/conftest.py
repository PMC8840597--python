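import numpy as np
import pytest

from opidyn.interactions import GeometricCriteria
from opidyn import synthetic as syn


@pytest.fixture(scope="session")
def criteria():
    return GeometricCriteria()


@pytest.fixture(scope="session")
def small_mor():
    """MOR-like conditions at reduced size: 2 replicates x 200 frames."""
    spec = syn.mor_spec(n_replicates=2, n_frames=200)
    template = syn.generate_template(spec)
    replicates, truth = syn.render_trajectory(template, spec)
    return spec, template, replicates, truth


@pytest.fixture(scope="session")
def template():
    return syn.generate_template(syn.mor_spec())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240919)
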