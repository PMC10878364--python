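import numpy as np
import pytest

from cpmkit.simulate import SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_signal_data():
    """A quickly generated dataset with a clear planted negative signal."""
    spec = SyntheticSpec(n_subjects=80, n_nodes=12, n_signal_edges=6,
                         signal_beta=-0.6, seed=11)
    return generate(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
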