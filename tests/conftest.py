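import numpy as np
import pytest

from pnnbrush.params import BrushConfig, ForceFieldParams


@pytest.fixture(scope="session")
def ff():
    return ForceFieldParams()


@pytest.fixture()
def small_config():
    """A miniature brush that builds and runs in well under a second."""
    return BrushConfig(
        d=3.0,
        grid_n=2,
        n_beads=11,
        n_equil_steps=200,
        n_prod_steps=400,
        dump_every=20,
        seed=0,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
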