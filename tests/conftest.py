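import numpy as np
import pytest

from pelkit.mm.pipeline import explore_dipeptide


@pytest.fixture(scope="session")
def ala_exploration():
    """Full alanine-dipeptide exploration on the built-in engine.

    Shared across thermodynamics/kinetics/pathway tests; built once because
    the saddle searches dominate the cost.
    """
    surface, net = explore_dipeptide("ALA", seed=1, bh_steps=10)
    return surface, net


@pytest.fixture(scope="session")
def ser_exploration():
    """Reduced serine exploration: trans minima only, no saddle searches."""
    surface, net = explore_dipeptide(
        "SER", seed=1, bh_steps=10, include_cis=False, connect=False
    )
    return surface, net


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
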