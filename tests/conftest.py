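import numpy as np
import pytest

from vesselseg.phantom import PRESETS, generate_phantom


@pytest.fixture(scope="session")
def easy_phantom():
    """One deterministic easy-preset phantom shared across tests."""
    import dataclasses

    return generate_phantom(dataclasses.replace(PRESETS["easy"], seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
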