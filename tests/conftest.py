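import numpy as np
import pytest

from phasefc import Connectome, generate_synthetic_connectome


@pytest.fixture
def toy3() -> Connectome:
    """Fully connected 3-node toy: all off-diagonal weights 0.5, distances 10 mm."""
    w = np.full((3, 3), 0.5)
    np.fill_diagonal(w, 0.0)
    d = np.full((3, 3), 10.0)
    np.fill_diagonal(d, 0.0)
    return Connectome(weights=w, distances=d)


@pytest.fixture(scope="session")
def human66() -> Connectome:
    """Bundled human-like synthetic connectome used across the suite."""
    return generate_synthetic_connectome(
        n=66, n_modules=6, weight_decades=5, decay_length_mm=40.0, seed=1
    )
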