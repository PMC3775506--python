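import numpy as np
import pytest

from mbpnet import GridSpec, TuningProperties, assemble_population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_tuning(rng):
    """A modest excitatory tuning table (400 neurons on a 4x4 cell grid)."""
    spec = GridSpec(n_cells=16, n_speeds=5, n_angles=5)
    return assemble_population(spec, 400, rng)


@pytest.fixture
def toy_tuning():
    """Three hand-placed neurons: a rightward mover, one ahead, one behind."""
    return TuningProperties(
        x=np.array([0.5, 0.7, 0.3]),
        y=np.array([0.5, 0.5, 0.5]),
        u=np.array([0.5, 0.5, 0.5]),
        v=np.array([0.0, 0.0, 0.0]),
    )
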