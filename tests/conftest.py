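import numpy as np
import pytest

from spikedet.synth import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scenes():
    """Eight small rendered field scenes shared across tests."""
    return [generate_scene(SceneSpec(canvas=(320, 320), n_spikes=12,
                                     length_range=(30, 60),
                                     width_range=(10, 18),
                                     overlap_target=0.25, rng_seed=100 + s))
            for s in range(8)]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
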