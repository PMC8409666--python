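import warnings

import numpy as np
import pytest

from gadseg.phantom import PhantomSpec, generate_phantom

# Small phantoms deliberately differ from the nominal 64x256x256 grid; the
# advisory warning is noise in tests.
warnings.filterwarnings("ignore", message="volume shape .* differs from nominal")


@pytest.fixture(scope="session")
def small_phantom():
    """One 32x64x64 phantom with three large lesions (one ring-enhancing)."""
    spec = PhantomSpec(shape=(32, 64, 64), n_lesions=3,
                       size_groups=(("51-100", 2), (">100", 1)),
                       ring_fraction=1.0, seed=11)
    return generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
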