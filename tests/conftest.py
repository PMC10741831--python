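import numpy as np
import pytest

from rms.phantom import PhantomSpec, render_phantom_sequence


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def small_spec():
    """32x32 phantom spec for fast unit tests (native network resolution)."""
    return PhantomSpec(image_size=(32, 32), pixel_spacing_mm=8.0)


@pytest.fixture(scope="session")
def default_case(default_spec):
    return render_phantom_sequence(default_spec, seed=11)


@pytest.fixture(scope="session")
def small_case(small_spec):
    return render_phantom_sequence(small_spec, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
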