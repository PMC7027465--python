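import numpy as np
import pytest

from fragsim import ResourceFieldSpec, TorusLandscape, make_landscape


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def neutral_spec():
    return ResourceFieldSpec(n_types=1, amplitude=0.0)


@pytest.fixture
def small_landscape():
    """Four fragments, 4% cover, habitable matrix on a 30x30 torus."""
    return make_landscape(N=4, C=0.04, V=30.0, seed=7)


@pytest.fixture
def intact_landscape(neutral_spec):
    return TorusLandscape(V=20.0, fragments=[], matrix_mode="habitable",
                          resource_spec=neutral_spec, intact=True)
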