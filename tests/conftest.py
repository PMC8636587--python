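import numpy as np
import pytest

from limbtorsion.phantom import PhantomSpec, generate_phantom

# compact grid used across landmark/torsion tests: 96 mm in-plane, 16 slices
SMALL = dict(shape=(96, 96, 16), spacing=(1.0, 1.0, 6.5))


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless right-sided phantom, 15 deg femoral / 30 deg tibial torsion."""
    return generate_phantom(PhantomSpec(femoral_torsion=15.0, tibial_torsion=30.0,
                                        **SMALL))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_phantom(**kwargs):
    params = {**SMALL, **kwargs}
    return generate_phantom(PhantomSpec(**params))
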