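import numpy as np
import pytest

from redpiranha.core import ObjectiveSpec, Sense
from redpiranha.objectives import example_quadratic, sphere
from redpiranha.rng import RandomStream


@pytest.fixture
def rng():
    return RandomStream(12345)


@pytest.fixture
def quadratic_spec():
    """The worked example's convex quadratic on [-5, 5]^2."""
    return ObjectiveSpec(
        dimension=2,
        lower=np.array([-5.0, -5.0]),
        upper=np.array([5.0, 5.0]),
        objective=example_quadratic,
        sense=Sense.MINIMIZE,
    )


@pytest.fixture
def sphere_spec():
    return ObjectiveSpec(
        dimension=2,
        lower=np.array([-5.12, -5.12]),
        upper=np.array([5.12, 5.12]),
        objective=sphere,
        sense=Sense.MINIMIZE,
    )
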