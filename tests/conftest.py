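import numpy as np
import pytest

from strainfit.param_space import SubsetMask, build_default_registry, build_demo_registry
from strainfit.synthetic_cohort import make_cohort
from strainfit.toy_model import ToyModel


@pytest.fixture(scope="session")
def full_space():
    return build_default_registry()


@pytest.fixture(scope="session")
def demo_space():
    return build_demo_registry()


@pytest.fixture(scope="session")
def demo_model(demo_space):
    return ToyModel(demo_space)


@pytest.fixture(scope="session")
def full_model(full_space):
    return ToyModel(full_space)


@pytest.fixture(scope="session")
def demo_cohort(demo_model):
    """Ten virtual subjects at default study conditions, fixed seed."""
    return make_cohort(demo_model, 10, rng=np.random.default_rng(42))


@pytest.fixture()
def demo_full_mask(demo_space):
    return SubsetMask.full(demo_space)
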