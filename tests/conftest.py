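import numpy as np
import pytest

from mitseg.datapipe import tile
from mitseg.fixtures import FixtureRecipe, generate_dataset, generate_specimen
from mitseg.model_config import TINY_SPEC_OVERRIDES, resolve_spec
from mitseg.network import SegFormer


@pytest.fixture(scope="session")
def tiny_spec():
    return resolve_spec("mit-b0", TINY_SPEC_OVERRIDES)


@pytest.fixture(scope="session")
def tiny_model(tiny_spec):
    return SegFormer(tiny_spec, seed=0)


@pytest.fixture(scope="session")
def fixture_specimen():
    return generate_specimen(FixtureRecipe(seed=0))


@pytest.fixture(scope="session")
def small_tiles():
    """Eight 64x64 labeled tiles from synthetic specimens."""
    specimens = generate_dataset(8, seed=7, size=(64, 64))
    return [tile(s, size=64, rescale_to=64)[0] for s in specimens]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
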