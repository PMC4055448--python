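import numpy as np
import pytest

from oligomod.fixtures import generate_fixtures

# re-exported for test modules
from .oracles import random_hmm, random_profile, random_sequence  # noqa: F401

FIXTURE_SEED = 17


@pytest.fixture(scope="session")
def fixture_tree(tmp_path_factory):
    """The full synthetic fixture set, generated once per session."""
    out = tmp_path_factory.mktemp("fixtures")
    manifest = generate_fixtures(FIXTURE_SEED, out)
    return out, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(20240612)
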