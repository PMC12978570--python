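import numpy as np
import pytest

from reefclr.studies import three_archetype_recipe
from reefclr.synth import build_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Small 3-archetype synthetic dataset shared across test modules."""
    out = tmp_path_factory.mktemp("synth")
    manifest = build_dataset([three_archetype_recipe()], 6, out, rng_seed=7)
    return manifest, out


def random_unit_vectors(rng, n, d):
    x = rng.normal(size=(n, d))
    return x / np.linalg.norm(x, axis=1, keepdims=True)
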