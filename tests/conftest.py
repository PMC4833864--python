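import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20160419)


@pytest.fixture
def random_pair(rng):
    """A pair of well-behaved random matrices with shared IDs."""
    from mancie import OmicsMatrix

    n_feat, n_samp = 50, 8
    feats = [f"f{i}" for i in range(n_feat)]
    samples = [f"s{j}" for j in range(n_samp)]
    main = OmicsMatrix(feats, samples, rng.normal(size=(n_feat, n_samp)))
    shared = rng.normal(size=(n_feat, n_samp))
    assoc_vals = 0.7 * shared + 0.7 * main.values + 0.4 * rng.normal(size=(n_feat, n_samp))
    assoc = OmicsMatrix(feats, samples, assoc_vals)
    return main, assoc
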