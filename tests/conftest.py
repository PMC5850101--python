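import numpy as np
import pytest
from hypothesis import settings

import rmqsar as rq

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def clean_spec(**kwargs) -> rq.SyntheticSpec:
    """A SyntheticSpec without contamination columns, for fixtures where
    only the planted signal matters."""
    defaults = dict(collinear_block_count=0, frac_constant=0.0,
                    frac_near_constant=0.0, frac_missing_cols=0.0,
                    frac_binary=0.0)
    defaults.update(kwargs)
    return rq.SyntheticSpec(**defaults)


@pytest.fixture(scope="session")
def planted_small():
    """80 compounds, 20-column clean pool, 3 planted descriptors, mild noise."""
    spec = clean_spec(n_compounds=80, n_descriptors=20, n_signal=3,
                      noise_sd=0.3, seed=7)
    dm, act, truth = rq.generate(spec)
    return dm, act, truth


@pytest.fixture(scope="session")
def planted_noiseless():
    spec = clean_spec(n_compounds=60, n_descriptors=12, n_signal=2,
                      noise_sd=0.0, seed=3)
    return rq.generate(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
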