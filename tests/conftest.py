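import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from polyswitch.synthetic_data import (
    ScreenFixtureParams,
    gen_reference,
    gen_screen_dataset,
)


@pytest.fixture(scope="session")
def small_params() -> ScreenFixtureParams:
    """A miniature screen fixture for fast unit tests."""
    return ScreenFixtureParams(
        n_contigs=1,
        genes_per_contig=8,
        gene_length_mean=450,
        intergenic_mean=1500,
        causal_gene_index=3,
        n_background_variants=3.0,
        shared_parental_variants=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_reference(small_params):
    return gen_reference(small_params)


@pytest.fixture(scope="session")
def small_dataset(small_params, small_reference):
    return gen_screen_dataset(small_reference, small_params)


@pytest.fixture(scope="session")
def default_dataset():
    """One realisation of the full-scale default screen fixture."""
    params = ScreenFixtureParams(seed=0)
    return gen_screen_dataset(gen_reference(params), params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
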