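import numpy as np
import pytest

from utrhotspots import pipeline as pl
from utrhotspots import synthetic_data as syn


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic dataset shared across tests."""
    return syn.generate(syn.SyntheticConfig(n_genes=120, rng_seed=42))


@pytest.fixture(scope="session")
def small_analysis(small_dataset):
    """Expression, profiles and positive-cluster footprints for it."""
    params = pl.PipelineParams(seed=42, n_sims=200)
    expr, expressed = pl.expression_stage(small_dataset, params)
    profiles = pl.profile_stage(small_dataset, expressed, params)
    footprints = pl.positive_clusters(small_dataset, profiles, expressed, params)
    centers = pl.footprint_centers(footprints)
    return {
        "params": params,
        "expressed": expressed,
        "profiles": profiles,
        "footprints": footprints,
        "centers": centers,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
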