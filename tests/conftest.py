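import logging

import numpy as np
import pytest

from rvcluster import GenotypePanel, PhenotypeVector, SimulationConfig

logging.getLogger("rvcluster").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20140415)


@pytest.fixture
def small_panel():
    """Hand-built 8-subject, 3-site panel with positions 100, 5100, 19000."""
    counts = np.array([
        [1, 0, 0],
        [0, 1, 0],
        [1, 0, 1],
        [0, 0, 0],
        [0, 1, 0],
        [0, 0, 0],
        [1, 0, 0],
        [0, 0, 1],
    ])
    return GenotypePanel([f"s{i}" for i in range(8)], ["v1", "v2", "v3"],
                         [100, 5100, 19000], counts)


@pytest.fixture
def small_pheno():
    return PhenotypeVector([1, 1, 1, 1, 0, 0, 0, 0])


def tiny_sim_config(seed=0, par=0.0, n_protective=0, n_deleterious=3,
                    clustered=True):
    """A miniature simulation config for fast end-to-end runs."""
    return SimulationConfig(
        H=400, region_length=5000, n_sites=30, n_causal=n_protective + n_deleterious,
        clustered=clustered, cluster_span=2500, n_protective=n_protective,
        n_deleterious=n_deleterious, par=par, f0=0.05, n_cases=30, n_controls=30,
        seed=seed)
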