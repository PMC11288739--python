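import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))  # makes oracles.py importable

from bulkmapper import (
    CausalSpec,
    ChromosomeConfig,
    MappingParams,
    SimConfig,
    make_fixture,
)


def two_bulk_configs(n_decoys: int = 25, n_mutant_pool: int = 200,
                     seed_a: int = 11, seed_b: int = 12):
    """Study-profile configs for the two-mutation mutual-control dataset."""
    chroms = tuple(
        ChromosomeConfig(name=f"chr{i}H", length_bp=2_000_000, n_markers=4000,
                         map_length_morgans=1.2)
        for i in (1, 2, 3)
    )
    config_a = SimConfig(
        chromosomes=chroms,
        causal=CausalSpec("chr1H", 400_000, "geneJ", "nonsense"),
        bulk_name="bulkJ", n_mutant_pool=n_mutant_pool, n_decoys=n_decoys,
        seed=seed_a,
    )
    config_b = SimConfig(
        chromosomes=chroms,
        causal=CausalSpec("chr2H", 1_300_000, "geneL", "missense"),
        bulk_name="bulkL", n_mutant_pool=n_mutant_pool, n_decoys=n_decoys,
        seed=seed_b,
    )
    return config_a, config_b


@pytest.fixture(scope="session")
def fixture_params():
    """Mapping parameters matched to the packaged 4000-marker test panels."""
    return MappingParams(window_k=250)


@pytest.fixture(scope="session")
def two_bulk_fixture(tmp_path_factory):
    """Session-wide synthetic two-bulk dataset (25 decoys per bulk)."""
    out = tmp_path_factory.mktemp("two_bulk")
    config_a, config_b = two_bulk_configs()
    paths = make_fixture(config_a, config_b, str(out))
    paths["configs"] = (config_a, config_b)
    return paths


@pytest.fixture()
def rng():
    return np.random.default_rng(20240417)
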