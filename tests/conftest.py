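import numpy as np
import pandas as pd
import pytest

from regevol import SimulationConfig, simulate_experiment
from regevol.containers import (
    ROLE_HYBRID1,
    ROLE_HYBRID2,
    ROLE_PARENT1,
    ROLE_PARENT2,
    allele_table_from_pairs,
)

MIXED_PROPORTIONS = {
    "conserved": 0.4,
    "all_cis": 0.15,
    "all_trans": 0.15,
    "cis_plus_trans": 0.1,
    "cis_times_trans": 0.1,
    "compensatory": 0.1,
}


@pytest.fixture(scope="session")
def small_experiment():
    """A 300-gene mixed-architecture comparison reused across tests."""
    cfg = SimulationConfig(
        n_genes=300,
        library_size=600_000,
        architecture_proportions=MIXED_PROPORTIONS,
        n_mito_genes=3,
        seed=42,
    )
    return cfg, simulate_experiment(cfg)


@pytest.fixture()
def tiny_allele_table():
    """Three genes, parents + reciprocal hybrids, hand-set counts."""
    pairs = {
        "p1": (np.array([120, 60, 40]), np.array([0, 0, 0])),
        "p2": (np.array([0, 0, 0]), np.array([80, 60, 10])),
        "h1": (np.array([90, 30, 25]), np.array([30, 30, 20])),
        "h2": (np.array([85, 31, 24]), np.array([35, 29, 21])),
    }
    roles = {
        "p1": ROLE_PARENT1,
        "p2": ROLE_PARENT2,
        "h1": ROLE_HYBRID1,
        "h2": ROLE_HYBRID2,
    }
    return allele_table_from_pairs(pd.Index(["ga", "gb", "gc"], name="gene_id"), pairs, roles)
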