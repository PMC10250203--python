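"""Shared fixtures: one seeded synthetic genome collection per session.

The default generator profile (20 genomes of one species, two
marker-flanked hotspots with occupancy 0.8 / 0.15, 10 system types,
planted decoys, cargo GC offset -0.06, a Yule phylogeny) is the study
condition every integration test scores against.
"""

import numpy as np
import pytest

from cdhsfinder.search_reduce import cluster_proteins, filter_hits
from cdhsfinder.synthetic_data import SimConfig, mock_hits, simulate
from cdhsfinder.system_caller import call_systems

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def sim():
    """(GenomeDB, GroundTruth) for the default profile."""
    return simulate(SimConfig(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def sim_db(sim):
    return sim[0]


@pytest.fixture(scope="session")
def sim_truth(sim):
    return sim[1]


@pytest.fixture(scope="session")
def sim_calls(sim):
    db, truth = sim
    hits = filter_hits(mock_hits(db, truth, n_noise=100, seed=3))
    return call_systems(hits, db, truth.definitions)


@pytest.fixture(scope="session")
def sim_cluster_index(sim_db):
    return cluster_proteins(sim_db.proteins())


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_nt(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def mutate_nt(rng, seq, rate):
    """Uniform substitution at per-base ``rate`` (any of the 3 other bases)."""
    bases = np.array(list("ACGT"))
    arr = np.array(list(seq))
    mask = rng.random(arr.size) < rate
    idx = np.searchsorted(bases, arr[mask])
    arr[mask] = bases[(idx + rng.integers(1, 4, mask.sum())) % 4]
    return "".join(arr)
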