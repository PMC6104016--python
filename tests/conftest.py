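"""Shared fixtures: toy taxonomies, synthetic genomes, and small databases.

Everything is generated programmatically with fixed seeds; nothing is read
from disk except files the tests themselves write to tmp paths.
"""

from __future__ import annotations

import numpy as np
import pytest

import markovbin as mb


@pytest.fixture(scope="session")
def divergent_pair():
    """Two genomes from independent order-1 chains (different phyla):
    the easy, well-separated classification fixture."""
    lineages, specs = mb.make_toy_taxonomy(
        n_phyla=2, genera_per_phylum=1, species_per_genus=1, seed=11, divergence=0.0
    )
    genomes = mb.realize_genomes(specs, length=30_000, seed=7)
    return lineages, genomes


@pytest.fixture(scope="session")
def divergent_pair_db(divergent_pair):
    lineages, genomes = divergent_pair
    return mb.build_database(genomes, lineages, k=5, pseudocount=1.0)


@pytest.fixture(scope="session")
def congener_trio():
    """Three genomes: two congeneric species with similar chains plus one
    distant genome in another phylum. Used for nearest-relative tests."""
    lineages, specs = mb.make_toy_taxonomy(
        n_phyla=2, genera_per_phylum=1, species_per_genus=2, seed=3, divergence=0.1
    )
    keep = ["p1.g1.s1", "p1.g1.s2", "p2.g1.s1"]
    specs = [s for s in specs if s.genome_id in keep]
    lineages = {gid: lineages[gid] for gid in keep}
    genomes = mb.realize_genomes(specs, length=30_000, seed=9)
    return lineages, genomes


@pytest.fixture(scope="session")
def congener_trio_db(congener_trio):
    lineages, genomes = congener_trio
    return mb.build_database(genomes, lineages, k=5, pseudocount=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_toy_model(rng, k: int, genome_id: str = "toy") -> mb.TransitionModel:
    """A transition model built from a random sequence (valid by construction)."""
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    return mb.build_transition_model(seq, k=k, pseudocount=1.0, genome_id=genome_id)
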