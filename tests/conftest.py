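"""Shared fixtures.

The expensive session fixtures (56-bead minima database) are built once
and reused by the reconstruction benchmark, physicality-split and
pathway-clustering tests.
"""

import numpy as np
import pytest

from gdsfold.bln import BeadSequence, Conformation
from gdsfold.fixtures import (build_minima_database, extended_chain,
                              make_toy_protein, toy_protein_parameters)


@pytest.fixture(scope="session")
def toy_protein():
    """(sequence, hairpin ranges, parameters) of the 56-bead fixture."""
    seq, ranges = make_toy_protein()
    return seq, ranges, toy_protein_parameters()


@pytest.fixture(scope="session")
def minima_db(toy_protein):
    """Seeded annealing-with-restarts minima database (scaled-down stop
    criterion to keep the suite fast; the acceptance script uses the full
    protocol)."""
    seq, _, params = toy_protein
    db = build_minima_database(seq, params, n_restarts=40, stop_after=10,
                               seed=42)
    assert len(db) >= 5
    return db


@pytest.fixture()
def small_sequence():
    return BeadSequence("BLNBLNBLNB", "HETHETH")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_conformation(small_sequence, rng):
    """Well-separated random 10-bead conformation (no LJ singularities)."""
    coords = extended_chain(10).coords + rng.normal(scale=0.3, size=(10, 3))
    return Conformation(coords)
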