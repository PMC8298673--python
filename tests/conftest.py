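"""Shared fixtures: synthetic isomer families and pre-trained models.

Everything is generated programmatically at test time; there are no data
files.  Session scope keeps the suite fast — the generators and models are
deterministic, so sharing them across tests loses nothing.
"""

from __future__ import annotations

import numpy as np
import pytest

from graph2struct import (
    MoleculeStructureModel,
    generate_crystal_fixtures,
    generate_fixture_family,
    load_radii_table,
)

# lambda -> 0 hyperparameters for interpolation-style checks
INTERP_HYPERS = ("laplacian", 5.0, 1e-10)


@pytest.fixture(scope="session")
def radii():
    return load_radii_table()


@pytest.fixture(scope="session")
def family_small():
    """30 seven-heavy-atom C6O constitutional isomers (trees)."""
    return generate_fixture_family(7, {"C": 6, "O": 1}, 30, seed=3)


@pytest.fixture(scope="session")
def family_nine():
    """320 nine-heavy-atom C7O2 constitutional isomers (trees)."""
    return generate_fixture_family(9, {"C": 7, "O": 2}, 320, seed=7)


@pytest.fixture(scope="session")
def mixed_graphs(family_small, family_nine):
    """50 graphs of mixed size/stoichiometry for invariance sweeps."""
    extra = generate_fixture_family(5, {"C": 4, "O": 1}, 5, seed=5)
    graphs = (
        [g for g, _ in family_small[:15]]
        + [g for g, _ in family_nine[:30]]
        + [g for g, _ in extra]
    )
    assert len(graphs) == 50
    return graphs


@pytest.fixture(scope="session")
def crystals():
    """500 synthetic elpasolite records, lattice noise 0.1 A."""
    return generate_crystal_fixtures(500, seed=11, noise_scale=0.1)


@pytest.fixture(scope="session")
def interp_results(family_small):
    """Model trained at lambda->0 on the small family (interpolation regime)."""
    model = MoleculeStructureModel(family_small, scheme="bond_length")
    return model, model.fit(hyperparameters=INTERP_HYPERS)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
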