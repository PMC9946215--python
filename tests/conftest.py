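"""Shared fixtures: hand-built micro metacommunities and assembled toys."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from lvmcm.dynamics import DispersalMatrix, Metacommunity
from lvmcm.landscape import Landscape
from lvmcm.orchestration import make_fixture
from lvmcm.species_pool import SpeciesPool


def build_state(growth, interactions, biomass, coords=None, adjacency=None,
                dispersal_matrix=None, emigration_rate=0.1,
                dispersal_length=1.0, lam=None, lam_prime=None,
                areas=None, env=None, side_length=None):
    """Assemble a Metacommunity from raw matrices (no sampling involved).

    Defaults give sites on a line with unit spacing, no dispersal, and
    unscaled interactions (lam = lam' = 1).
    """
    growth = np.atleast_2d(np.asarray(growth, dtype=float))
    s, n = growth.shape
    biomass = np.atleast_2d(np.asarray(biomass, dtype=float))
    interactions = np.asarray(interactions, dtype=float)
    if coords is None:
        coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    distances = squareform(pdist(coords)) if n > 1 else np.zeros((1, 1))
    if adjacency is None:
        adjacency = np.zeros((n, n), dtype=np.int8)
    if areas is None:
        areas = np.ones(n)
    if env is None:
        env = np.zeros((1, n))
    ls = Landscape(coords=coords, side_length=side_length or float(max(n, 1)),
                   adjacency=np.asarray(adjacency), distances=distances,
                   env=np.atleast_2d(env), areas=np.asarray(areas, dtype=float))
    if dispersal_matrix is None:
        dispersal_matrix = np.zeros((n, n))
    disp = DispersalMatrix(matrix=np.asarray(dispersal_matrix, dtype=float),
                           emigration_rate=emigration_rate,
                           dispersal_length=dispersal_length,
                           degrees=np.asarray(adjacency).sum(axis=1))
    return Metacommunity(
        landscape=ls,
        pool=SpeciesPool(optima=np.zeros((s, 1)), interactions=interactions,
                         niche_width=1.0),
        dispersal=disp,
        growth=growth,
        biomass=biomass,
        lam=np.ones(n) if lam is None else np.asarray(lam, dtype=float),
        lam_prime=np.ones(n) if lam_prime is None else np.asarray(lam_prime, dtype=float),
        species_ids=np.arange(s, dtype=np.int64),
        next_species_id=s,
    )


@pytest.fixture(scope="session")
def toy_metacommunity():
    """Small pre-assembled 6-site metacommunity (deterministic seed)."""
    mc, log = make_fixture("toy_metacommunity", rng_seed=7)
    return mc, log
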