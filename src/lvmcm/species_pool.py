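"""Species generation: environmental optima, growth rates, interaction matrix.

Each species i responds to the K environmental variables through a quadratic
(Hutchinsonian) niche with common width w:

    R_ix = 1 - (2/w)^2 * sum_k (E_kx - Eopt_ik)^2

so R peaks at 1 when the site matches the optimum on every axis and crosses
zero when the total deviation reaches w/2. Optima are uniform on
[1.25*min_x E_kx, 1.25*max_x E_kx] per axis; interspecific competition
coefficients are 0.3 with probability 0.3 and 0 otherwise (hollow matrix,
self-regulation is carried separately by the identity term of A = I + A0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import _as_rng

__all__ = ["SpeciesPool", "sample_optima", "growth_rates", "sample_interactions"]

INTERACTION_STRENGTH = 0.3
INTERACTION_PROB = 0.3


@dataclass
class SpeciesPool:
    optima: np.ndarray        # (S, K)
    interactions: np.ndarray  # (S, S) hollow
    niche_width: float

    @property
    def n_species(self) -> int:
        return self.optima.shape[0]


def sample_optima(env: np.ndarray, n_species: int, rng_seed=None) -> np.ndarray:
    """Uniform optima in [1.25*min_x E_kx, 1.25*max_x E_kx], per species and axis."""
    rng = _as_rng(rng_seed)
    env = np.atleast_2d(env)
    lo = 1.25 * env.min(axis=1)
    hi = 1.25 * env.max(axis=1)
    return rng.uniform(lo, hi, size=(n_species, env.shape[0]))


def growth_rates(env: np.ndarray, optima: np.ndarray, niche_width: float,
                 niche_coefficient: str = "inverse") -> np.ndarray:
    """Quadratic niche growth rates R (S x N); may be negative.

    ``niche_coefficient`` selects the reading of the quadratic coefficient:
    "inverse" (default) uses (2/w)^2 so that large w means broad niches;
    "direct" uses (2w)^2, inverting the niche-width semantics.
    """
    if niche_width <= 0:
        raise ValueError("niche_width must be > 0")
    env = np.atleast_2d(env)          # (K, N)
    optima = np.atleast_2d(optima)    # (S, K)
    dev2 = ((env[None, :, :] - optima[:, :, None]) ** 2).sum(axis=1)  # (S, N)
    if niche_coefficient == "inverse":
        coeff = (2.0 / niche_width) ** 2
    elif niche_coefficient == "direct":
        coeff = (2.0 * niche_width) ** 2
    else:
        raise ValueError(f"unknown niche_coefficient {niche_coefficient!r}")
    return 1.0 - coeff * dev2


def sample_interactions(n_species: int, rng_seed=None,
                        strength: float = INTERACTION_STRENGTH,
                        prob: float = INTERACTION_PROB) -> np.ndarray:
    """Hollow S x S matrix; off-diagonal entries are `strength` w.p. `prob`, else 0."""
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = _as_rng(rng_seed)
    a = np.where(rng.random((n_species, n_species)) < prob, strength, 0.0)
    np.fill_diagonal(a, 0.0)
    return a
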