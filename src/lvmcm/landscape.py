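"""Spatial arena: site coordinates, Gabriel graph, environment, areas.

The metacommunity lives on ``N`` sites scattered uniformly in a square box of
side ``L = N``. Nearby sites are linked by a Gabriel graph (edge iff no third
site falls inside the closed disc with the edge as diameter), which yields a
connected random planar network for points in general position. Each site
carries ``K`` environmental variables drawn jointly from a zero-mean,
unit-variance Gaussian random field with isotropic covariance over the site
coordinates, and an area ``a_x`` (biomass units, reference ``a0 = 1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Landscape",
    "sample_coordinates",
    "gabriel_graph",
    "sample_environment",
    "assign_areas",
    "generate_landscape",
    "equirectangular_projection",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class Landscape:
    """Immutable description of the spatial arena.

    Attributes
    ----------
    coords : (N, 2) array
        Site coordinates in the box ``[0, L]^2`` (or arbitrary planar
        coordinates for empirical landscapes).
    side_length : float
        Box side ``L``; distance statistics are reported as fractions of L.
    adjacency : (N, N) int array
        Symmetric 0/1 Gabriel adjacency, zero diagonal.
    distances : (N, N) array
        Euclidean inter-site distances.
    env : (K, N) array
        Environmental variables ``E_kx`` (one GRF realisation per row).
    areas : (N,) array
        Site areas ``a_x > 0``.
    corr_length : float
        GRF correlation length used to generate ``env``.
    """

    coords: np.ndarray
    side_length: float
    adjacency: np.ndarray
    distances: np.ndarray
    env: np.ndarray
    areas: np.ndarray
    corr_length: float = 1.0

    @property
    def n_sites(self) -> int:
        return self.coords.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def is_connected(self) -> bool:
        n = self.n_sites
        seen = np.zeros(n, dtype=bool)
        stack = [0]
        seen[0] = True
        while stack:
            x = stack.pop()
            for y in np.flatnonzero(self.adjacency[x]):
                if not seen[y]:
                    seen[y] = True
                    stack.append(y)
        return bool(seen.all())

    def drop_site(self, site: int) -> "Landscape":
        """Landscape with one site and all its edges deleted.

        Remaining edges are kept as-is (never recomputed), matching the
        removal-experiment protocol where only incident edges disappear.
        """
        n = self.n_sites
        if n < 2:
            raise ValueError("cannot remove the last site")
        keep = np.ones(n, dtype=bool)
        keep[site] = False
        return Landscape(
            coords=self.coords[keep],
            side_length=self.side_length,
            adjacency=self.adjacency[np.ix_(keep, keep)],
            distances=self.distances[np.ix_(keep, keep)],
            env=self.env[:, keep],
            areas=self.areas[keep],
            corr_length=self.corr_length,
        )


def sample_coordinates(n_sites: int, rng_seed=None) -> tuple[np.ndarray, float]:
    """Uniform site coordinates in ``[0, N]^2``; returns (coords, L=N)."""
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    rng = _as_rng(rng_seed)
    side = float(n_sites)
    coords = rng.uniform(0.0, side, size=(n_sites, 2))
    return coords, side


def _gabriel_brute(coords: np.ndarray, d2: np.ndarray) -> np.ndarray:
    n = coords.shape[0]
    adj = np.zeros((n, n), dtype=np.int8)
    for x in range(n):
        for y in range(x + 1, n):
            ok = True
            for z in range(n):
                if z == x or z == y:
                    continue
                if d2[x, y] >= d2[x, z] + d2[z, y]:
                    ok = False
                    break
            if ok:
                adj[x, y] = adj[y, x] = 1
    return adj


def gabriel_graph(coords: np.ndarray) -> np.ndarray:
    """Gabriel adjacency: edge (x,y) iff d(x,y)^2 < d(x,z)^2 + d(z,y)^2 for all z.

    The strict inequality excludes points on the closed disc boundary. The
    Gabriel graph is a subgraph of the Delaunay triangulation, so candidate
    edges are taken from scipy's Delaunay and filtered by the disc condition;
    degenerate inputs (collinear, tiny N) fall back to the O(N^3) check.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    d2 = squareform(pdist(coords)) ** 2
    offdiag = d2[~np.eye(n, dtype=bool)]
    if offdiag.min() == 0.0:
        raise ValueError("duplicate coordinates: Gabriel disc undefined")
    if n < 4:
        return _gabriel_brute(coords, d2)
    try:
        tri = Delaunay(coords)
    except QhullError:
        return _gabriel_brute(coords, d2)
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = simplex[i], simplex[(i + 1) % 3]
            edges.add((min(a, b), max(a, b)))
    adj = np.zeros((n, n), dtype=np.int8)
    idx = np.arange(n)
    for x, y in edges:
        others = idx[(idx != x) & (idx != y)]
        if np.all(d2[x, y] < d2[x, others] + d2[others, y]):
            adj[x, y] = adj[y, x] = 1
    return adj


def sample_environment(
    coords: np.ndarray,
    k_vars: int = 1,
    corr_length: float = 1.0,
    rng_seed=None,
    kernel: str = "exponential",
) -> np.ndarray:
    """Draw K independent GRF realisations at the site coordinates.

    Marginals are N(0, 1); the spatial covariance between sites at distance d
    is ``exp(-d/rho)`` (exponential kernel, default) or ``exp(-(d/rho)^2/2)``
    (squared-exponential), with correlation length ``rho = corr_length``.
    Sampling is exact: a joint multivariate normal via Cholesky factorisation
    of the N x N covariance (with escalating diagonal jitter if needed).
    """
    if corr_length <= 0:
        raise ValueError("corr_length must be > 0")
    rng = _as_rng(rng_seed)
    coords = np.asarray(coords, dtype=float)
    d = squareform(pdist(coords))
    if kernel == "exponential":
        cov = np.exp(-d / corr_length)
    elif kernel == "gaussian":
        cov = np.exp(-0.5 * (d / corr_length) ** 2)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    n = coords.shape[0]
    chol = None
    for jitter in (0.0, 1e-12, 1e-10, 1e-8, 1e-6):
        try:
            chol = np.linalg.cholesky(cov + jitter * np.eye(n))
            break
        except np.linalg.LinAlgError:
            continue
    if chol is None:
        raise np.linalg.LinAlgError("GRF covariance not positive definite after jitter")
    z = rng.standard_normal(size=(k_vars, n))
    return z @ chol.T


def assign_areas(n_sites: int, a_min: float = 1.0, a_max: float = 30.0, rng_seed=None) -> np.ndarray:
    """Arithmetic progression of areas from a_min to a_max, shuffled over sites."""
    if a_min <= 0 or a_max < a_min:
        raise ValueError("need 0 < a_min <= a_max")
    rng = _as_rng(rng_seed)
    areas = np.linspace(a_min, a_max, n_sites)
    return rng.permutation(areas)


def generate_landscape(
    n_sites: int,
    k_vars: int = 1,
    corr_length: float = 1.0,
    a_min: float = 1.0,
    a_max: float = 30.0,
    rng_seed=None,
    kernel: str = "exponential",
    require_connected: bool = True,
    max_tries: int = 100,
) -> Landscape:
    """Sample a complete random landscape; redraws coordinates if the Gabriel
    graph comes out disconnected (rare for uniform points in general position)."""
    rng = _as_rng(rng_seed)
    for _ in range(max_tries):
        coords, side = sample_coordinates(n_sites, rng)
        adj = gabriel_graph(coords)
        env = sample_environment(coords, k_vars, corr_length, rng, kernel=kernel)
        areas = assign_areas(n_sites, a_min, a_max, rng)
        ls = Landscape(
            coords=coords,
            side_length=side,
            adjacency=adj,
            distances=squareform(pdist(coords)),
            env=env,
            areas=areas,
            corr_length=corr_length,
        )
        if not require_connected or ls.is_connected():
            return ls
    raise RuntimeError("failed to draw a connected Gabriel graph")


EARTH_RADIUS_KM = 6371.0


def equirectangular_projection(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Project geographic coordinates (decimal degrees) to planar km about the centroid."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    lat0 = np.deg2rad(lat.mean())
    x = EARTH_RADIUS_KM * np.cos(lat0) * np.deg2rad(lon - lon.mean())
    y = EARTH_RADIUS_KM * np.deg2rad(lat - lat.mean())
    return np.column_stack([x, y])
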