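"""Occupancy frequency distributions and the empirical-fitting bridge.

The LVMCM is too parameter-rich for direct fitting, so matching simulations
to empirical species-by-site tables goes through a one-parameter patch
occupancy model. A species occupying n of N sites gains sites by internal
colonisation at rate b(n) = m * n(N-n)/(N-1) and loses them at rate
d(n) = n (local extinction sets the time unit); external invaders enter the
region at single-site occupancy at a constant rate. The stationary expected
number of species at occupancy n is then

    p(n) ∝ (1/d(n)) * prod_{k=1}^{n-1} b(k)/d(k)
         = (1/n) * m^(n-1) * (N-1)! / ((N-n)! (N-1)^(n-1))

The mixing rate m — the ratio of internal colonisation to external invasion
— is fitted to an observed OFD by multinomial maximum likelihood, and the
LVMCM niche width w is chosen so that simulations on the empirical landscape
reproduce the empirical mixing rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .dynamics import EXTINCTION_THRESHOLD
from .landscape import Landscape, equirectangular_projection, gabriel_graph

__all__ = [
    "OFD", "MixingFit", "EmpiricalDataset",
    "compute_ofd", "occupancy_model_ofd", "fit_mixing_rate",
    "ingest_empirical", "pool_nearby_sites", "empirical_landscape",
    "fit_niche_width",
]


@dataclass
class OFD:
    counts: np.ndarray   # counts[n-1] = number of species occupying exactly n sites
    n_sites: int

    @property
    def n_species(self) -> int:
        return int(self.counts.sum())


@dataclass
class MixingFit:
    m: float
    loglik: float
    predicted_ofd: np.ndarray


@dataclass
class EmpiricalDataset:
    abundance: pd.DataFrame    # S x N (rows species, columns site ids)
    coords: np.ndarray         # N x 2 planar (km or model units)
    env: pd.DataFrame          # raw per-site environmental variables (N rows)
    env_pcs: np.ndarray        # 2 x N principal components (standardised)
    alpha_obs: np.ndarray      # per-site observed richness
    areas: np.ndarray          # effective areas, mean 1

    @property
    def n_sites(self) -> int:
        return self.abundance.shape[1]


def compute_ofd(incidence: np.ndarray, n_sites: int | None = None) -> OFD:
    """Histogram of per-species site counts from an S x N incidence matrix."""
    incidence = np.asarray(incidence).astype(bool)
    occ = incidence.sum(axis=1)
    if (occ == 0).any():
        raise ValueError("species with zero occupancy in incidence table")
    n = n_sites if n_sites is not None else incidence.shape[1]
    counts = np.bincount(occ, minlength=n + 1)[1:n + 1]
    return OFD(counts=counts, n_sites=n)


def incidence_from_biomass(biomass: np.ndarray,
                           threshold: float = EXTINCTION_THRESHOLD) -> np.ndarray:
    """Simulation-side incidence: above-threshold presence."""
    return np.asarray(biomass) >= threshold


def occupancy_model_ofd(m: float, n_sites: int) -> np.ndarray:
    """Stationary occupancy distribution of the patch occupancy model.

    Returns the expected proportion of species at each occupancy 1..N,
    normalised to a simplex.
    """
    if m <= 0:
        raise ValueError("mixing rate m must be > 0")
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    n = np.arange(1, n_sites + 1, dtype=float)
    big_n = float(n_sites)
    # log p(n) = -log n + (n-1) log m + log((N-1)!/(N-n)!) - (n-1) log(N-1)
    logp = (-np.log(n)
            + (n - 1) * np.log(m)
            + gammaln(big_n) - gammaln(big_n - n + 1)
            - (n - 1) * np.log(big_n - 1))
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


def fit_mixing_rate(ofd: OFD, log10_bounds: tuple[float, float] = (-6.0, 6.0)
                    ) -> MixingFit:
    """Multinomial maximum-likelihood mixing rate for an observed OFD."""
    counts = np.asarray(ofd.counts, dtype=float)
    if counts.sum() < 10:
        raise ValueError("need at least 10 species to fit the mixing rate")
    if counts[:-1].sum() == 0:
        import warnings
        warnings.warn("degenerate OFD: all species occupy every site; "
                      "fitted m sits at the upper search bound")

    def nll(log10_m: float) -> float:
        p = occupancy_model_ofd(10.0 ** log10_m, ofd.n_sites)
        return -float(np.sum(counts * np.log(np.maximum(p, 1e-300))))

    res = minimize_scalar(nll, bounds=log10_bounds, method="bounded",
                          options={"xatol": 1e-8})
    m = float(10.0 ** res.x)
    return MixingFit(m=m, loglik=-float(res.fun),
                     predicted_ofd=occupancy_model_ofd(m, ofd.n_sites))


def _env_principal_components(env_raw: np.ndarray) -> np.ndarray:
    """First <=2 PCs of the centred/scaled environment, re-standardised to
    unit variance; shape (n_pcs, n_sites). Degenerate inputs (a single site)
    yield zero variation."""
    n_sites, n_vars = env_raw.shape
    n_pcs = min(2, n_vars, n_sites)
    if n_sites < 2:
        return np.zeros((min(2, n_vars), n_sites))
    scaled = StandardScaler().fit_transform(env_raw)
    pcs = PCA(n_components=n_pcs).fit_transform(scaled)
    sd = pcs.std(axis=0, ddof=0)
    return (pcs / np.where(sd > 0, sd, 1.0)).T


def ingest_empirical(species_by_site: pd.DataFrame, sites: pd.DataFrame,
                     environment: pd.DataFrame, geographic: bool | None = None
                     ) -> EmpiricalDataset:
    """Assemble an EmpiricalDataset from the three standard tables.

    ``species_by_site``: rows species, columns site ids (abundance or 0/1).
    ``sites``: site_id plus either (lat, lon) or planar (x, y).
    ``environment``: site_id plus raw environmental variables.

    The environment is centred/scaled and reduced to its first two principal
    components (re-standardised to unit variance, matching the model's
    N(0,1) environmental fields); effective areas are proportional to
    observed richness with mean 1 (linear within-site species-area
    assumption).
    """
    site_ids = list(species_by_site.columns)
    sites = sites.set_index("site_id") if "site_id" in sites.columns else sites
    environment = environment.set_index("site_id") \
        if "site_id" in environment.columns else environment
    missing = [s for s in site_ids if s not in sites.index] + \
              [s for s in site_ids if s not in environment.index]
    if missing:
        raise ValueError(f"site id mismatch across tables: {sorted(set(missing))}")
    sites = sites.loc[site_ids]
    environment = environment.loc[site_ids]

    if geographic is None:
        geographic = {"lat", "lon"} <= set(sites.columns)
    if geographic:
        coords = equirectangular_projection(sites["lat"].to_numpy(),
                                            sites["lon"].to_numpy())
    else:
        coords = sites[["x", "y"]].to_numpy(dtype=float)

    pcs = _env_principal_components(environment.to_numpy(dtype=float))

    abund = species_by_site.to_numpy(dtype=float)
    alpha = (abund > 0).sum(axis=0)
    if (alpha == 0).any():
        raise ValueError("site with zero observed richness")
    areas = alpha / alpha.mean()
    return EmpiricalDataset(abundance=species_by_site, coords=coords,
                            env=environment, env_pcs=pcs, alpha_obs=alpha,
                            areas=areas)


def pool_nearby_sites(dataset: EmpiricalDataset, radius_km: float = 20.0
                      ) -> EmpiricalDataset:
    """Merge single-linkage clusters of sites closer than ``radius_km``.

    Abundances are summed, coordinates and environments averaged, observed
    richness and effective areas recomputed.
    """
    n = dataset.n_sites
    if n < 2:
        return dataset
    z = linkage(pdist(dataset.coords), method="single")
    labels = fcluster(z, t=radius_km, criterion="distance")
    if len(np.unique(labels)) == n:
        return dataset
    groups = [np.flatnonzero(labels == lab) for lab in np.unique(labels)]
    abund = dataset.abundance.to_numpy(dtype=float)
    new_ab = np.column_stack([abund[:, g].sum(axis=1) for g in groups])
    new_coords = np.vstack([dataset.coords[g].mean(axis=0) for g in groups])
    env_raw = dataset.env.to_numpy(dtype=float)
    new_env = np.vstack([env_raw[g].mean(axis=0) for g in groups])
    ids = [f"pool{j}" for j in range(len(groups))]
    ab_df = pd.DataFrame(new_ab, index=dataset.abundance.index, columns=ids)
    env_df = pd.DataFrame(new_env, index=ids, columns=dataset.env.columns)
    pcs = _env_principal_components(new_env)
    alpha = (new_ab > 0).sum(axis=0)
    return EmpiricalDataset(abundance=ab_df, coords=new_coords, env=env_df,
                            env_pcs=pcs, alpha_obs=alpha,
                            areas=alpha / alpha.mean())


def empirical_landscape(dataset: EmpiricalDataset) -> Landscape:
    """Landscape with spatial/environmental/area structure taken from data."""
    coords = dataset.coords
    adj = gabriel_graph(coords)
    d = squareform(pdist(coords))
    extent = coords.max(axis=0) - coords.min(axis=0)
    return Landscape(coords=coords, side_length=float(extent.max()),
                     adjacency=adj, distances=d, env=np.atleast_2d(dataset.env_pcs),
                     areas=np.asarray(dataset.areas, dtype=float))


def fit_niche_width(dataset: EmpiricalDataset, w_grid, replicates: int = 2,
                    rng_seed=None, assemble_fn=None,
                    threshold: float = EXTINCTION_THRESHOLD) -> tuple[float, dict]:
    """Scan niche widths; pick the one whose simulated OFD matches the data.

    For each w in ``w_grid``, ``assemble_fn(landscape, w, rng)`` (supplied by
    the orchestration layer; returns an assembled Metacommunity) is run
    ``replicates`` times on the empirical landscape. The mean simulated OFD
    is fitted with the patch occupancy model, and the w minimising
    |log m_sim - log m_emp| wins. Failed grid points are flagged in the
    diagnostics, never silently dropped.
    """
    w_grid = list(w_grid)
    if len(w_grid) < 3:
        raise ValueError("w_grid needs at least 3 values")
    if assemble_fn is None:
        raise ValueError("assemble_fn is required (see orchestration.fit_empirical)")
    rng = np.random.default_rng(rng_seed)
    emp_ofd = compute_ofd((dataset.abundance.to_numpy(dtype=float) > 0))
    m_emp = fit_mixing_rate(emp_ofd).m
    ls = empirical_landscape(dataset)
    diagnostics = {"m_emp": m_emp, "per_w": []}
    best = None
    for w in w_grid:
        entry = {"w": w, "ok": True}
        try:
            counts = np.zeros(ls.n_sites)
            for _ in range(replicates):
                mc = assemble_fn(ls, w, rng)
                inc = incidence_from_biomass(mc.biomass, threshold)
                inc = inc[inc.any(axis=1)]
                counts = counts + compute_ofd(inc, ls.n_sites).counts
            mean_counts = counts / replicates
            sim_ofd = OFD(counts=np.round(mean_counts * replicates).astype(int),
                          n_sites=ls.n_sites)
            m_sim = fit_mixing_rate(sim_ofd).m
            entry["m_sim"] = m_sim
            entry["mean_ofd"] = (counts / replicates).tolist()
            score = abs(np.log(m_sim) - np.log(m_emp))
            entry["score"] = score
            if best is None or score < best[0]:
                best = (score, w)
        except Exception as exc:  # noqa: BLE001 - flagged, not dropped
            entry["ok"] = False
            entry["error"] = str(exc)
        diagnostics["per_w"].append(entry)
    if best is None:
        raise RuntimeError("assembly failed at every niche width on the grid")
    return best[1], diagnostics
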