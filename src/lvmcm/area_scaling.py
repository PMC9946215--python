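"""Competition-area relation (CAR): regional interactions and area scaling.

Site area enters the dynamics through the scaled local interaction matrix

    A_x = lam'_x I + lam_x A0,   lam_x = (a_x/a0)^v,  lam'_x = (a_x/a0)^v'

The exponents v, v' are measured from simulations: metacommunities of
different total area are assembled, the regional-scale sensitivity of
equilibrium biomasses to sustained growth-rate presses is estimated, and its
inverse — the regional effective interaction matrix C — decays with area as
two power laws (one for the mean off-diagonal |C_ij|, one for the mean
diagonal C_ii). Each site of the heterogeneous-area landscape is then an
implicit sub-network whose internal interactions follow the fitted CAR.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .dynamics import EXTINCTION_THRESHOLD, Metacommunity, integrate

__all__ = [
    "CarFit",
    "CarFitError",
    "estimate_regional_interactions",
    "sensitivity_matrix",
    "regional_competition",
    "fit_power_law",
    "fit_car",
    "scaling_factors",
]


class CarFitError(RuntimeError):
    pass


@dataclass
class CarFit:
    v: float                      # interspecific exponent
    v_prime: float                # intraspecific exponent
    areas_used: list[float]
    mean_inter: list[float]       # mean |C_ij|, i != j, per area level
    mean_intra: list[float]       # mean C_ii per area level
    r_squared: tuple[float, float] = (np.nan, np.nan)

    def to_dict(self) -> dict:
        return {
            "v": self.v, "v_prime": self.v_prime,
            "areas_used": list(map(float, self.areas_used)),
            "mean_inter": list(map(float, self.mean_inter)),
            "mean_intra": list(map(float, self.mean_intra)),
            "r_squared": [float(r) for r in self.r_squared],
        }


def _jacobian(mc: Metacommunity) -> np.ndarray:
    """Dense Jacobian of the LV flow at the current biomass, shape (S*N, S*N)."""
    b = mc.biomass
    s, n = b.shape
    a0 = mc.pool.interactions
    d = mc.dispersal.matrix
    growth_excess = mc.growth - mc.lam_prime * b - mc.lam * (a0 @ b)
    jac = np.zeros((s, n, s, n))
    # within-site species coupling: dF_ix/dB_jx = -B_ix * lam_x * A0_ij (i != j)
    cross = -b[:, :, None] * mc.lam[None, :, None] * a0[:, None, :]
    for x in range(n):
        jac[:, x, :, x] += cross[:, x, :]
    for i in range(s):
        jac[i, :, i, :] += d  # dispersal, includes the -e diagonal
        diag = np.einsum("xx->x", jac[i, :, i, :])
        diag += growth_excess[i] - mc.lam_prime * b[i]
    return jac.reshape(s * n, s * n)


def sensitivity_matrix(mc: Metacommunity) -> np.ndarray:
    """Analytic press-response matrix V_ij = sum_x dB*_ix / dR_j (linearised).

    A sustained unit depression of species j's growth rate at every site
    shifts the equilibrium by dB = -J^{-1} dF/ds; V sums the per-species
    responses over sites. Equals the press-perturbation estimate in the
    small-press limit.
    """
    s, n = mc.biomass.shape
    jac = _jacobian(mc)
    gmat = np.zeros((s * n, s))
    for j in range(s):
        gmat[j * n:(j + 1) * n, j] = mc.biomass[j]
    try:
        x = np.linalg.solve(jac, gmat)
    except np.linalg.LinAlgError:
        x = np.linalg.lstsq(jac, gmat, rcond=None)[0]
    return -x.reshape(s, n, s).sum(axis=1)


def estimate_regional_interactions(mc: Metacommunity, press_size: float = 1e-3,
                                   relax_time: float = 2000.0,
                                   steady_tol: float = 1e-10,
                                   rtol: float = 1e-8, atol: float = 1e-12,
                                   max_retries: int = 5) -> np.ndarray:
    """Press-perturbation estimate of the regional sensitivity matrix.

    For each species j in turn, a constant ``press_size`` is subtracted from
    R_jx at all sites, the system is re-integrated to steady state, and

        C_ij = sum_x (B_ix^pressed - B_ix^*) / (-press_size).

    If a press drives any resident regionally extinct the press is halved and
    retried (up to ``max_retries`` times).
    """
    s = mc.n_species
    base = mc.biomass.copy()
    extant0 = (base >= EXTINCTION_THRESHOLD).any(axis=1)
    c = np.zeros((s, s))
    for j in range(s):
        press = press_size
        for attempt in range(max_retries + 1):
            trial = copy.copy(mc)
            trial.biomass = base.copy()
            trial.growth = mc.growth.copy()
            trial.growth[j] = mc.growth[j] - press
            integrate(trial, relax_time, rtol=rtol, atol=atol, steady_tol=steady_tol)
            extant = (trial.biomass >= EXTINCTION_THRESHOLD).any(axis=1)
            if (extant0 & ~extant).any():
                press *= 0.5
                if attempt == max_retries:
                    raise CarFitError(
                        f"press on species {j} causes extinctions even at {press:g}")
                continue
            c[:, j] = (trial.biomass - base).sum(axis=1) / (-press)
            break
    return c


def regional_competition(sensitivity: np.ndarray) -> np.ndarray:
    """Regional effective interaction coefficients: the inverse sensitivity.

    If the regional assemblage behaved as a well-mixed LV community
    dB_i/dt = (r_i - sum_j C_ij B_j) B_i, the equilibrium response to growth
    presses would be C^{-1}; inverting the measured response recovers C.
    """
    s = sensitivity.shape[0]
    try:
        return np.linalg.solve(sensitivity, np.eye(s))
    except np.linalg.LinAlgError:
        return np.linalg.pinv(sensitivity)


def car_means(mc: Metacommunity, method: str = "analytic") -> tuple[float, float]:
    """Mean |C_ij| (i!=j) and mean C_ii of the regional interaction matrix."""
    if method == "analytic":
        v = sensitivity_matrix(mc)
    elif method == "press":
        v = estimate_regional_interactions(mc)
    else:
        raise ValueError(f"unknown method {method!r}")
    c = regional_competition(v)
    s = c.shape[0]
    intra = float(np.mean(np.diag(c)))
    if s < 2:
        return np.nan, intra
    off = c[~np.eye(s, dtype=bool)]
    return float(np.mean(np.abs(off))), intra


def fit_power_law(areas, values) -> tuple[float, float]:
    """OLS exponent of values ~ areas^v on log-log axes; returns (v, r^2)."""
    y = np.asarray(values, dtype=float)
    if np.any(y <= 0) or not np.all(np.isfinite(y)):
        raise CarFitError(f"non-positive mean interaction at some area level: {values}")
    x = sm.add_constant(np.log(np.asarray(areas, dtype=float)))
    fit = sm.OLS(np.log(y), x).fit()
    return float(fit.params[1]), float(fit.rsquared)


def fit_car(assembly_factory, area_levels, replicates: int = 2, rng_seed=None,
            method: str = "analytic", min_r2: float = 0.5) -> CarFit:
    """Fit the two CAR power laws over assembled arenas of varying total area.

    ``assembly_factory(area, rng)`` must return a relaxed Metacommunity of
    total area ``area``. Mean interaction magnitudes are averaged over
    replicates at each level and regressed (OLS) on log area.
    """
    area_levels = list(area_levels)
    if len(area_levels) < 3:
        raise CarFitError("need at least 3 area levels")
    rng = np.random.default_rng(rng_seed)
    mean_inter, mean_intra = [], []
    for a in area_levels:
        inters, intras = [], []
        for _ in range(replicates):
            mc = assembly_factory(a, rng)
            inter, intra = car_means(mc, method=method)
            if np.isfinite(inter):
                inters.append(inter)
            intras.append(intra)
        mean_inter.append(float(np.mean(inters)) if inters else np.nan)
        mean_intra.append(float(np.mean(intras)))
    r2 = []
    exps = []
    for means in (mean_inter, mean_intra):
        v, r = fit_power_law(area_levels, means)
        exps.append(v)
        r2.append(r)
    fit_result = CarFit(v=exps[0], v_prime=exps[1], areas_used=area_levels,
                        mean_inter=mean_inter, mean_intra=mean_intra,
                        r_squared=(r2[0], r2[1]))
    if min(r2) < min_r2:
        raise CarFitError(f"CAR fit rejected: r^2 = {r2} below {min_r2}; "
                          f"fit was {fit_result.to_dict()}")
    return fit_result


def scaling_factors(areas: np.ndarray, v: float, v_prime: float,
                    a0: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-site scaling factors lam_x = (a_x/a0)^v, lam'_x = (a_x/a0)^v'."""
    areas = np.asarray(areas, dtype=float)
    if (areas <= 0).any():
        raise ValueError("areas must be positive")
    ratio = areas / a0
    return ratio ** v, ratio ** v_prime
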