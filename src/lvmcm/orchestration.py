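"""Sweeps, CAR calibration wiring, fixtures and run manifests.

``run_sweep`` reproduces the study design: a grid of (niche width w,
dispersal length l) cells, each holding replicate assembled metacommunities
whose every site is removed in turn; the output pools one predictor/response
row per removal plus one record per species extinction. CAR exponents are
calibrated per niche width from site-count arenas before the grid runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from . import __version__
from .area_scaling import CarFit, fit_car
from .assembly import AssemblyParams, assemble
from .dynamics import EXTINCTION_THRESHOLD, Metacommunity
from .landscape import Landscape, generate_landscape, sample_environment
from .occupancy_fit import EmpiricalDataset, fit_niche_width, occupancy_model_ofd
from .removal import run_removal_experiment
from .stats import centralities, distinctness

__all__ = ["SweepConfig", "SweepResult", "scaled_sweep_config", "calibrate_car",
           "assemble_cell", "run_sweep", "fit_empirical", "make_fixture"]

logger = logging.getLogger(__name__)


def _log_spaced(lo: float, hi: float, n: int) -> tuple[float, ...]:
    return tuple(float(v) for v in np.geomspace(lo, hi, n))


@dataclass
class SweepConfig:
    """Parameter grid and numerical settings for a removal sweep.

    Defaults follow the full study design: 20 sites, 10 log-spaced niche
    widths in [0.5, 15] and dispersal lengths in [0.02, 10], areas 1..30 in
    equal intervals. ``analysis_w_floor`` marks the smallest niche width kept
    at the analysis stage (extreme grid values are excluded from reporting,
    never from simulation).
    """

    n_sites: int = 20
    w_values: tuple = field(default_factory=lambda: _log_spaced(0.5, 15.0, 10))
    ell_values: tuple = field(default_factory=lambda: _log_spaced(0.02, 10.0, 10))
    analysis_w_floor: float = 0.63
    replicates: int = 2
    k_vars: int = 1
    corr_length: float = 1.0
    emigration_rate: float = 0.1
    a_min: float = 1.0
    a_max: float = 30.0
    threshold: float = EXTINCTION_THRESHOLD
    epoch_duration: float = 500.0
    max_epochs: int = 1000
    saturation_window: int = 200
    saturation_slope: float = 0.01
    relax_time: float = 1e4
    snapshot_dt: float = 1.0
    # cadence for strata whose extinction timings feed no distance/lag
    # statistic (every stratum above the smallest analysed niche width)
    snapshot_dt_coarse: float = 1.0
    rtol: float = 1e-4
    atol: float = 1e-10
    steady_tol: float = 1e-8
    removal_steady_tol: float = 1e-9
    # CAR calibration (per niche width)
    car_area_levels: tuple = (1, 2, 4, 8, 16, 32)
    car_replicates: int = 5
    car_max_epochs: int = 150
    car_saturation_window: int = 40
    car_ell: float | None = None   # default: geometric mean of ell_values
    car_min_r2: float = 0.0        # sweeps record fit diagnostics rather than abort

    def manifest(self, seed: int) -> dict:
        cfg = asdict(self)
        blob = json.dumps(cfg, sort_keys=True, default=str)
        return {
            "config": cfg,
            "seed": int(seed),
            "version": __version__,
            "config_hash": hashlib.sha256(blob.encode()).hexdigest(),
        }


def scaled_sweep_config() -> SweepConfig:
    """Desk-scale preset: 10 sites, 4 niche widths x 3 dispersal lengths,
    2 replicates, capped assembly length. Grids span the full study ranges
    (the smallest dispersal extreme is excluded, mirroring the analysis-stage
    exclusions of the full design)."""
    return SweepConfig(
        n_sites=10,
        w_values=_log_spaced(0.63, 15.0, 4),
        ell_values=(0.1, 1.0, 10.0),
        replicates=2,
        max_epochs=250,
        saturation_window=50,
        car_area_levels=(1, 2, 4, 8, 16),
        car_replicates=2,
        car_max_epochs=120,
        car_saturation_window=30,
        snapshot_dt_coarse=4.0,
    )


def _single_site_landscape(k_vars: int, rng) -> Landscape:
    # the unit-area reference arena sits at the environmental mean (E = 0):
    # with a random E the degenerate single-site optimum interval collapses
    # to 1.25*E, which for narrow niches and |E| > w/(2*0.25) leaves no
    # viable invader at all
    coords = np.array([[0.5, 0.5]])
    env = np.zeros((k_vars, 1))
    return Landscape(coords=coords, side_length=1.0,
                     adjacency=np.zeros((1, 1), dtype=np.int8),
                     distances=np.zeros((1, 1)), env=env,
                     areas=np.ones(1), corr_length=1.0)


def _arena_factory(config: SweepConfig, w: float, ell: float):
    """Factory of relaxed unit-area arenas of n = area sites, for CAR fits."""

    def factory(area: float, rng) -> Metacommunity:
        n = int(round(area))
        if n < 1:
            raise ValueError("arena needs at least one site")
        params = AssemblyParams(
            niche_width=w, dispersal_length=ell,
            emigration_rate=config.emigration_rate,
            v=0.0, v_prime=0.0,
            epoch_duration=config.epoch_duration,
            threshold=config.threshold,
            saturation_window=config.car_saturation_window,
            saturation_slope=config.saturation_slope,
            rtol=config.rtol, atol=config.atol, steady_tol=config.steady_tol,
        )
        # a tiny arena can draw an environment so far from the regional
        # mean that no optimum is viable for narrow niches; redraw it
        for _ in range(20):
            if n == 1:
                ls = _single_site_landscape(config.k_vars, rng)
            else:
                ls = generate_landscape(n, config.k_vars, config.corr_length,
                                        a_min=1.0, a_max=1.0, rng_seed=rng)
            try:
                mc, _ = assemble(ls, params, config.car_max_epochs, rng)
            except RuntimeError as exc:
                if "viable invader" not in str(exc):
                    raise
                logger.info("redrawing degenerate %d-site arena (w=%g)", n, w)
                continue
            return mc
        raise RuntimeError(f"no viable {n}-site arena found for w={w}")

    return factory


def calibrate_car(config: SweepConfig, w: float, rng_seed=None,
                  ell: float | None = None, method: str = "analytic") -> CarFit:
    """Fit the CAR exponents for one niche width from site-count arenas."""
    if ell is None:
        ell = config.car_ell
    if ell is None:
        ell = float(np.exp(np.mean(np.log(config.ell_values))))
    return fit_car(_arena_factory(config, w, ell), config.car_area_levels,
                   replicates=config.car_replicates, rng_seed=rng_seed,
                   method=method, min_r2=config.car_min_r2)


def assemble_cell(config: SweepConfig, w: float, ell: float, car: CarFit,
                  rng_seed=None):
    """One assembled metacommunity for a (w, l) grid cell."""
    rng = np.random.default_rng(rng_seed)
    ls = generate_landscape(config.n_sites, config.k_vars, config.corr_length,
                            a_min=config.a_min, a_max=config.a_max, rng_seed=rng)
    params = AssemblyParams(
        niche_width=w, dispersal_length=ell,
        emigration_rate=config.emigration_rate,
        v=car.v, v_prime=car.v_prime,
        epoch_duration=config.epoch_duration,
        threshold=config.threshold,
        saturation_window=config.saturation_window,
        saturation_slope=config.saturation_slope,
        rtol=config.rtol, atol=config.atol, steady_tol=config.steady_tol,
    )
    return assemble(ls, params, config.max_epochs, rng)


def removal_rows(config: SweepConfig, mc: Metacommunity, meta: dict,
                 snapshot_dt: float | None = None
                 ) -> tuple[list[dict], list[dict]]:
    """Remove each site in turn; returns (predictor rows, extinction rows)."""
    beta = distinctness(mc.biomass)
    cent = centralities(mc.landscape.adjacency)
    total_b = mc.total_biomass()
    site_b = mc.site_biomass()
    rows, ext_rows = [], []
    for site in range(mc.n_sites):
        outcome = run_removal_experiment(
            mc, site, relax_time=config.relax_time,
            snapshot_dt=snapshot_dt or config.snapshot_dt,
            threshold=config.threshold,
            rtol=config.rtol, atol=config.atol,
            steady_tol=config.removal_steady_tol)
        row = dict(meta)
        row.update({
            "site": site,
            "biomass_fraction": site_b[site] / total_b,
            "distinctness": beta[site],
            "degree": cent["degree"][site],
            "closeness": cent["closeness"][site],
            "betweenness": cent["betweenness"][site],
            "eigenvector": cent["eigenvector"][site],
            "delta_gamma0": outcome.delta_gamma0,
            "delta_gamma": outcome.delta_gamma,
            "gamma_star": outcome.gamma_star,
            "value": outcome.value,
            "valid": outcome.valid,
        })
        rows.append(row)
        for rec in outcome.extinction_records:
            er = dict(meta)
            er.update({"removed_site": site, "species_id": rec.species_id,
                       "time": rec.time, "last_site": rec.last_site,
                       "distance_frac": rec.distance_frac})
            ext_rows.append(er)
    return rows, ext_rows


@dataclass
class SweepResult:
    predictors: pd.DataFrame
    extinctions: pd.DataFrame
    car_fits: dict
    manifest: dict

    def analysis_view(self, config: SweepConfig) -> pd.DataFrame:
        """Reporting-stage filter: drop niche widths below the analysis floor."""
        keep = self.predictors["w"] >= config.analysis_w_floor - 1e-9
        return self.predictors[keep & self.predictors["valid"]]


def _cell_seed(base_seed: int, key: tuple) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(base_seed), spawn_key=tuple(key))


def run_sweep(config: SweepConfig, rng_seed: int = 0,
              out_dir: str | Path | None = None) -> SweepResult:
    """Run the full grid; deterministic given the seed, resumable per cell.

    With ``out_dir`` set, completed cells are written as CSV and skipped on
    rerun, so an interrupted sweep resumes to an identical archive.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest = config.manifest(rng_seed)
    car_fits = {}
    failures = []
    for i, w in enumerate(config.w_values):
        car_file = out / f"car_w{i}.json" if out is not None else None
        if car_file is not None and car_file.exists():
            d = json.loads(car_file.read_text())
            car_fits[w] = CarFit(v=d["v"], v_prime=d["v_prime"],
                                 areas_used=d["areas_used"],
                                 mean_inter=d["mean_inter"],
                                 mean_intra=d["mean_intra"],
                                 r_squared=tuple(d["r_squared"]))
            continue
        car = calibrate_car(config, w, rng_seed=_cell_seed(rng_seed, (9000, i)))
        car_fits[w] = car
        if car_file is not None:
            car_file.write_text(json.dumps(car.to_dict()))
    all_rows, all_ext = [], []
    for i, w in enumerate(config.w_values):
        for j, ell in enumerate(config.ell_values):
            for rep in range(config.replicates):
                meta = {"w": w, "ell": ell, "replicate": rep}
                tag = f"cell_w{i}_l{j}_r{rep}"
                if out is not None and (out / f"{tag}.predictors.csv").exists():
                    all_rows.append(pd.read_csv(out / f"{tag}.predictors.csv"))
                    ef = out / f"{tag}.extinctions.csv"
                    if ef.exists() and ef.stat().st_size > 1:
                        all_ext.append(pd.read_csv(ef))
                    continue
                snap_dt = config.snapshot_dt if w <= min(config.w_values) \
                    else config.snapshot_dt_coarse
                try:
                    mc, log = assemble_cell(config, w, ell, car_fits[w],
                                            rng_seed=_cell_seed(rng_seed, (i, j, rep)))
                    rows, ext = removal_rows(config, mc, meta,
                                             snapshot_dt=snap_dt)
                    rows_df = pd.DataFrame(rows)
                    rows_df["gamma_star_cell"] = log.gamma_star
                    ext_df = pd.DataFrame(ext)
                except Exception as exc:  # noqa: BLE001 - collected, reported
                    logger.error("cell %s failed: %s", tag, exc)
                    failures.append({"cell": tag, "error": str(exc)})
                    continue
                all_rows.append(rows_df)
                all_ext.append(ext_df)
                if out is not None:
                    rows_df.to_csv(out / f"{tag}.predictors.csv", index=False)
                    ext_df.to_csv(out / f"{tag}.extinctions.csv", index=False)
    manifest["failures"] = failures
    predictors = pd.concat(all_rows, ignore_index=True) if all_rows else pd.DataFrame()
    ext_cols = ["w", "ell", "replicate", "removed_site", "species_id",
                "time", "last_site", "distance_frac"]
    non_empty = [e for e in all_ext if len(e)]
    extinctions = pd.concat(non_empty, ignore_index=True) if non_empty \
        else pd.DataFrame(columns=ext_cols)
    result = SweepResult(predictors=predictors, extinctions=extinctions,
                         car_fits=car_fits, manifest=manifest)
    if out is not None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        predictors.to_csv(out / "predictors.csv", index=False)
        extinctions.to_csv(out / "extinctions.csv", index=False)
    if failures:
        raise RuntimeError(f"{len(failures)} sweep cell(s) failed: {failures}")
    return result


def fit_empirical(dataset: EmpiricalDataset, w_grid, config: SweepConfig | None = None,
                  replicates: int = 2, rng_seed=None,
                  dispersal_length: float | None = None):
    """Locate the niche width whose simulations reproduce the empirical OFD.

    Builds the per-w assembly function (CAR calibration + assembly on the
    empirical landscape) and delegates the scan to
    ``occupancy_fit.fit_niche_width``.
    """
    config = config or scaled_sweep_config()
    if dispersal_length is None:
        d = squareform(pdist(dataset.coords))
        np.fill_diagonal(d, np.inf)
        dispersal_length = float(np.exp(np.mean(np.log(d.min(axis=1)))))
    car_cache: dict[float, CarFit] = {}

    def assemble_fn(ls: Landscape, w: float, rng) -> Metacommunity:
        if w not in car_cache:
            car_cache[w] = calibrate_car(config, w, rng_seed=rng,
                                         ell=dispersal_length)
        car = car_cache[w]
        params = AssemblyParams(
            niche_width=w, dispersal_length=dispersal_length,
            emigration_rate=config.emigration_rate,
            v=car.v, v_prime=car.v_prime,
            epoch_duration=config.epoch_duration,
            threshold=config.threshold,
            saturation_window=config.saturation_window,
            saturation_slope=config.saturation_slope,
            rtol=config.rtol, atol=config.atol, steady_tol=config.steady_tol,
        )
        mc, _ = assemble(ls, params, config.max_epochs, rng)
        return mc

    w_best, diag = fit_niche_width(dataset, w_grid, replicates=replicates,
                                   rng_seed=rng_seed, assemble_fn=assemble_fn)
    diag["dispersal_length"] = dispersal_length
    diag["car_fits"] = {str(w): c.to_dict() for w, c in car_cache.items()}
    return w_best, diag


def make_fixture(kind: str, rng_seed=None, out_dir: str | Path | None = None):
    """Generate test fixtures programmatically.

    kinds: ``toy_metacommunity`` (6 sites, pre-assembled small state),
    ``toy_species_by_site`` (200 species x 12 sites with right-skewed
    occupancy from the patch occupancy model at m = 0.3, plus coordinates
    and two GRF environmental variables), ``regression_synthetic``
    (predictor table with planted coefficients).
    """
    rng = np.random.default_rng(rng_seed)
    if kind == "toy_metacommunity":
        ls = generate_landscape(6, k_vars=1, a_min=1.0, a_max=6.0, rng_seed=rng)
        params = AssemblyParams(niche_width=1.5, dispersal_length=1.0,
                                v=-1.0, v_prime=-1.0, saturation_window=20,
                                epoch_duration=200.0)
        mc, log = assemble(ls, params, max_epochs=40, rng_seed=rng)
        return mc, log
    if kind == "toy_species_by_site":
        n_sites, n_species, m = 12, 200, 0.3
        p = occupancy_model_ofd(m, n_sites)
        occ = rng.choice(np.arange(1, n_sites + 1), size=n_species, p=p)
        table = np.zeros((n_species, n_sites))
        for s, n_occ in enumerate(occ):
            sites = rng.choice(n_sites, size=n_occ, replace=False)
            table[s, sites] = rng.integers(1, 50, size=n_occ)
        xy = rng.uniform(0, 12, (n_sites, 2))
        env = sample_environment(xy, k_vars=2, corr_length=1.0, rng_seed=rng)
        ids = [f"s{j}" for j in range(n_sites)]
        species_df = pd.DataFrame(table, columns=ids,
                                  index=[f"sp{i}" for i in range(n_species)])
        sites_df = pd.DataFrame({"site_id": ids, "x": xy[:, 0], "y": xy[:, 1]})
        env_df = pd.DataFrame({"site_id": ids, "var1": env[0], "var2": env[1]})
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            species_df.to_csv(out / "species_by_site.csv")
            sites_df.to_csv(out / "sites.csv", index=False)
            env_df.to_csv(out / "environment.csv", index=False)
        return species_df, sites_df, env_df
    if kind == "regression_synthetic":
        n = 200
        planted = {"biomass_fraction": 0.0, "distinctness": 0.6, "noise_sd": 0.05}
        x = rng.standard_normal((n, len(PREDICTOR_COLS)))
        df = pd.DataFrame(x, columns=PREDICTOR_COLS)
        df["value"] = (planted["biomass_fraction"] * df["biomass_fraction"]
                       + planted["distinctness"] * df["distinctness"]
                       + planted["noise_sd"] * rng.standard_normal(n))
        return df, planted
    raise ValueError(f"unknown fixture kind {kind!r}")


PREDICTOR_COLS = ["biomass_fraction", "distinctness", "degree", "closeness",
                  "betweenness", "eigenvector"]
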