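# lvmcm — Lotka–Volterra metacommunity simulations of habitat loss

`lvmcm` is a simulator and analysis toolkit for a question in conservation
ecology: **when a habitat patch is destroyed, how many species does the
region eventually lose — and which properties of the patch predict that
loss?** Immediate losses (endemics of the destroyed site) are only part of
the story; extinction debts are paid over long times and often far from the
perturbation, as source–sink structures collapse and competitive
rearrangements cascade through the landscape. The package is written for
quantitative/metacommunity ecologists who want mechanistic, process-based
removal experiments rather than species–area extrapolations.

## The model

A guild of `S` competing species occupies `N` sites linked by a Gabriel
graph. Biomass `B_ix` of species `i` at site `x` follows a spatial
Lotka–Volterra system

```
dB_ix/dt = (R_ix − λ'_x B_ix − λ_x Σ_j A_ij B_jx) B_ix + Σ_y B_iy D_xy
```

- `R_ix = 1 − (2/w)² Σ_k (E_kx − Eopt_ik)²` — quadratic niches of common
  width `w` over Gaussian-random-field environments `E` (mean 0, sd 1,
  correlation length 1), with random optima per species.
- `A` — hollow random competition matrix (`A_ij = 0.3` w.p. 0.3).
- `D` — exponential dispersal on graph edges, `D_xy = (e/k_y)e^(−d_xy/ℓ)`,
  `D_xx = −e`.
- `λ_x = (a_x/a₀)^v`, `λ'_x = (a_x/a₀)^v'` — site area `a_x` scales local
  interaction intensity through the *competition–area relation* (CAR),
  whose exponents the package measures from its own simulations
  (`lvmcm.area_scaling`).

Metacommunities self-organise by iterated invasion until regional richness
saturates; removal experiments then delete each site in turn, relax the
system for 10⁴ unit times and record the long-term regional species loss
Δγ (relative to the pre-disturbance richness γ*), plus per-species
extinction times and last-detection locations. Site predictors — biomass
share `B*_x/B*` (an area proxy), compositional distinctness `β̄_x` (mean
Bray–Curtis dissimilarity to all other sites) and four network
centralities — are related to `Δγ/γ*` by AIC-selected multivariate
regression, variance partitioning and rank correlations. An
occupancy-frequency-distribution (OFD) bridge with a one-parameter patch
occupancy model (the "mixing rate" `m`) fits the niche width `w` to
empirical species-by-site tables.

See `docs/methods.md` for the numerical scheme (a compiled exponential
ETDRK4 integrator — the niche term makes the system stiff), calibration
protocol, and the desk-scale problem sizes used by the bundled configs.

## Worked example

Assemble one 10-site metacommunity, calibrate the CAR for its niche width,
and remove the most compositionally distinct site:

```python
import numpy as np
from lvmcm.orchestration import scaled_sweep_config, calibrate_car, assemble_cell
from lvmcm.removal import run_removal_experiment
from lvmcm.stats import distinctness

cfg = scaled_sweep_config()
car = calibrate_car(cfg, w := 0.63, rng_seed=21)
print(f"CAR exponents: v = {car.v:.2f}, v' = {car.v_prime:.2f}")

mc, log = assemble_cell(cfg, w, ell := 1.0, car, rng_seed=22)
print(f"assembled gamma* = {log.gamma_star} species on {mc.n_sites} sites")

beta = distinctness(mc.biomass)
site = int(np.argmax(beta))
out = run_removal_experiment(mc, site)
print(f"removing site {site} (distinctness {beta[site]:.2f}, "
      f"biomass share {out.biomass_fraction:.2%}):")
print(f"  immediate loss dg0 = {out.delta_gamma0}, "
      f"long-term loss dg = {out.delta_gamma}, "
      f"conservation value dg/gamma* = {out.value:.3f}")
late = [r for r in out.extinction_records if r.time > 50]
print(f"  {len(late)} extinctions completed later than 50 unit times")
```

Output (under a minute on one core):

```
CAR exponents: v = -0.84, v' = -0.19
assembled gamma* = 212 species on 10 sites
removing site 6 (distinctness 1.00, biomass share 14.82%):
  immediate loss dg0 = 20, long-term loss dg = 45, conservation value dg/gamma* = 0.212
  0 extinctions completed later than 50 unit times
```

Read: the most distinct site held ~15% of regional biomass, but its
removal cost 21% of the regional species pool — 20 endemics immediately,
plus another 25 species lost as the metacommunity restructured. Across a
full sweep, distinctness out-ranks biomass share as a predictor of these
losses; that asymmetry between area and composition is the package's
central phenomenon.

The same machinery is exposed on the command line:

```bash
lvmcm sweep --seed 1 --out sweep_out/          # scaled (w, l) removal sweep
lvmcm analyze --removals sweep_out/predictors.csv --out report.json
lvmcm fit-empirical --species sp.csv --sites sites.csv --env env.csv \
      --w-grid 0.6,1.5,3.75 --out fit.json
lvmcm fixture --kind toy_species_by_site --seed 0 --out fixtures/
```

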