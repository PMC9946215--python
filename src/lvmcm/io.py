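"""HDF5 archives and CSV exports for simulation states."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dynamics import DispersalMatrix, Metacommunity
from .landscape import Landscape
from .species_pool import SpeciesPool

__all__ = ["save_metacommunity", "load_metacommunity",
           "save_landscape", "load_landscape", "landscape_to_csv"]


def save_landscape(group: h5py.Group, ls: Landscape) -> None:
    for name, arr in (("coords", ls.coords), ("adjacency", ls.adjacency),
                      ("distances", ls.distances), ("env", ls.env),
                      ("areas", ls.areas)):
        group.create_dataset(name, data=arr)
    group.attrs["side_length"] = ls.side_length
    group.attrs["corr_length"] = ls.corr_length


def load_landscape(group: h5py.Group) -> Landscape:
    return Landscape(
        coords=group["coords"][...],
        side_length=float(group.attrs["side_length"]),
        adjacency=group["adjacency"][...],
        distances=group["distances"][...],
        env=group["env"][...],
        areas=group["areas"][...],
        corr_length=float(group.attrs["corr_length"]),
    )


def save_metacommunity(path: str | Path, mc: Metacommunity) -> None:
    with h5py.File(path, "w") as f:
        save_landscape(f.create_group("landscape"), mc.landscape)
        pool = f.create_group("pool")
        pool.create_dataset("optima", data=mc.pool.optima)
        pool.create_dataset("interactions", data=mc.pool.interactions)
        pool.attrs["niche_width"] = mc.pool.niche_width
        state = f.create_group("state")
        state.create_dataset("biomass", data=mc.biomass)
        state.create_dataset("growth", data=mc.growth)
        state.create_dataset("species_ids", data=mc.species_ids)
        state.create_dataset("lam", data=mc.lam)
        state.create_dataset("lam_prime", data=mc.lam_prime)
        state.attrs["time"] = mc.time
        state.attrs["next_species_id"] = mc.next_species_id
        disp = f.create_group("dispersal")
        disp.create_dataset("matrix", data=mc.dispersal.matrix)
        disp.create_dataset("degrees", data=mc.dispersal.degrees)
        disp.attrs["emigration_rate"] = mc.dispersal.emigration_rate
        disp.attrs["dispersal_length"] = mc.dispersal.dispersal_length


def load_metacommunity(path: str | Path) -> Metacommunity:
    with h5py.File(path, "r") as f:
        ls = load_landscape(f["landscape"])
        pool = SpeciesPool(
            optima=f["pool/optima"][...],
            interactions=f["pool/interactions"][...],
            niche_width=float(f["pool"].attrs["niche_width"]),
        )
        disp = DispersalMatrix(
            matrix=f["dispersal/matrix"][...],
            emigration_rate=float(f["dispersal"].attrs["emigration_rate"]),
            dispersal_length=float(f["dispersal"].attrs["dispersal_length"]),
            degrees=f["dispersal/degrees"][...],
        )
        state = f["state"]
        return Metacommunity(
            landscape=ls, pool=pool, dispersal=disp,
            growth=state["growth"][...],
            biomass=state["biomass"][...],
            lam=state["lam"][...],
            lam_prime=state["lam_prime"][...],
            species_ids=state["species_ids"][...],
            next_species_id=int(state.attrs["next_species_id"]),
            time=float(state.attrs["time"]),
        )


def landscape_to_csv(path: str | Path, ls: Landscape) -> None:
    cols = {"site_id": np.arange(ls.n_sites),
            "x": ls.coords[:, 0], "y": ls.coords[:, 1], "area": ls.areas}
    for k in range(ls.env.shape[0]):
        cols[f"E{k + 1}"] = ls.env[k]
    pd.DataFrame(cols).to_csv(path, index=False)
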