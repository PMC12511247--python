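"""Aboveground biomass, combustion and composition classification.

Biomass comes from power-law allometry ``m = a * d**b`` (kg dry matter, d in
cm) applied per species and biomass component; combusted biomass is the
component-wise product with the discrete combustion class assessed in the
field.  Coarse woody debris uses the Van Wagner line-intercept estimator with
decay-class wood densities.  Plot composition is classified from the
deciduous fraction index DI = (relative density + relative biomass of
deciduous trees) / 2 * 100.

Aboveground carbon is 50% of dry biomass throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from reburn.core_data import (
    CARBON_FRACTION,
    SHRUB_COMPONENTS,
    TREE_COMPONENTS,
    CompositionClass,
)
from reburn.errors import AllometryLookupError, ConfigError

#: DI thresholds separating spruce / mixed / deciduous dominance.
DI_SPRUCE_MAX = 33.33      # DI <= 33.33 -> spruce
DI_DECIDUOUS_MIN = 66.66   # DI >= 66.66 -> deciduous


@dataclass
class AllometricTable:
    """Species/component power-law coefficients plus CWD wood densities.

    ``trees`` and ``shrubs`` map species -> component -> (a, b); ``seedlings``
    maps species -> (a, b) for whole-seedling biomass.  ``cwd_density`` maps
    decay class -> wood density (g cm^-3).  ``deciduous_species`` drives the
    DI calculation; unknown species fall back to the ``"default"`` entry when
    one is declared.
    """

    trees: dict[str, dict[str, tuple[float, float]]]
    shrubs: dict[str, dict[str, tuple[float, float]]]
    seedlings: dict[str, tuple[float, float]]
    cwd_density: dict[str, float]
    deciduous_species: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for spp, comps in {**self.trees, **self.shrubs}.items():
            for comp, (a, b) in comps.items():
                if a <= 0:
                    raise ConfigError(
                        f"allometry: {spp}/{comp} coefficient a must be > 0")
        for decay, dens in self.cwd_density.items():
            if dens <= 0:
                raise ConfigError(f"cwd density for '{decay}' must be > 0")

    def lookup(self, kind: str, species: str) -> dict[str, tuple[float, float]]:
        table = self.trees if kind == "tree" else self.shrubs
        if species in table:
            return table[species]
        if "default" in table:
            return table["default"]
        raise AllometryLookupError(
            f"no {kind} allometry for species '{species}' and no default")

    def seedling_coeffs(self, species: str) -> tuple[float, float]:
        if species in self.seedlings:
            return self.seedlings[species]
        if "default" in self.seedlings:
            return self.seedlings["default"]
        raise AllometryLookupError(
            f"no seedling allometry for species '{species}' and no default")

    def is_deciduous(self, species: str) -> bool:
        return species in self.deciduous_species

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AllometricTable":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "AllometricTable":
        def conv(block):
            return {spp: {comp: (float(ab["a"]), float(ab["b"]))
                          for comp, ab in comps.items()}
                    for spp, comps in block.items()}
        return cls(
            trees=conv(raw["trees"]),
            shrubs=conv(raw["shrubs"]),
            seedlings={spp: (float(ab["a"]), float(ab["b"]))
                       for spp, ab in raw["seedlings"].items()},
            cwd_density={k: float(v) for k, v in raw["cwd_density"].items()},
            deciduous_species=set(raw.get("deciduous_species", [])),
        )

    @classmethod
    def default(cls) -> "AllometricTable":
        """Placeholder coefficient table shipped with the package."""
        return cls.from_yaml(Path(__file__).parent / "data" /
                             "allometry_default.yaml")


def stem_biomass(species: str, diameter_cm: float, table: AllometricTable,
                 kind: str = "tree") -> dict[str, float]:
    """Per-component dry biomass (kg) of one stem from power-law allometry."""
    if diameter_cm <= 0:
        raise ValueError("diameter must be positive")
    coeffs = table.lookup(kind, species)
    return {comp: a * diameter_cm ** b for comp, (a, b) in coeffs.items()}


def stem_combusted(biomass: Mapping[str, float],
                   combustion: Mapping[str, float]) -> float:
    """Combusted biomass (kg) = sum over components of biomass * fraction.

    Components with no recorded combustion fraction contribute zero loss.
    """
    total = 0.0
    for comp, mass in biomass.items():
        frac = combustion.get(comp, 0.0)
        if frac is None or (isinstance(frac, float) and math.isnan(frac)):
            frac = 0.0
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"combustion fraction for '{comp}' outside [0, 1]")
        total += mass * frac
    return total


def _row_combustion(row: pd.Series, components: tuple[str, ...]) -> dict[str, float]:
    out = {}
    for comp in components:
        v = row.get(f"comb_{comp}")
        out[comp] = 0.0 if pd.isna(v) else float(v)
    return out


def tree_pools(trees: pd.DataFrame, table: AllometricTable) -> pd.DataFrame:
    """Per-stem pre-fire, combusted and post-fire dry biomass (kg).

    Live trees and pre-fire snags share the same allometry; the
    ``pre_fire_status`` column routes them to separate pools downstream.
    """
    rows = []
    for _, row in trees.iterrows():
        bm = stem_biomass(row["species"], float(row["diameter_cm"]), table, "tree")
        comb = stem_combusted(bm, _row_combustion(row, TREE_COMPONENTS))
        pre = sum(bm.values())
        rows.append({"tree_id": row["tree_id"], "plot_id": row["plot_id"],
                     "species": row["species"],
                     "pre_fire_status": row["pre_fire_status"],
                     "pre_fire_kg": pre, "combusted_kg": comb,
                     "post_fire_kg": pre - comb})
    return pd.DataFrame(rows, columns=["tree_id", "plot_id", "species",
                                       "pre_fire_status", "pre_fire_kg",
                                       "combusted_kg", "post_fire_kg"])


def shrub_pools(shrubs: pd.DataFrame, table: AllometricTable) -> pd.DataFrame:
    rows = []
    for _, row in shrubs.iterrows():
        bm = stem_biomass(row["species"], float(row["basal_diameter_cm"]),
                          table, "shrub")
        comb = stem_combusted(bm, _row_combustion(row, SHRUB_COMPONENTS))
        pre = sum(bm.values())
        rows.append({"shrub_id": row["shrub_id"], "plot_id": row["plot_id"],
                     "species": row["species"], "pre_fire_kg": pre,
                     "combusted_kg": comb, "post_fire_kg": pre - comb})
    return pd.DataFrame(rows, columns=["shrub_id", "plot_id", "species",
                                       "pre_fire_kg", "combusted_kg",
                                       "post_fire_kg"])


def cwd_pools(cwd: pd.DataFrame, transect_length_m: float,
              table: AllometricTable) -> dict[str, float]:
    """Coarse-woody-debris pools (kg dry matter m^-2) by line intercept.

    Volume per unit area follows Van Wagner:
    ``V = pi^2 * sum(d_i^2) / (8 L)`` with diameters in cm and transect
    length L in m (the 1e-4 factor converts cm^2 to m^2), giving m^3 m^-2;
    mass uses the decay-class wood density.
    """
    if transect_length_m <= 0:
        raise ValueError("transect length must be positive")
    pre = comb = 0.0
    for _, row in cwd.iterrows():
        decay = row["decay_class"]
        if decay not in table.cwd_density:
            raise ValueError(f"unknown CWD decay class '{decay}'")
        dens_kg_m3 = table.cwd_density[decay] * 1000.0
        vol = math.pi ** 2 * float(row["diameter_cm"]) ** 2 * 1e-4 / \
            (8.0 * transect_length_m)
        mass = vol * dens_kg_m3
        pre += mass
        comb += mass * float(row["combustion_fraction"])
    return {"pre_fire": pre, "combusted": comb, "post_fire": pre - comb}


def plot_structure(trees: pd.DataFrame, belt_area_m2: float,
                   table: AllometricTable) -> pd.DataFrame:
    """Per-species stand structure: density, basal area, biomass.

    Returns stems m^-2, basal area cm^2 m^-2 and dry biomass kg m^-2 over
    all pre-fire stems in the belt transect.
    """
    if belt_area_m2 <= 0:
        raise ValueError("plot area must be positive")
    if trees.empty:
        return pd.DataFrame(columns=["species", "density", "basal_area",
                                     "biomass"])
    pools = tree_pools(trees, table)
    rows = []
    for spp, grp in trees.groupby("species"):
        d = grp["diameter_cm"].to_numpy(float)
        rows.append({
            "species": spp,
            "density": len(grp) / belt_area_m2,
            "basal_area": float(np.sum(np.pi * (d / 2.0) ** 2)) / belt_area_m2,
            "biomass": pools.loc[pools["species"] == spp, "pre_fire_kg"].sum()
            / belt_area_m2,
        })
    return pd.DataFrame(rows).sort_values("species").reset_index(drop=True)


def deciduous_index(trees: pd.DataFrame, table: AllometricTable) -> float:
    """DI (%) over pre-fire live trees of a plot; NaN when no live trees."""
    live = trees[trees["pre_fire_status"] == "live"]
    if live.empty:
        return float("nan")
    pools = tree_pools(live, table)
    is_dec = live["species"].map(table.is_deciduous).to_numpy(bool)
    rel_density = float(np.mean(is_dec))
    total_bm = pools["pre_fire_kg"].sum()
    rel_biomass = pools.loc[is_dec, "pre_fire_kg"].sum() / total_bm \
        if total_bm > 0 else 0.0
    return (rel_density + rel_biomass) / 2.0 * 100.0


def classify_composition(di: float, any_trees: bool) -> CompositionClass:
    """Dominance class from DI: <=33.33 spruce, >=66.66 deciduous, else mixed.

    A plot (or site) with no trees at all is ``open`` regardless of DI.
    """
    if not any_trees:
        return CompositionClass.OPEN
    if not 0.0 <= di <= 100.0:
        raise ValueError("DI must lie in [0, 100]")
    if di <= DI_SPRUCE_MAX:
        return CompositionClass.SPRUCE
    if di >= DI_DECIDUOUS_MIN:
        return CompositionClass.DECIDUOUS
    return CompositionClass.MIXED


def plot_aboveground_pools(trees: pd.DataFrame, shrubs: pd.DataFrame,
                           cwd: pd.DataFrame, plot: pd.Series,
                           table: AllometricTable) -> dict[str, float]:
    """Aboveground C pools (g C m^-2) of one plot, split by component.

    Live trees, snags and shrubs are normalised by their sampling areas
    (belt transect for trees/snags, half-belt subplot for shrubs); CWD uses
    the line-intercept estimator.  Returns pre_fire/post_fire/combusted for
    each of trees, snags, shrubs, cwd plus aboveground totals.
    """
    belt = float(plot["belt_area_m2"])
    shrub_area = float(plot["shrub_subplot_area_m2"])
    out: dict[str, float] = {}

    tp = tree_pools(trees, table) if len(trees) else pd.DataFrame(
        columns=["pre_fire_status", "pre_fire_kg", "combusted_kg",
                 "post_fire_kg"])
    for label, status in (("trees", "live"), ("snags", "snag")):
        sub = tp[tp["pre_fire_status"] == status]
        for pool in ("pre_fire", "combusted", "post_fire"):
            kg_m2 = sub[f"{pool}_kg"].sum() / belt
            out[f"{label}_{pool}"] = kg_m2 * CARBON_FRACTION * 1000.0

    sp = shrub_pools(shrubs, table) if len(shrubs) else None
    for pool in ("pre_fire", "combusted", "post_fire"):
        kg_m2 = (sp[f"{pool}_kg"].sum() / shrub_area) if sp is not None else 0.0
        out[f"shrubs_{pool}"] = kg_m2 * CARBON_FRACTION * 1000.0

    cp = cwd_pools(cwd, float(plot["transect_length_m"]), table) if len(cwd) \
        else {"pre_fire": 0.0, "combusted": 0.0, "post_fire": 0.0}
    for pool in ("pre_fire", "combusted", "post_fire"):
        out[f"cwd_{pool}"] = cp[pool] * CARBON_FRACTION * 1000.0

    for pool in ("pre_fire", "combusted", "post_fire"):
        out[f"aboveground_{pool}"] = sum(
            out[f"{c}_{pool}"] for c in ("trees", "snags", "shrubs", "cwd"))
    return out
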