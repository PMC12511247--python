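"""Synthetic field campaigns with known truth.

The generator emulates the sampling design of an Interior-Alaska reburn
campaign — fires containing 5-7 sites, three 10 m x 2 m plots per site,
2-3 measurement points and paired 1 m^2 seedling quadrats per plot, one
residual SOL monolith per plot, plus unburned reference SOL profiles — under
five fire-return-interval classes with class-specific stand ages, pre-fire
SOL depths, burn depths, stand structure and regeneration intensities.

Every latent quantity (true pre-fire depth, true burn depth, true biomass
pools, true depth->C curves, site random effects) is recorded in a truth
dictionary so downstream stages have parameter-recovery oracles.  Identical
seeds give identical output; per-site random substreams keep sites
reproducible under partial regeneration.

Default parameter values are calibrated so class-mean pools land near the
magnitudes reported for Interior-Alaska reburns; they are a calibration
device, not field truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from reburn.burn_depth import AR_OFFSET_CM
from reburn.core_data import (
    COMBUSTION_CLASSES,
    SHRUB_COMPONENTS,
    TREE_COMPONENTS,
    CompositionClass,
    Dataset,
    FRIClass,
    SOLRegime,
    empty_table,
    format_year_list,
    write_dataset,
)
from reburn.errors import ConfigError
from reburn.soil import NOMINAL_INCREMENT_CM, depth_class
from reburn.vegetation import AllometricTable, plot_aboveground_pools

FRI_VALUES = [c.value for c in FRIClass]
COMP_VALUES = [c.value for c in CompositionClass]

SPRUCE = "Picea mariana"
DECIDUOUS_TREES = ("Populus tremuloides", "Betula neoalaskana")
SHRUB_SPECIES = ("Salix spp.", "Alnus spp.", "Betula spp.")

#: Additive severity shifts per biomass component (foliage burns first).
COMPONENT_SEVERITY_SHIFT = {
    "stem": -0.10, "bark": 0.0, "coarse_branches": 0.0,
    "fine_branches": 0.15, "foliage": 0.25, "cones": 0.10,
    "branches": 0.10,
}


def _per_class(values: dict) -> dict[str, float]:
    missing = set(FRI_VALUES) - set(values)
    if missing:
        raise ConfigError(f"per-class table missing classes {sorted(missing)}")
    return values


@dataclass
class SimConfig:
    """Truth parameters of a synthetic campaign.

    Per-class dictionaries are keyed by FRI class value; SOL truth curves by
    composition class.  ``sol_curves`` holds the log-scale fixed effects of
    the depth-wise gamma model used both to draw increment pools and as the
    recovery target: intercept, depth slope, the two depth-class offsets and
    the two depth-by-class interactions.
    """

    n_fires: int = 31
    sites_per_fire: tuple[int, int] = (5, 7)
    plots_per_site: int = 3
    points_per_plot: tuple[int, int] = (2, 3)

    #: FRI class mix over sites (long/mid/short/triple_mid/triple_short).
    class_mix: dict = field(default_factory=lambda: {
        "long": 68 / 185, "mid": 47 / 185, "short": 44 / 185,
        "triple_mid": 13 / 185, "triple_short": 13 / 185})

    #: stand age at fire: class -> (mean, sd, low, high), truncated normal.
    stand_age: dict = field(default_factory=lambda: {
        "long": (102.0, 25.0, 71.0, 260.0), "mid": (45.7, 9.0, 32.0, 70.0),
        "short": (15.9, 3.5, 11.0, 29.0), "triple_mid": (39.5, 8.0, 31.0, 70.0),
        "triple_short": (21.0, 3.0, 12.0, 29.0)})

    #: site composition mix per FRI class.
    composition_mix: dict = field(default_factory=lambda: {
        "long": {"spruce": .87, "mixed": .05, "deciduous": .06, "open": .02},
        "mid": {"spruce": .83, "mixed": .09, "deciduous": .06, "open": .02},
        "short": {"spruce": .23, "mixed": .15, "deciduous": .52, "open": .10},
        "triple_mid": {"spruce": .46, "mixed": .16, "deciduous": .23,
                       "open": .15},
        "triple_short": {"spruce": .46, "mixed": .38, "deciduous": .08,
                         "open": .08}})

    #: pre-fire SOL depth (cm): class -> (lognormal median, sigma).
    prefire_depth: dict = field(default_factory=lambda: {
        "long": (26.0, 0.30), "mid": (19.0, 0.30), "short": (12.5, 0.30),
        "triple_mid": (18.5, 0.30), "triple_short": (14.0, 0.30)})

    #: mean fraction of the pre-fire SOL depth combusted, per class.
    burn_fraction: dict = field(default_factory=lambda: {
        "long": 0.38, "mid": 0.45, "short": 0.55, "triple_mid": 0.34,
        "triple_short": 0.44})
    burn_fraction_concentration: float = 12.0

    #: pre-fire tree density (stems m^-2) per class.
    tree_density: dict = field(default_factory=lambda: {
        "long": 0.97, "mid": 1.24, "short": 0.55, "triple_mid": 0.62,
        "triple_short": 1.44})
    #: fraction of pre-fire stems standing dead (snags) per class.
    snag_fraction: dict = field(default_factory=lambda: {
        "long": 0.08, "mid": 0.10, "short": 0.40, "triple_mid": 0.25,
        "triple_short": 0.15})
    #: latent aboveground combustion severity mean per class (beta scale).
    severity: dict = field(default_factory=lambda: {
        "long": 0.30, "mid": 0.36, "short": 0.42, "triple_mid": 0.47,
        "triple_short": 0.33})
    severity_concentration: float = 10.0

    shrubs_per_subplot: float = 8.0
    cwd_pieces: dict = field(default_factory=lambda: {
        "long": 8.0, "mid": 8.0, "short": 14.0, "triple_mid": 8.0,
        "triple_short": 6.0})

    #: SOL truth curves: regime -> composition -> fixed effects (log scale).
    sol_curves: dict = field(default_factory=lambda: {
        regime: {
            "spruce": {"intercept": 7.05, "depth": 0.022, "d10_20": 0.15,
                       "d20plus": 0.25, "depth:d10_20": 0.0,
                       "depth:d20plus": 0.0},
            "mixed": {"intercept": 6.90, "depth": 0.022, "d10_20": 0.15,
                      "d20plus": 0.25, "depth:d10_20": 0.0,
                      "depth:d20plus": 0.0},
            "deciduous": {"intercept": 6.80, "depth": 0.022, "d10_20": 0.15,
                          "d20plus": 0.25, "depth:d10_20": 0.0,
                          "depth:d20plus": 0.0},
            "open": {"intercept": 6.70, "depth": 0.022, "d10_20": 0.15,
                     "d20plus": 0.25, "depth:d10_20": 0.0,
                     "depth:d20plus": 0.0},
        } for regime in ("residual_burned_sites", "unburned_reference")})
    sol_site_sd: float = 0.3
    sol_gamma_shape: float = 2.0
    sol_c_fraction: float = 0.42

    #: unburned reference sampling: composition -> (n_sites, profiles/site),
    #: mirroring the ~111-site unburned reference network (mostly spruce).
    reference_profiles: dict = field(default_factory=lambda: {
        "spruce": (70, 2), "mixed": (13, 2), "deciduous": (16, 2),
        "open": (12, 2)})
    #: unburned SOL depth (cm): composition -> (lognormal median, sigma).
    reference_depth: dict = field(default_factory=lambda: {
        "spruce": (28.0, 0.25), "mixed": (20.0, 0.25),
        "deciduous": (16.0, 0.25), "open": (14.0, 0.25)})

    #: seedling truth: fri -> composition -> (p_fail, spruce m^-2, decid m^-2)
    seedlings: dict = field(default_factory=lambda: {
        "long": {"spruce": (.08, 2.0, .3), "deciduous": (.05, .1, 3.0),
                 "mixed": (.08, 1.0, 1.0), "open": (.5, .05, .1)},
        "mid": {"spruce": (.12, 1.5, .3), "deciduous": (.05, .1, 3.0),
                "mixed": (.10, 1.0, 1.0), "open": (.5, .05, .1)},
        "short": {"spruce": (.50, .3, .5), "deciduous": (.20, .05, 2.0),
                  "mixed": (.40, .3, .8), "open": (.8, .02, .05)},
        "triple_mid": {"spruce": (.75, .1, .1), "deciduous": (.5, .02, .5),
                       "mixed": (.60, .1, .3), "open": (.9, .01, .02)},
        "triple_short": {"spruce": (.60, .1, .3), "deciduous": (.4, .05, 1.0),
                         "mixed": (.55, .1, .5), "open": (.85, .01, .05)}})

    allometry: dict | None = None  # truth coefficient tables (None -> default)
    rng_seed: int = 0

    def validate(self) -> None:
        for name, probs in (("class_mix", self.class_mix),):
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                raise ConfigError(f"{name} probabilities must sum to 1")
        for cls, mix in self.composition_mix.items():
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ConfigError(
                    f"composition_mix[{cls}] probabilities must sum to 1")
        for cls in ("triple_mid", "triple_short"):
            _, _, lo, hi = self.stand_age[cls]
            if hi > 70:
                raise ConfigError(
                    f"{cls}: three fires in < 70 years is incompatible with "
                    f"stand age up to {hi}")
        if self.sol_site_sd < 0 or self.sol_gamma_shape <= 0:
            raise ConfigError("SOL dispersion parameters must be positive")

    def allometric_table(self) -> AllometricTable:
        if self.allometry is None:
            return AllometricTable.default()
        return AllometricTable.from_dict(self.allometry)


def _truncnorm(rng, mean, sd, lo, hi):
    for _ in range(200):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(mean, lo, hi))


def _discretize_combustion(x: float) -> float:
    return float(COMBUSTION_CLASSES[int(np.argmin(
        [abs(x - c) for c in COMBUSTION_CLASSES]))])


def curve_eval(curve: dict, depth_mid: float) -> float:
    """Log-mean increment pool (per nominal 5-cm) of a truth curve."""
    eta = curve["intercept"] + curve["depth"] * depth_mid
    dc = depth_class(depth_mid)
    if dc == "d10_20":
        eta += curve["d10_20"] + curve["depth:d10_20"] * depth_mid
    elif dc == "d20plus":
        eta += curve["d20plus"] + curve["depth:d20plus"] * depth_mid
    return eta


def curve_cumulative(curve: dict, depth_cm: float) -> float:
    """Population-level cumulative C over [0, depth) under a truth curve."""
    total, top = 0.0, 0.0
    while top < depth_cm - 1e-12:
        bot = min(top + NOMINAL_INCREMENT_CM, depth_cm)
        total += np.exp(curve_eval(curve, 0.5 * (top + bot))) \
            * (bot - top) / NOMINAL_INCREMENT_CM
        top = bot
    return float(total)


def simulate_sol_profile(depth_cm: float, composition: str | CompositionClass,
                         site_effect: float, rng: np.random.Generator,
                         config: SimConfig | None = None,
                         regime: str = "residual_burned_sites") -> pd.DataFrame:
    """Draw one SOL profile as gamma increment pools around the truth curve.

    Increments are nominal 5-cm slabs plus a variable-depth bottom slab; the
    pool of each is gamma with mean
    ``exp(curve(midpoint) + site_effect) * thickness/5`` and the configured
    shape.  Returns columns top/bottom/depth_mid/thickness/c_pool.
    """
    if depth_cm < 0:
        raise ValueError("profile depth must be non-negative")
    config = config or SimConfig()
    composition = CompositionClass(composition).value
    curve = config.sol_curves[SOLRegime(regime).value][composition]
    rows, top = [], 0.0
    while top < depth_cm - 1e-12:
        bot = min(top + NOMINAL_INCREMENT_CM, depth_cm)
        mid = 0.5 * (top + bot)
        mean = np.exp(curve_eval(curve, mid) + site_effect) \
            * (bot - top) / NOMINAL_INCREMENT_CM
        shape = config.sol_gamma_shape
        pool = rng.gamma(shape, mean / shape)
        rows.append({"top_depth_cm": top, "bottom_depth_cm": bot,
                     "depth_mid": mid, "thickness": bot - top,
                     "c_pool": float(pool)})
        top = bot
    return pd.DataFrame(rows)


def _profile_to_lab_rows(profile: pd.DataFrame, config: SimConfig,
                         rng: np.random.Generator) -> list[dict]:
    """Back out lab measurements (mass, dimensions, rocks) from drawn pools."""
    out = []
    for _, r in profile.iterrows():
        thick = r["thickness"]
        length = width = 10.0
        rock = float(rng.uniform(0.0, 0.05) * length * width * thick
                     if rng.random() < 0.2 else 0.0)
        cfrac = config.sol_c_fraction
        bd = r["c_pool"] / (thick * cfrac * 1e4)
        mass = bd * (length * width * thick - rock)
        out.append({"top_depth_cm": r["top_depth_cm"],
                    "bottom_depth_cm": r["bottom_depth_cm"],
                    "fine_dry_mass_g": mass, "sample_length_cm": length,
                    "sample_width_cm": width, "rock_volume_cm3": rock,
                    "c_fraction": cfrac})
    return out


def _draw_trees(rng, comp, cls, config, plot_id, belt_area, severity_plot,
                table) -> list[dict]:
    if comp == "open":
        return []
    n = rng.poisson(config.tree_density[cls] * belt_area)
    p_dec = {"spruce": 0.05, "mixed": 0.5, "deciduous": 0.9}[comp]
    age = config.stand_age[cls][0]
    rows = []
    for i in range(n):
        deciduous = rng.random() < p_dec
        spp = rng.choice(DECIDUOUS_TREES) if deciduous else SPRUCE
        d = float(np.exp(rng.normal(np.log(3.2 + 0.012 * age), 0.4)))
        snag = rng.random() < config.snag_fraction[cls]
        comb = {}
        for cmp_ in TREE_COMPONENTS:
            latent = severity_plot + COMPONENT_SEVERITY_SHIFT[cmp_] \
                + rng.normal(0.0, 0.15)
            comb[cmp_] = _discretize_combustion(float(np.clip(latent, 0, 1)))
        rows.append({"tree_id": f"{plot_id}-T{i:03d}", "plot_id": plot_id,
                     "species": spp,
                     "pre_fire_status": "snag" if snag else "live",
                     "diameter_cm": round(d, 2),
                     **{f"comb_{c}": comb[c] for c in TREE_COMPONENTS}})
    return rows


def _draw_shrubs(rng, cls, config, plot_id, subplot_area, severity_plot
                 ) -> list[dict]:
    n = rng.poisson(config.shrubs_per_subplot)
    rows = []
    for i in range(n):
        spp = str(rng.choice(SHRUB_SPECIES))
        d = float(np.exp(rng.normal(np.log(1.2), 0.4)))
        comb = {}
        for cmp_ in SHRUB_COMPONENTS:
            latent = severity_plot + COMPONENT_SEVERITY_SHIFT[cmp_] \
                + rng.normal(0.0, 0.15)
            comb[cmp_] = _discretize_combustion(float(np.clip(latent, 0, 1)))
        rows.append({"shrub_id": f"{plot_id}-S{i:03d}", "plot_id": plot_id,
                     "species": spp, "basal_diameter_cm": round(d, 2),
                     **{f"comb_{c}": comb[c] for c in SHRUB_COMPONENTS}})
    return rows


def _draw_cwd(rng, cls, config, plot_id, severity_plot) -> list[dict]:
    n = rng.poisson(config.cwd_pieces[cls])
    rows = []
    for i in range(n):
        d = 2.0 + float(np.exp(rng.normal(np.log(3.0), 0.6)))
        decay = str(rng.choice(["hard", "crumbly", "soft"],
                               p=[0.5, 0.3, 0.2]))
        conc = 6.0
        m = float(np.clip(severity_plot, 0.02, 0.98))
        frac = float(rng.beta(m * conc, (1 - m) * conc))
        rows.append({"piece_id": f"{plot_id}-W{i:03d}", "plot_id": plot_id,
                     "species": SPRUCE if rng.random() < 0.6 else None,
                     "diameter_cm": round(d, 2), "decay_class": decay,
                     "combustion_fraction": round(frac, 3)})
    return rows


def simulate_campaign(config: SimConfig | None = None,
                      seed: int | None = None) -> tuple[Dataset, dict]:
    """Generate a full synthetic campaign and its truth record.

    Returns ``(dataset, truth)``; the dataset passes
    :func:`reburn.core_data.validate` and the truth dict stores every latent
    quantity needed for parameter recovery, including per-plot truth carbon
    pools and the SOL truth curves.  The same config and seed always produce
    the same output.
    """
    config = config or SimConfig()
    config.validate()
    seed = config.rng_seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root)
    table = config.allometric_table()

    fires, sites, plots = [], [], []
    trees, shrubs, cwd, points, sol_rows, quadrats = [], [], [], [], [], []
    truth_points, truth_plots, truth_sites = [], [], {}
    site_effects = {}

    site_counter = 0
    for fi in range(config.n_fires):
        fire_id = f"F{fi:03d}"
        burn_year = int(rng.integers(2018, 2022))
        fire_priors: set[int] = set()
        n_sites = int(rng.integers(config.sites_per_fire[0],
                                   config.sites_per_fire[1] + 1))
        for si in range(n_sites):
            site_id = f"S{site_counter:04d}"
            site_counter += 1
            srng = np.random.default_rng(
                np.random.SeedSequence(entropy=root.entropy,
                                       spawn_key=(fi, si)))
            cls = str(srng.choice(FRI_VALUES,
                                  p=[config.class_mix[c] for c in FRI_VALUES]))
            age = _truncnorm(srng, *config.stand_age[cls])
            comp_mix = config.composition_mix[cls]
            site_comp = str(srng.choice(COMP_VALUES,
                                        p=[comp_mix[c] for c in COMP_VALUES]))
            ysf = int(srng.integers(1, 5))
            b_eff = float(srng.normal(0.0, config.sol_site_sd))
            site_effects[site_id] = b_eff

            # fire history consistent with the class
            if cls == "long":
                priors = []
            elif cls in ("mid", "short"):
                priors = [burn_year - int(round(age))]
            else:
                first = burn_year - int(round(age)) - int(srng.integers(20, 41))
                priors = [first, burn_year - int(round(age))]
            fire_priors.update(priors)

            sites.append({
                "site_id": site_id, "fire_id": fire_id,
                "fri_class_history": cls, "fri_class_final": cls,
                "stand_age_at_fire": round(age, 1),
                "years_since_fire_at_sampling": ysf,
                "drainage_class": int(srng.integers(1, 7)),
                "permafrost_detected": int(srng.random() < 0.3),
                "elevation": round(float(srng.uniform(80, 830)), 1),
                "slope": round(float(srng.uniform(0, 0.5)), 3),
                "aspect": round(float(srng.uniform(0, 6.28)), 2)})
            truth_sites[site_id] = {"fri_class": cls, "composition": site_comp,
                                    "site_effect": b_eff}

            med, sigma = config.prefire_depth[cls]
            site_depth = float(med * np.exp(srng.normal(0.0, sigma)))
            frac_mean = config.burn_fraction[cls]
            conc = config.burn_fraction_concentration
            use_ar = site_comp == "spruce" and age >= 30

            for pi in range(config.plots_per_site):
                plot_id = f"{site_id}-P{pi}"
                plots.append({"plot_id": plot_id, "site_id": site_id,
                              "belt_area_m2": 20.0,
                              "shrub_subplot_area_m2": 10.0,
                              "transect_length_m": 10.0})
                sev = float(np.clip(srng.beta(
                    config.severity[cls] * config.severity_concentration,
                    (1 - config.severity[cls]) *
                    config.severity_concentration), 0.02, 0.98))
                plot_trees = _draw_trees(srng, site_comp, cls, config, plot_id,
                                         20.0, sev, table)
                plot_shrubs = _draw_shrubs(srng, cls, config, plot_id, 10.0,
                                           sev)
                plot_cwd = _draw_cwd(srng, cls, config, plot_id, sev)
                trees += plot_trees
                shrubs += plot_shrubs
                cwd += plot_cwd

                frac_plot = float(srng.beta(frac_mean * conc,
                                            (1 - frac_mean) * conc)) \
                    if frac_mean > 0 else 0.0
                n_pts = int(srng.integers(config.points_per_plot[0],
                                          config.points_per_plot[1] + 1))
                res_curve = config.sol_curves["residual_burned_sites"][site_comp]
                unb_curve = config.sol_curves["unburned_reference"][site_comp]
                pt_truths = []
                for qi in range(n_pts):
                    point_id = f"{plot_id}-pt{qi}"
                    prefire = site_depth * float(np.exp(srng.normal(0.0, 0.15)))
                    if use_ar:
                        prefire = max(prefire, AR_OFFSET_CM)
                    prefire = round(prefire, 2)
                    frac = float(np.clip(frac_plot + srng.normal(0.0, 0.05),
                                         0.02, 0.95)) if frac_mean > 0 else 0.0
                    burn = round(frac * prefire, 2)
                    if use_ar and 0.0 < burn < AR_OFFSET_CM:
                        burn = min(AR_OFFSET_CM, prefire)  # roots at surface
                    residual = round(prefire - burn, 2)
                    arh = [None, None, None]
                    if use_ar and burn >= AR_OFFSET_CM:
                        base = round(burn - AR_OFFSET_CM, 2)
                        n_roots = int(srng.integers(1, 4))
                        if n_roots == 1:
                            vals = [base]
                        else:
                            delta = round(float(
                                srng.uniform(0, min(1.0, base))), 2) \
                                if base > 0 else 0.0
                            vals = [round(base - delta, 2),
                                    round(base + delta, 2)]
                            if n_roots == 3:
                                vals = [base] + vals
                        arh[:len(vals)] = vals
                    thaw = float(srng.uniform(20, 80))
                    frozen = int(srng.random() < 0.7)
                    points.append({
                        "point_id": point_id, "plot_id": plot_id,
                        "residual_sol_depth_cm": residual,
                        "thaw_depth_cm": None if frozen else round(thaw, 1),
                        "frozen_not_reached": frozen,
                        "arh1_cm": arh[0], "arh2_cm": arh[1],
                        "arh3_cm": arh[2]})
                    resid_c = curve_cumulative(res_curve, residual)
                    comb_c = curve_cumulative(unb_curve, burn)
                    truth_points.append({
                        "point_id": point_id, "plot_id": plot_id,
                        "site_id": site_id, "prefire_depth_cm": prefire,
                        "burn_depth_cm": burn, "residual_depth_cm": residual,
                        "residual_c": resid_c, "combusted_c": comb_c,
                        "prefire_c": resid_c + comb_c})
                    pt_truths.append((residual, burn, resid_c, comb_c))

                    # one paired seedling quadrat per point
                    p_fail, s_rate, d_rate = \
                        config.seedlings[cls][site_comp]
                    failed = truth_sites[site_id].setdefault(
                        "regen_failed", bool(srng.random() < p_fail))
                    quadrat_id = f"{point_id}-q"
                    any_row = False
                    if not failed:
                        for spp, rate in ((SPRUCE, s_rate),
                                          (DECIDUOUS_TREES[0], d_rate)):
                            cnt = int(srng.poisson(rate))
                            if cnt == 0:
                                continue
                            any_row = True
                            bds = [round(float(np.exp(
                                srng.normal(np.log(0.3), 0.3))), 3)
                                for _ in range(min(cnt, 3))]
                            bds += [None] * (3 - len(bds))
                            quadrats.append({
                                "quadrat_id": quadrat_id, "plot_id": plot_id,
                                "area_m2": 1.0, "species": spp, "count": cnt,
                                "bd1_cm": bds[0], "bd2_cm": bds[1],
                                "bd3_cm": bds[2], "search_quadrat": 0})
                    if not any_row:
                        quadrats.append({
                            "quadrat_id": quadrat_id, "plot_id": plot_id,
                            "area_m2": 1.0, "species": None, "count": 0,
                            "bd1_cm": None, "bd2_cm": None, "bd3_cm": None,
                            "search_quadrat": 0})

                # one residual SOL monolith per plot, taken at point 0
                mono_residual = pt_truths[0][0]
                profile = simulate_sol_profile(
                    mono_residual, site_comp, b_eff, srng, config,
                    regime="residual_burned_sites")
                profile_id = f"{plot_id}-mono"
                for lab in _profile_to_lab_rows(profile, config, srng):
                    sol_rows.append({
                        "profile_id": profile_id, "group_id": site_id,
                        "plot_id": plot_id, "point_id": f"{plot_id}-pt0",
                        "composition": site_comp,
                        "regime": SOLRegime.RESIDUAL_BURNED.value, **lab})

                # truth plot pools: aboveground from the records themselves,
                # belowground as point means of population-curve pools
                plot_df = pd.Series({"belt_area_m2": 20.0,
                                     "shrub_subplot_area_m2": 10.0,
                                     "transect_length_m": 10.0})
                ag = plot_aboveground_pools(
                    pd.DataFrame(plot_trees, columns=list(
                        empty_table("trees").columns)),
                    pd.DataFrame(plot_shrubs, columns=list(
                        empty_table("shrubs").columns)),
                    pd.DataFrame(plot_cwd, columns=list(
                        empty_table("cwd").columns)),
                    plot_df, table)
                bg_post = float(np.mean([t[2] for t in pt_truths]))
                bg_comb = float(np.mean([t[3] for t in pt_truths]))
                truth_plots.append({
                    "plot_id": plot_id, "site_id": site_id, "fri_class": cls,
                    "composition": site_comp,
                    "aboveground_pre_fire": ag["aboveground_pre_fire"],
                    "aboveground_post_fire": ag["aboveground_post_fire"],
                    "aboveground_combusted": ag["aboveground_combusted"],
                    "belowground_post_fire": bg_post,
                    "belowground_combusted": bg_comb,
                    "belowground_pre_fire": bg_post + bg_comb})

        fires.append({"fire_id": fire_id, "burn_year": burn_year,
                      "prior_burn_years":
                          format_year_list(sorted(fire_priors))})

    # unburned reference SOL profiles (separate reference sites)
    ref_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=root.entropy, spawn_key=(99999,)))
    for comp, (n_ref_sites, per_site) in config.reference_profiles.items():
        med, sigma = config.reference_depth[comp]
        for ri in range(n_ref_sites):
            gid = f"REF-{comp}-{ri:03d}"
            b_eff = float(ref_rng.normal(0.0, config.sol_site_sd))
            for pj in range(per_site):
                depth = float(med * np.exp(ref_rng.normal(0.0, sigma)))
                profile = simulate_sol_profile(
                    depth, comp, b_eff, ref_rng, config,
                    regime="unburned_reference")
                for lab in _profile_to_lab_rows(profile, config, ref_rng):
                    sol_rows.append({
                        "profile_id": f"{gid}-{pj}", "group_id": gid,
                        "plot_id": None, "point_id": None,
                        "composition": comp,
                        "regime": SOLRegime.UNBURNED_REFERENCE.value, **lab})

    def frame(rows, name):
        if not rows:
            return empty_table(name)
        df = pd.DataFrame(rows)
        for col in empty_table(name).columns:
            if col not in df.columns:
                df[col] = None
        return df[list(empty_table(name).columns)]

    ds = Dataset(fires=frame(fires, "fires"), sites=frame(sites, "sites"),
                 plots=frame(plots, "plots"), trees=frame(trees, "trees"),
                 shrubs=frame(shrubs, "shrubs"), cwd=frame(cwd, "cwd"),
                 points=frame(points, "points"),
                 sol_increments=frame(sol_rows, "sol_increments"),
                 quadrats=frame(quadrats, "quadrats"))

    truth = {
        "seed": seed,
        "config": {k: v for k, v in asdict(config).items()
                   if k != "allometry"},
        "sol_curves": config.sol_curves,
        "sol_site_sd": config.sol_site_sd,
        "sol_gamma_shape": config.sol_gamma_shape,
        "site_effects": site_effects,
        "sites": truth_sites,
        "points": truth_points,
        "plot_pools": truth_plots,
    }
    return ds, truth


#: Belowground (pre-fire, combusted) class-mean magnitudes (g C m^-2) of the
#: published Interior-Alaska accounting, used as calibration targets.
PUBLISHED_BELOWGROUND = {
    "long": (8240.0, 3157.0), "mid": (6039.0, 2689.0),
    "short": (4566.0, 2525.0), "triple_mid": (6260.0, 2149.0),
    "triple_short": (5822.0, 2553.0)}


def _expected_class_pools(config: SimConfig, cls: str, median: float,
                          frac: float) -> tuple[float, float]:
    """Expected class-mean (pre-fire, combusted) belowground pools.

    Averages the population-curve pools over the composition mix and the
    lognormal depth spread; the pre-fire pool is residual-curve C over the
    residual depth plus reference-curve C over the burn depth, mirroring the
    reconstruction.
    """
    from scipy.stats import norm
    sigma = float(np.hypot(config.prefire_depth[cls][1], 0.15))
    qs = norm.ppf(np.linspace(0.1, 0.9, 5))
    mix = config.composition_mix[cls]
    pre = comb = 0.0
    for comp, w in mix.items():
        res_curve = config.sol_curves["residual_burned_sites"][comp]
        unb_curve = config.sol_curves["unburned_reference"][comp]
        for q in qs:
            depth = median * float(np.exp(sigma * q))
            c = curve_cumulative(unb_curve, frac * depth)
            r = curve_cumulative(res_curve, (1.0 - frac) * depth)
            comb += w / len(qs) * c
            pre += w / len(qs) * (r + c)
    return pre, comb


def calibrated_config(targets: dict | None = None,
                      **overrides) -> SimConfig:
    """A SimConfig whose truth belowground class pools hit target magnitudes.

    Solves, per FRI class, for the pre-fire depth median and mean burn
    fraction that put the expected class-mean pre-fire and combusted
    belowground pools at *targets* (default: the published class-mean
    magnitudes).  Other fields can be overridden via keyword arguments.
    """
    from scipy.optimize import brentq
    targets = targets or PUBLISHED_BELOWGROUND
    config = SimConfig(**overrides)
    depth_cfg, frac_cfg = {}, {}
    for cls, (pre_target, comb_target) in targets.items():
        sigma = config.prefire_depth[cls][1]
        med, frac = 25.0, 0.4
        for _ in range(4):  # alternate the two 1-D solves; converges fast
            med = brentq(lambda m: _expected_class_pools(config, cls, m,
                                                         frac)[0] - pre_target,
                         2.0, 150.0, xtol=1e-3)
            frac = brentq(lambda f: _expected_class_pools(config, cls, med,
                                                          f)[1] - comb_target,
                          0.01, 0.98, xtol=1e-5)
        depth_cfg[cls] = (float(med), sigma)
        frac_cfg[cls] = float(frac)
    config.prefire_depth = depth_cfg
    config.burn_fraction = frac_cfg
    return config


def truth_plot_pools(truth: dict) -> pd.DataFrame:
    """Truth carbon pools per plot as a DataFrame, with totals."""
    df = pd.DataFrame(truth["plot_pools"])
    for pool in ("pre_fire", "post_fire", "combusted"):
        df[f"total_{pool}"] = df[f"aboveground_{pool}"] \
            + df[f"belowground_{pool}"]
    return df


def truth_predictor(truth: dict) -> Callable:
    """Pre-fire depth predictor returning the exact truth at each point."""
    by_point = {p["point_id"]: p["prefire_depth_cm"]
                for p in truth["points"]}

    def predict(context: pd.Series) -> float:
        return float(by_point[str(context["point_id"])])
    return predict


def save_campaign(ds: Dataset, truth: dict, out_dir: str | Path) -> None:
    """Write the CSV files plus truth.json under *out_dir*."""
    out_dir = Path(out_dir)
    write_dataset(ds, out_dir)
    with open(out_dir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, default=float)
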