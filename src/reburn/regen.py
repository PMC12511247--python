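"""Post-fire regeneration: seedling density/biomass, successional-trajectory
classification, and contingency-table inference.

Sites are classified into post-fire trajectories by the same deciduous
fraction index used for pre-fire composition, computed over seedlings pooled
across a site's quadrats (6-9 m^2 of sampled area); a site with zero
seedlings is ``open`` (regeneration failure).  Sites sampled less than two
years after fire are excluded, since seedlings may not yet have emerged.

FRI-by-trajectory independence is tested with a chi-square statistic whose
p-value comes from Monte-Carlo resampling of margin-fixed tables (Patefield
sampling via :func:`scipy.stats.random_table`), followed by post hoc
standardized Pearson residuals with Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from reburn.core_data import CompositionClass
from reburn.vegetation import AllometricTable, classify_composition

#: Fallback basal diameter (cm) for counted seedlings of a species with no
#: measured individuals anywhere in the site.
DEFAULT_SEEDLING_DIAMETER_CM = 0.2


@dataclass
class SiteRegeneration:
    site_id: str
    sampled_area_m2: float
    density_by_species: dict[str, float]      # seedlings m^-2
    biomass_by_species: dict[str, float]      # kg dry matter m^-2
    post_fire_di: float
    trajectory: CompositionClass

    @property
    def total_density(self) -> float:
        return sum(self.density_by_species.values())


def site_regeneration(quadrats: pd.DataFrame, site: pd.Series,
                      table: AllometricTable, *, min_years_post_fire: float = 2.0,
                      count_search_quadrat_area: bool = True,
                      ) -> SiteRegeneration | None:
    """Seedling density, biomass and trajectory for one site.

    Returns None when the site was sampled sooner than *min_years_post_fire*
    after the fire (excluded from trajectory analyses).  Quadrats are pooled
    over the site; per-species individual biomass uses the mean measured
    basal diameter under seedling allometry, falling back to a nominal
    diameter when a counted species was never measured.  Trajectory is
    ``open`` exactly when the total seedling count is zero.
    """
    ysf = site.get("years_since_fire_at_sampling")
    if pd.notna(ysf) and float(ysf) < min_years_post_fire:
        return None
    q = quadrats
    if not count_search_quadrat_area and "search_quadrat" in q.columns:
        area_rows = q[(q["search_quadrat"].isna()) | (q["search_quadrat"] == 0)]
    else:
        area_rows = q
    area = float(area_rows.drop_duplicates("quadrat_id")["area_m2"].sum())
    if area <= 0:
        raise ValueError(f"site {site['site_id']} has zero sampled quadrat area")

    counts: dict[str, int] = {}
    diams: dict[str, list[float]] = {}
    for _, row in q.iterrows():
        spp = row["species"]
        if pd.isna(spp):
            continue
        counts[spp] = counts.get(spp, 0) + int(row["count"])
        for col in ("bd1_cm", "bd2_cm", "bd3_cm"):
            if pd.notna(row.get(col)):
                diams.setdefault(spp, []).append(float(row[col]))

    density = {spp: n / area for spp, n in counts.items() if n > 0}
    biomass = {}
    for spp, dens in density.items():
        a, b = table.seedling_coeffs(spp)
        ds = diams.get(spp) or [DEFAULT_SEEDLING_DIAMETER_CM]
        indiv_kg = float(np.mean([a * d ** b for d in ds]))
        biomass[spp] = dens * indiv_kg

    total = sum(density.values())
    if total == 0:
        di = float("nan")
        trajectory = CompositionClass.OPEN
    else:
        rel_dens = sum(d for s, d in density.items()
                       if table.is_deciduous(s)) / total
        total_bm = sum(biomass.values())
        rel_bm = (sum(b for s, b in biomass.items() if table.is_deciduous(s))
                  / total_bm) if total_bm > 0 else 0.0
        di = (rel_dens + rel_bm) / 2.0 * 100.0
        trajectory = classify_composition(di, any_trees=True)

    return SiteRegeneration(
        site_id=str(site["site_id"]), sampled_area_m2=area,
        density_by_species=density, biomass_by_species=biomass,
        post_fire_di=di, trajectory=trajectory)


def regeneration_table(ds, table: AllometricTable, *,
                       min_years_post_fire: float = 2.0) -> pd.DataFrame:
    """Site-level regeneration summary across a whole dataset.

    One row per included site: sampled area, total/spruce/deciduous seedling
    density, biomass, DI and trajectory.  Excluded (too-recent) sites are
    listed with ``included = 0`` and no trajectory.
    """
    plots_by_site = ds.plots.groupby("site_id")["plot_id"].apply(list)
    rows = []
    for _, site in ds.sites.iterrows():
        sid = site["site_id"]
        pids = plots_by_site.get(sid, [])
        q = ds.quadrats[ds.quadrats["plot_id"].isin(pids)]
        reg = site_regeneration(q, site, table,
                                min_years_post_fire=min_years_post_fire) \
            if len(q) else None
        if reg is None:
            rows.append({"site_id": sid, "fri_class": site["fri_class_final"],
                         "included": 0, "sampled_area_m2": np.nan,
                         "total_density": np.nan, "deciduous_density": np.nan,
                         "spruce_density": np.nan, "total_biomass": np.nan,
                         "post_fire_di": np.nan, "trajectory": None})
            continue
        dec = sum(d for s, d in reg.density_by_species.items()
                  if table.is_deciduous(s))
        rows.append({
            "site_id": sid, "fri_class": site["fri_class_final"],
            "included": 1, "sampled_area_m2": reg.sampled_area_m2,
            "total_density": reg.total_density,
            "deciduous_density": dec,
            "spruce_density": reg.total_density - dec,
            "total_biomass": sum(reg.biomass_by_species.values()),
            "post_fire_di": reg.post_fire_di,
            "trajectory": reg.trajectory.value})
    return pd.DataFrame(rows)


def trajectory_contingency(regen: pd.DataFrame) -> pd.DataFrame:
    """FRI-class x trajectory site counts over included sites."""
    inc = regen[regen["included"] == 1]
    return pd.crosstab(inc["fri_class"], inc["trajectory"])


@dataclass
class ContingencyResult:
    observed: pd.DataFrame
    expected: np.ndarray
    statistic: float
    mc_p_value: float
    n_replicates: int
    residuals: pd.DataFrame | None = None


def _chisq_stat(tables: np.ndarray, expected: np.ndarray) -> np.ndarray:
    dev = tables - expected
    return np.sum(dev * dev / expected, axis=(-2, -1))


def mc_chisq(table: pd.DataFrame | np.ndarray, B: int = 10_000,
             seed: int | np.random.Generator | None = 0) -> ContingencyResult:
    """Chi-square test of independence with a simulated null distribution.

    The null is sampled by Patefield's algorithm (random tables with the
    observed margins); ``p = (1 + #{X2* >= X2}) / (B + 1)``, deterministic
    for a given seed.
    """
    obs_df = pd.DataFrame(table)
    obs = obs_df.to_numpy(float)
    if obs.ndim != 2 or np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("table must be a 2-D array of non-negative counts")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("contingency table has a zero margin")
    expected = np.outer(row, col) / obs.sum()
    x2 = float(_chisq_stat(obs, expected))
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    sim = stats.random_table(row.astype(int), col.astype(int)).rvs(
        B, random_state=rng)
    x2_null = _chisq_stat(np.asarray(sim, float), expected)
    p = (1.0 + float(np.sum(x2_null >= x2 - 1e-12))) / (B + 1.0)
    return ContingencyResult(observed=obs_df, expected=expected, statistic=x2,
                             mc_p_value=p, n_replicates=B)


def posthoc_residuals(table: pd.DataFrame | np.ndarray,
                      method: str = "fdr_bh") -> pd.DataFrame:
    """Cell-wise standardized Pearson residuals with FDR-adjusted p-values.

    z = (O - E) / sqrt(E (1 - p_row)(1 - p_col)); two-sided normal p-values,
    adjusted jointly over all cells of the table (Benjamini-Hochberg by
    default).
    """
    obs_df = pd.DataFrame(table)
    obs = obs_df.to_numpy(float)
    n = obs.sum()
    row_p = obs.sum(axis=1) / n
    col_p = obs.sum(axis=0) / n
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    denom = np.sqrt(expected * np.outer(1.0 - row_p, 1.0 - col_p))
    z = (obs - expected) / denom
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    p_adj = multipletests(pvals.ravel(), method=method)[1].reshape(z.shape)
    rows = []
    for i, r in enumerate(obs_df.index):
        for j, c in enumerate(obs_df.columns):
            rows.append({"row": r, "col": c, "observed": obs[i, j],
                         "expected": expected[i, j], "residual": z[i, j],
                         "p_value": pvals[i, j], "p_adjusted": p_adj[i, j]})
    return pd.DataFrame(rows)
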