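"""Fire-return-interval class means and legacy-carbon accounting.

Legacy carbon is carbon that escaped combustion in one or more previous
fires.  For each reburned FRI class the carbon accumulated over the
fire-free interval is the class pre-fire pool minus a reference post-fire
pool: the long-FRI class post-fire mean for mid/short (whose previous
interval was long) and the mid-FRI post-fire mean for triple burns (whose
previous interval was most often mid).  Legacy loss is then

    G = L - A          (L = C lost in the most recent fire,
                        A = P_pre - P_ref accumulation)

with G > 0 meaning legacy carbon was combusted; the percent of the loss
attributable to legacy C is 100 * G / L.  The long class references its own
post-fire pool, so A = L and G = 0 identically there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from reburn.core_data import FRIClass
from reburn.errors import AccountingError

COMPONENTS = ("belowground", "aboveground", "total")

#: Which class's mean post-fire pool serves as the accumulation reference.
REFERENCE_CLASS = {
    FRIClass.LONG: FRIClass.LONG,          # self-reference: A = L, G = 0
    FRIClass.MID: FRIClass.LONG,
    FRIClass.SHORT: FRIClass.LONG,
    FRIClass.TRIPLE_MID: FRIClass.MID,
    FRIClass.TRIPLE_SHORT: FRIClass.MID,
}

#: Fire-free interval (years) per class used for annual accumulation rates.
DEFAULT_TAU = {"long": 102.0, "mid": 45.0, "short": 16.0,
               "triple_mid": 39.0, "triple_short": 21.0}


@dataclass
class LegacyRow:
    fri_class: str
    component: str
    postfire_reference_pool: float
    prefire_pool: float
    accumulation: float
    interval_years: float
    annual_rate: float
    loss: float
    legacy_loss: float
    pct_legacy: float


def class_mean_pools(plot_pools: pd.DataFrame,
                     value_cols: list[str] | None = None) -> pd.DataFrame:
    """Unweighted FRI-class means of plot pools, averaging sites first.

    *plot_pools* needs ``plot_id``, ``site_id``, ``fri_class`` plus numeric
    pool columns.  Plots are averaged within sites and sites within classes,
    respecting the sampling hierarchy.  Returns one row per class with means
    and between-site standard errors (columns suffixed ``_se``).
    """
    if value_cols is None:
        value_cols = [c for c in plot_pools.columns
                      if c not in ("plot_id", "site_id", "fri_class")
                      and pd.api.types.is_numeric_dtype(plot_pools[c])]
    site_means = (plot_pools.groupby(["fri_class", "site_id"], as_index=False)
                  [value_cols].mean())
    out_rows = []
    for cls in [c.value for c in FRIClass]:
        grp = site_means[site_means["fri_class"] == cls]
        if grp.empty:
            warnings.warn(f"FRI class '{cls}' has no plots; excluded",
                          stacklevel=2)
            continue
        row = {"fri_class": cls, "n_sites": len(grp)}
        for col in value_cols:
            vals = grp[col].to_numpy(float)
            row[col] = float(np.mean(vals))
            row[f"{col}_se"] = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) \
                if len(vals) > 1 else float("nan")
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def reference_pool(fri_class: FRIClass | str, component: str,
                   class_postfire: pd.DataFrame) -> float:
    """Reference post-fire pool P_ref for one class and pool component.

    *class_postfire* has one row per fri_class with columns
    ``{component}_post_fire``.
    """
    cls = FRIClass(fri_class)
    ref_cls = REFERENCE_CLASS[cls]
    sub = class_postfire[class_postfire["fri_class"] == ref_cls.value]
    if sub.empty:
        raise AccountingError(
            f"reference class '{ref_cls.value}' missing from class means "
            f"(needed for '{cls.value}')")
    return float(sub.iloc[0][f"{component}_post_fire"])


def legacy_rows(rows: pd.DataFrame) -> pd.DataFrame:
    """Core accounting on explicit per-row inputs.

    *rows* columns: ``fri_class``, ``component``, ``prefire_pool``,
    ``postfire_reference_pool``, ``loss``, ``interval_years``.  Adds
    ``accumulation`` A = P_pre - P_ref, ``annual_rate`` A/tau,
    ``legacy_loss`` G = L - A and ``pct_legacy`` = 100 G / L (NA with a
    warning when L = 0).
    """
    out = rows.copy()
    out["accumulation"] = out["prefire_pool"] - out["postfire_reference_pool"]
    out["annual_rate"] = out["accumulation"] / out["interval_years"]
    out["legacy_loss"] = out["loss"] - out["accumulation"]
    pct = np.full(len(out), np.nan)
    nonzero = out["loss"].to_numpy(float) != 0.0
    pct[nonzero] = 100.0 * out["legacy_loss"].to_numpy(float)[nonzero] \
        / out["loss"].to_numpy(float)[nonzero]
    if not nonzero.all():
        warnings.warn("zero C loss in some rows: %-legacy undefined (NA)",
                      stacklevel=2)
    out["pct_legacy"] = pct
    cols = ["fri_class", "component", "postfire_reference_pool",
            "prefire_pool", "accumulation", "interval_years", "annual_rate",
            "loss", "legacy_loss", "pct_legacy"]
    return out[cols]


def legacy_table(class_pools: pd.DataFrame,
                 tau: dict[str, float] | None = None) -> pd.DataFrame:
    """Full legacy accounting (5 classes x 3 components) from class means.

    *class_pools* has one row per fri_class with columns
    ``{belowground,aboveground}_{pre_fire,post_fire,combusted}``.  Total rows
    are component sums of P_pre, P_ref and L.  *tau* maps class -> fire-free
    interval years (defaults to the intervals implied by class stand ages).
    """
    tau = {**DEFAULT_TAU, **(tau or {})}
    present = list(class_pools["fri_class"])
    recs = []
    for cls in [c.value for c in FRIClass]:
        if cls not in present:
            continue
        row = class_pools[class_pools["fri_class"] == cls].iloc[0]
        parts = {}
        for comp in ("belowground", "aboveground"):
            parts[comp] = {
                "prefire_pool": float(row[f"{comp}_pre_fire"]),
                "postfire_reference_pool":
                    reference_pool(cls, comp, class_pools),
                "loss": float(row[f"{comp}_combusted"]),
            }
        parts["total"] = {k: parts["belowground"][k] + parts["aboveground"][k]
                          for k in parts["belowground"]}
        for comp in COMPONENTS:
            recs.append({"fri_class": cls, "component": comp,
                         "interval_years": float(tau[cls]), **parts[comp]})
    return legacy_rows(pd.DataFrame(recs))


def proportional_loss(class_pools: pd.DataFrame,
                      component: str = "total") -> pd.DataFrame:
    """Percent of the pre-fire pool combusted, per FRI class."""
    pre = class_pools[f"{component}_pre_fire"].to_numpy(float)
    loss = class_pools[f"{component}_combusted"].to_numpy(float)
    if np.any(pre <= 0):
        raise ValueError("pre-fire pools must be positive")
    return pd.DataFrame({"fri_class": class_pools["fri_class"],
                         "pct_of_prefire_lost": 100.0 * loss / pre})
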