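"""Burn-depth and pre-fire SOL-depth reconstruction per measurement point.

Two routes:

* **Adventitious-root method** — on black-spruce plots the height of
  adventitious roots above the residual SOL surface calibrates burn depth:
  ``burn_depth = mean(ARH) + 3.2 cm``, the offset being the depth at which
  adventitious roots sit within the intact SOL.
* **Modeled method** — elsewhere a pluggable pre-fire-depth predictor gives
  the expected pre-fire SOL depth; burn depth is the (zero-clamped)
  difference from the measured residual depth.

In both cases pre-fire depth = residual depth + burn depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from reburn.errors import ConfigError

#: Depth (cm) of adventitious roots within the intact soil organic layer.
AR_OFFSET_CM = 3.2


class BurnDepthMethod(str, Enum):
    ADVENTITIOUS_ROOT = "adventitious_root"
    MODELED = "modeled"


@dataclass
class BurnDepthEstimate:
    point_id: str
    method: BurnDepthMethod
    burn_depth: float
    pre_fire_sol_depth: float
    residual_sol_depth: float

    def __post_init__(self) -> None:
        if self.burn_depth < 0:
            raise ValueError("burn depth must be non-negative")
        if abs(self.pre_fire_sol_depth -
               (self.residual_sol_depth + self.burn_depth)) > 1e-9:
            raise ValueError("pre-fire depth must equal residual + burn depth")


def burn_depth_from_arh(arh_values: Sequence[float], *,
                        agg: str = "mean") -> float:
    """Burn depth (cm) from adventitious-root heights above the residual SOL.

    Heights from the 1-3 measured roots are aggregated (mean by default,
    median optionally) before adding the 3.2 cm root-depth offset.
    """
    vals = [float(v) for v in arh_values if v is not None and not np.isnan(v)]
    if not vals:
        raise ValueError(
            "no adventitious-root heights: route this point to the modeled "
            "method")
    if any(v < 0 for v in vals):
        raise ValueError("adventitious-root heights must be non-negative")
    if agg == "mean":
        centre = float(np.mean(vals))
    elif agg == "median":
        centre = float(np.median(vals))
    else:
        raise ConfigError(f"unknown ARH aggregation '{agg}'")
    return centre + AR_OFFSET_CM


def burn_depth_modeled(residual_depth: float, predicted_pre_fire_depth: float,
                       point_id: str = "") -> BurnDepthEstimate:
    """Burn depth as the zero-clamped model-minus-residual difference.

    When the residual SOL is deeper than the predicted pre-fire depth the
    burn depth is zero and the pre-fire depth is taken to be the residual
    depth itself.
    """
    if residual_depth < 0 or predicted_pre_fire_depth < 0:
        raise ValueError("depths must be non-negative")
    burn = max(0.0, predicted_pre_fire_depth - residual_depth)
    return BurnDepthEstimate(
        point_id=point_id, method=BurnDepthMethod.MODELED, burn_depth=burn,
        pre_fire_sol_depth=residual_depth + burn,
        residual_sol_depth=residual_depth)


#: A pre-fire-depth predictor takes the point's plot context (a mapping with
#: at least ``plot_id``, ``composition`` and ``drainage_class``) and returns a
#: non-negative depth in cm.
PrefireDepthPredictor = Callable[[pd.Series], float]


class LookupTablePredictor:
    """Pre-fire SOL depth from a (composition, drainage class) lookup table."""

    def __init__(self, table: dict[tuple[str, int], float],
                 default: float | None = None):
        self.table = {(str(c), int(d)): float(v) for (c, d), v in table.items()}
        self.default = default

    def __call__(self, context: pd.Series) -> float:
        key = (str(context["composition"]), int(context["drainage_class"]))
        if key in self.table:
            return self.table[key]
        if self.default is not None:
            return self.default
        raise ConfigError(
            f"no pre-fire depth configured for composition/drainage {key}")


def estimate_point_burn_depths(points: pd.DataFrame,
                               context: pd.DataFrame,
                               predictor: PrefireDepthPredictor | None,
                               *, agg: str = "mean") -> pd.DataFrame:
    """Burn-depth estimates for every measurement point.

    The adventitious-root method is used wherever at least one ARH value is
    present; all other points require *predictor*.  *context* maps plot_id to
    the columns predictors may need.  Returns one row per point with
    ``method``, ``burn_depth_cm``, ``pre_fire_sol_depth_cm``.
    """
    ctx = context.set_index("plot_id")
    rows = []
    for _, pt in points.iterrows():
        residual = float(pt["residual_sol_depth_cm"])
        arh = [pt.get("arh1_cm"), pt.get("arh2_cm"), pt.get("arh3_cm")]
        arh = [float(v) for v in arh if pd.notna(v)]
        if arh:
            burn = burn_depth_from_arh(arh, agg=agg)
            est = BurnDepthEstimate(
                point_id=pt["point_id"],
                method=BurnDepthMethod.ADVENTITIOUS_ROOT, burn_depth=burn,
                pre_fire_sol_depth=residual + burn,
                residual_sol_depth=residual)
        else:
            if predictor is None:
                raise ConfigError(
                    "points without adventitious roots present but no "
                    "pre-fire depth predictor registered")
            context_row = pd.concat([pt, ctx.loc[pt["plot_id"]]])
            context_row["plot_id"] = pt["plot_id"]
            predicted = float(predictor(context_row))
            if predicted < 0:
                raise ValueError(
                    "pre-fire depth predictor returned a negative depth "
                    f"({predicted}) for point {pt['point_id']}")
            est = burn_depth_modeled(residual, predicted, pt["point_id"])
        rows.append({"point_id": est.point_id, "plot_id": pt["plot_id"],
                     "method": est.method.value,
                     "residual_sol_depth_cm": est.residual_sol_depth,
                     "burn_depth_cm": est.burn_depth,
                     "pre_fire_sol_depth_cm": est.pre_fire_sol_depth})
    return pd.DataFrame(rows)


def plot_burn_depths(point_estimates: pd.DataFrame) -> pd.DataFrame:
    """Average point-level estimates to the plot level."""
    return (point_estimates
            .groupby("plot_id", as_index=False)
            .agg(burn_depth_cm=("burn_depth_cm", "mean"),
                 residual_sol_depth_cm=("residual_sol_depth_cm", "mean"),
                 pre_fire_sol_depth_cm=("pre_fire_sol_depth_cm", "mean"),
                 n_points=("point_id", "size")))
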