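"""Soil-organic-layer carbon: increment pools, depth-wise gamma mixed model,
and residual / combusted / pre-fire SOL carbon assembly.

Increment C pools (g C m^-2) come from monolith lab data as
``thickness * bulk_density * C_fraction * 1e4``, with bulk density the fine
dry mass over rock-corrected sample volume.  Pools are then modeled as a
gamma GLMM with log link: fixed effects are increment midpoint depth, depth
class (0-10, 10-20, > 20 cm) and their interaction, with a random site
intercept.  The marginal likelihood over site intercepts is maximised with a
Laplace approximation (one inner Newton per site).  An ``offset`` of
``log(thickness / 5)`` puts partial bottom increments on the same footing as
the nominal 5-cm increments.

Fitted models predict cumulative C over any depth interval by summing
increment-level predictions on a 5-cm grid (population level: random
intercept at zero).  Residual SOL C uses a model fitted to residual profiles
from burned sites; combusted C applies a model fitted to unburned reference
profiles over the burn-depth interval, because combustion removes the top of
the pre-fire profile.  Pre-fire SOL C is their sum.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.tools.numdiff import approx_hess3

from reburn.core_data import CompositionClass, SOLRegime
from reburn.errors import ConfigError, ConvergenceError

DEPTH_CLASSES = ("d0_10", "d10_20", "d20plus")
NOMINAL_INCREMENT_CM = 5.0

FIXED_EFFECT_NAMES = ("intercept", "depth", "d10_20", "d20plus",
                      "depth:d10_20", "depth:d20plus")


def depth_class(depth_mid_cm: float) -> str:
    """Depth class of an increment by its midpoint; ties go deeper."""
    if depth_mid_cm < 10.0:
        return "d0_10"
    if depth_mid_cm < 20.0:
        return "d10_20"
    return "d20plus"


def increment_c_pool(top_depth_cm: float, bottom_depth_cm: float,
                     fine_dry_mass_g: float, sample_length_cm: float,
                     sample_width_cm: float, rock_volume_cm3: float,
                     c_fraction: float) -> dict[str, float]:
    """Carbon pool of one depth increment from monolith lab measurements.

    bulk density (g cm^-3) = fine dry mass / (L*W*thickness - rock volume);
    C pool (g C m^-2) = thickness * bulk density * C fraction * 1e4.
    """
    if bottom_depth_cm <= top_depth_cm:
        raise ValueError("bottom depth must exceed top depth")
    if sample_length_cm <= 0 or sample_width_cm <= 0:
        raise ValueError("sample dimensions must be positive")
    thickness = bottom_depth_cm - top_depth_cm
    gross = sample_length_cm * sample_width_cm * thickness
    if rock_volume_cm3 >= gross:
        raise ValueError("rock volume equals or exceeds gross sample volume")
    bd = fine_dry_mass_g / (gross - rock_volume_cm3)
    mid = 0.5 * (top_depth_cm + bottom_depth_cm)
    return {
        "depth_mid": mid,
        "depth_class": depth_class(mid),
        "thickness": thickness,
        "bulk_density": bd,
        "c_pool": thickness * bd * c_fraction * 1e4,
    }


def build_increment_table(sol_increments: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`increment_c_pool` row-wise to a lab increments table."""
    rows = []
    for _, r in sol_increments.iterrows():
        pool = increment_c_pool(
            float(r["top_depth_cm"]), float(r["bottom_depth_cm"]),
            float(r["fine_dry_mass_g"]), float(r["sample_length_cm"]),
            float(r["sample_width_cm"]), float(r["rock_volume_cm3"]),
            float(r["c_fraction"]))
        rows.append({"profile_id": r["profile_id"], "group_id": r["group_id"],
                     "plot_id": r.get("plot_id"),
                     "point_id": r.get("point_id"),
                     "composition": r["composition"], "regime": r["regime"],
                     **pool})
    return pd.DataFrame(rows)


@dataclass
class DepthCModel:
    """Fitted depth-wise gamma GLMM for one composition class and regime."""

    composition: str
    regime: str
    coefficients: dict[str, float]
    site_intercept_sd: float
    gamma_shape: float
    converged: bool
    loglik: float
    n_obs: int
    n_groups: int
    se: dict[str, float] = field(default_factory=dict)
    reduced: bool = False  # True when only one depth class was present

    def linear_predictor(self, depth_mid: float) -> float:
        c = self.coefficients
        eta = c["intercept"] + c["depth"] * depth_mid
        if not self.reduced:
            dc = depth_class(depth_mid)
            if dc == "d10_20":
                eta += c["d10_20"] + c["depth:d10_20"] * depth_mid
            elif dc == "d20plus":
                eta += c["d20plus"] + c["depth:d20plus"] * depth_mid
        return eta

    def predict_increment(self, depth_mid: float,
                          thickness: float = NOMINAL_INCREMENT_CM) -> float:
        """Population-level increment pool (g C m^-2); partial increments
        scale by thickness / 5."""
        return float(np.exp(self.linear_predictor(depth_mid))
                     * thickness / NOMINAL_INCREMENT_CM)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({
                "composition": self.composition, "regime": self.regime,
                "coefficients": self.coefficients,
                "site_intercept_sd": self.site_intercept_sd,
                "gamma_shape": self.gamma_shape, "converged": self.converged,
                "loglik": self.loglik, "n_obs": self.n_obs,
                "n_groups": self.n_groups, "se": self.se,
                "reduced": self.reduced}, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "DepthCModel":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _design(depth_mid: np.ndarray, reduced: bool) -> np.ndarray:
    d = np.asarray(depth_mid, float)
    if reduced:
        return np.column_stack([np.ones_like(d), d])
    i10 = ((d >= 10) & (d < 20)).astype(float)
    i20 = (d >= 20).astype(float)
    return np.column_stack([np.ones_like(d), d, i10, i20, d * i10, d * i20])


def _laplace_nll(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                 offset: np.ndarray, group_idx: np.ndarray,
                 n_groups: int) -> float:
    """Negative Laplace-approximated marginal log-likelihood.

    theta = (beta..., log sigma_site, log gamma_shape).  The inner modes of
    all site intercepts are found jointly by vectorized Newton steps (the
    penalized log-likelihood in each b is strictly concave for the
    gamma/log-link family, so the iteration is globally convergent).
    """
    k = X.shape[1]
    beta = theta[:k]
    sigma2 = np.exp(2.0 * theta[k])
    shape = np.exp(theta[k + 1])
    inv_s2 = 1.0 / sigma2
    eta0 = X @ beta + offset
    b = np.zeros(n_groups)
    for _ in range(60):
        mu = np.exp(eta0 + b[group_idx])
        r = y / mu
        grad = shape * np.bincount(group_idx, r - 1.0, n_groups) - b * inv_s2
        hess = shape * np.bincount(group_idx, r, n_groups) + inv_s2
        step = np.clip(grad / hess, -5.0, 5.0)
        b += step
        if np.max(np.abs(step)) < 1e-13:
            break
    mu = np.exp(eta0 + b[group_idx])
    ll_obs = float(np.sum(shape * np.log(shape) - shape * np.log(mu)
                          + (shape - 1.0) * np.log(y) - shape * y / mu)
                   - len(y) * special.gammaln(shape))
    hess = shape * np.bincount(group_idx, y / mu, n_groups) + inv_s2
    ll = ll_obs - 0.5 * inv_s2 * float(np.sum(b * b)) \
        - 0.5 * n_groups * np.log(sigma2) - 0.5 * float(np.sum(np.log(hess)))
    return -ll


def fit_depth_model(increments: pd.DataFrame, composition: str | CompositionClass,
                    regime: str | SOLRegime, *, gtol: float = 1e-8,
                    max_iter: int = 500) -> DepthCModel:
    """Fit the depth-wise gamma GLMM for one composition class and regime.

    *increments* needs columns ``c_pool``, ``depth_mid``, ``thickness`` and
    ``group_id`` (already filtered or carrying ``composition``/``regime``
    columns, in which case the relevant subset is taken).  Requires at least
    2 sites and 12 increments.  When only one depth class is present a
    reduced intercept+depth model is fitted with a warning.
    """
    composition = CompositionClass(composition).value
    regime = SOLRegime(regime).value
    df = increments
    if "composition" in df.columns:
        df = df[(df["composition"] == composition) & (df["regime"] == regime)]
    if df["group_id"].nunique() < 2 or len(df) < 12:
        raise ValueError(
            f"too little data for {composition}/{regime}: "
            f"{len(df)} increments in {df['group_id'].nunique()} sites")

    y = df["c_pool"].to_numpy(float)
    if np.any(y <= 0):
        raise ValueError("increment C pools must be positive for a gamma fit")
    dmid = df["depth_mid"].to_numpy(float)
    thick = df["thickness"].to_numpy(float) if "thickness" in df.columns \
        else np.full_like(y, NOMINAL_INCREMENT_CM)
    offset = np.log(thick / NOMINAL_INCREMENT_CM)

    classes_present = {depth_class(d) for d in dmid}
    reduced = len(classes_present) < 2
    if reduced:
        warnings.warn(
            f"only one depth class present for {composition}/{regime}; "
            "fitting reduced intercept+depth model", stacklevel=2)
    X = _design(dmid, reduced)
    k = X.shape[1]

    codes, _ = pd.factorize(df["group_id"])
    group_idx = np.asarray(codes, np.int64)
    n_groups = int(group_idx.max()) + 1
    args = (X, y, offset, group_idx, n_groups)

    # start values: log-scale least squares for beta, modest sd and shape
    beta0, *_ = np.linalg.lstsq(X, np.log(y) - offset, rcond=None)
    theta0 = np.concatenate([beta0, [np.log(0.3), np.log(2.0)]])

    res = optimize.minimize(
        _laplace_nll, theta0, args=args, method="L-BFGS-B", jac="3-point",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-13})
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success or grad_norm < 1e-3)
    if not converged and grad_norm > 1.0:
        raise ConvergenceError(
            f"depth model for {composition}/{regime} did not converge "
            f"(max |gradient| = {grad_norm:.3g})")

    theta = res.x
    names = ("intercept", "depth") if reduced else FIXED_EFFECT_NAMES
    coef = dict(zip(names, theta[:k]))
    if reduced:  # keep the full coefficient vocabulary, zeros elsewhere
        coef = {**{n: 0.0 for n in FIXED_EFFECT_NAMES}, **coef}

    se: dict[str, float] = {}
    try:
        H = approx_hess3(theta, _laplace_nll, args=args)
        cov = np.linalg.inv(0.5 * (H + H.T))
        dse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        se = dict(zip(names, dse[:k]))
        se["log_site_sd"] = float(dse[k])
        se["log_shape"] = float(dse[k + 1])
    except (np.linalg.LinAlgError, ValueError):
        pass

    return DepthCModel(
        composition=composition, regime=regime, coefficients=coef,
        site_intercept_sd=float(np.exp(theta[k])),
        gamma_shape=float(np.exp(theta[k + 1])), converged=converged,
        loglik=float(-res.fun), n_obs=len(y), n_groups=n_groups, se=se,
        reduced=reduced)


def depth_grid(from_depth: float, to_depth: float) -> list[tuple[float, float]]:
    """Split [from, to) into 5-cm increments plus a partial last increment."""
    edges = [from_depth]
    x = from_depth
    while x + NOMINAL_INCREMENT_CM < to_depth - 1e-12:
        x += NOMINAL_INCREMENT_CM
        edges.append(x)
    edges.append(to_depth)
    return list(zip(edges[:-1], edges[1:]))


def predict_cumulative_c(model: DepthCModel, from_depth: float,
                         to_depth: float) -> float:
    """Cumulative SOL C (g C m^-2) over [from_depth, to_depth).

    Sums population-level increment predictions at 5-cm-segment midpoints,
    the final partial segment scaled by thickness/5.  Returns 0 when the
    interval is empty; raises for an inverted interval.
    """
    if from_depth < 0:
        raise ValueError("depths must be non-negative")
    if to_depth < from_depth:
        raise ValueError("to_depth must be >= from_depth")
    if to_depth == from_depth:
        return 0.0
    total = 0.0
    for a, b in depth_grid(from_depth, to_depth):
        total += model.predict_increment(0.5 * (a + b), thickness=b - a)
    return total


def residual_sol_c(residual_depth_cm: float, model: DepthCModel) -> float:
    """Residual SOL C at one point, from the burned-site residual model."""
    if model.regime != SOLRegime.RESIDUAL_BURNED.value:
        raise ConfigError("residual_sol_c needs a residual_burned_sites model")
    return predict_cumulative_c(model, 0.0, residual_depth_cm)


def combusted_sol_c(burn_depth_cm: float, model: DepthCModel) -> float:
    """Combusted SOL C at one point: the top [0, burn depth) of the pre-fire
    profile, priced with the unburned-reference model."""
    if model.regime != SOLRegime.UNBURNED_REFERENCE.value:
        raise ConfigError("combusted_sol_c needs an unburned_reference model")
    return predict_cumulative_c(model, 0.0, burn_depth_cm)


def prefire_sol_c(residual_c: float, combusted_c: float) -> float:
    """Pre-fire SOL C = residual + combusted (both g C m^-2, >= 0)."""
    if residual_c < 0 or combusted_c < 0:
        raise ValueError("C pools must be non-negative")
    return residual_c + combusted_c


def measured_profile_c(increment_table: pd.DataFrame) -> pd.DataFrame:
    """Measured residual C per monolith: sum of its increment pools.

    Returns one row per residual-regime profile with ``plot_id``,
    ``point_id`` and ``measured_c``; used to override the modeled residual
    value at monolithed points.
    """
    res = increment_table[
        increment_table["regime"] == SOLRegime.RESIDUAL_BURNED.value]
    if res.empty:
        return pd.DataFrame(columns=["profile_id", "plot_id", "point_id",
                                     "measured_c"])
    return (res.groupby(["profile_id", "plot_id", "point_id"], dropna=False,
                        as_index=False)
            .agg(measured_c=("c_pool", "sum")))


def plot_soil_pools(point_burn: pd.DataFrame,
                    models_residual: dict[str, DepthCModel],
                    models_unburned: dict[str, DepthCModel],
                    plot_composition: pd.DataFrame,
                    measured: pd.DataFrame | None = None) -> pd.DataFrame:
    """Belowground C pools per plot (g C m^-2).

    For each point: residual C from the residual model over
    [0, residual depth) — replaced by the measured monolith sum where one
    exists — combusted C from the unburned-reference model over
    [0, burn depth), pre-fire C their sum; then the plot-level average.
    ``plot_composition`` maps plot_id -> composition class for model routing.
    """
    comp = plot_composition.set_index("plot_id")["composition"]
    measured_map: dict[str, float] = {}
    if measured is not None:
        for _, r in measured.iterrows():
            if pd.notna(r.get("point_id")):
                measured_map[str(r["point_id"])] = float(r["measured_c"])

    rows = []
    for _, pt in point_burn.iterrows():
        c = str(comp.loc[pt["plot_id"]])
        if c not in models_residual or c not in models_unburned:
            raise ConfigError(f"no fitted SOL model for composition '{c}'")
        resid_c = measured_map.get(str(pt["point_id"]))
        if resid_c is None:
            resid_c = residual_sol_c(float(pt["residual_sol_depth_cm"]),
                                     models_residual[c])
        comb_c = combusted_sol_c(float(pt["burn_depth_cm"]), models_unburned[c])
        rows.append({"point_id": pt["point_id"], "plot_id": pt["plot_id"],
                     "belowground_post_fire": resid_c,
                     "belowground_combusted": comb_c,
                     "belowground_pre_fire": prefire_sol_c(resid_c, comb_c)})
    pts = pd.DataFrame(rows)
    return (pts.groupby("plot_id", as_index=False)
            [["belowground_post_fire", "belowground_combusted",
              "belowground_pre_fire"]].mean())
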