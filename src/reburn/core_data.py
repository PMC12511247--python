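"""Domain types, CSV schemas, readers/writers and validation.

The data model mirrors the sampling hierarchy of a reburn field campaign:
fires contain sites, sites contain three 10 m x 2 m plots, and plots carry
point-level measurements (residual soil-organic-layer depth, thaw depth,
adventitious-root heights), stem/piece inventories with discrete combustion
classes, soil-organic-layer (SOL) depth-increment samples, and seedling
quadrats.

All tables travel as long-format pandas DataFrames keyed by string ids; the
:class:`Dataset` container groups them and :func:`load_dataset` /
:func:`write_dataset` round-trip them through plain CSV (UTF-8, header row,
``NA`` as the missing-value token).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, fields as dc_fields
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from reburn.errors import DatasetValidationError, ReferentialError, SchemaError

logger = logging.getLogger("reburn")
if not logger.handlers:  # stderr stage logging, configurable by the host app
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[reburn] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

NA_TOKEN = "NA"

#: Discrete combustion classes assessed in the field for trees and shrubs.
COMBUSTION_CLASSES = (0.0, 0.25, 0.50, 0.75, 1.0)

#: Biomass components scored for combustion on each tree.
TREE_COMPONENTS = ("stem", "coarse_branches", "fine_branches", "foliage",
                   "cones", "bark")
#: Biomass components scored on each tall shrub.
SHRUB_COMPONENTS = ("stem", "branches", "foliage")

#: Dry biomass is assumed to be 50% carbon for all aboveground pools.
CARBON_FRACTION = 0.5


class FRIClass(str, Enum):
    """Fire-return-interval class of a site.

    ``long`` > 70 y between fires, ``mid`` 30-70 y, ``short`` < 30 y;
    ``triple_mid`` / ``triple_short`` are sites burned three times in
    < 70 years with the most recent interval in the mid / short band.
    """

    LONG = "long"
    MID = "mid"
    SHORT = "short"
    TRIPLE_MID = "triple_mid"
    TRIPLE_SHORT = "triple_short"


class CompositionClass(str, Enum):
    """Pre-fire (or post-fire seedling) tree species dominance class."""

    SPRUCE = "spruce"
    MIXED = "mixed"
    DECIDUOUS = "deciduous"
    OPEN = "open"


class SOLRegime(str, Enum):
    """Provenance of an SOL profile for the depth-wise carbon models."""

    RESIDUAL_BURNED = "residual_burned_sites"
    UNBURNED_REFERENCE = "unburned_reference"


def fri_band(interval_years: float) -> FRIClass:
    """Map a single fire-free interval (years) onto long/mid/short bands."""
    if interval_years > 70:
        return FRIClass.LONG
    if interval_years >= 30:
        return FRIClass.MID
    return FRIClass.SHORT


# --------------------------------------------------------------------------
# CSV schemas
# --------------------------------------------------------------------------

#: table name -> ordered mapping column -> pandas dtype ("str", "float", "int")
SCHEMAS: dict[str, dict[str, str]] = {
    "fires": {
        "fire_id": "str",
        "burn_year": "int",
        "prior_burn_years": "str",  # semicolon-joined years, may be NA
    },
    "sites": {
        "site_id": "str",
        "fire_id": "str",
        "fri_class_history": "str",
        "fri_class_final": "str",
        "stand_age_at_fire": "float",
        "years_since_fire_at_sampling": "float",
        "drainage_class": "int",
        "permafrost_detected": "int",
        "elevation": "float",
        "slope": "float",
        "aspect": "float",
    },
    "plots": {
        "plot_id": "str",
        "site_id": "str",
        "belt_area_m2": "float",
        "shrub_subplot_area_m2": "float",
        "transect_length_m": "float",
    },
    "trees": {
        "tree_id": "str",
        "plot_id": "str",
        "species": "str",
        "pre_fire_status": "str",  # live | snag
        "diameter_cm": "float",
        "comb_stem": "float",
        "comb_coarse_branches": "float",
        "comb_fine_branches": "float",
        "comb_foliage": "float",
        "comb_cones": "float",
        "comb_bark": "float",
    },
    "shrubs": {
        "shrub_id": "str",
        "plot_id": "str",
        "species": "str",
        "basal_diameter_cm": "float",
        "comb_stem": "float",
        "comb_branches": "float",
        "comb_foliage": "float",
    },
    "cwd": {
        "piece_id": "str",
        "plot_id": "str",
        "species": "str",  # may be NA (unidentifiable)
        "diameter_cm": "float",
        "decay_class": "str",  # hard | crumbly | soft
        "combustion_fraction": "float",
    },
    "points": {
        "point_id": "str",
        "plot_id": "str",
        "residual_sol_depth_cm": "float",
        "thaw_depth_cm": "float",  # NA when frozen ground not reached
        "frozen_not_reached": "int",
        "arh1_cm": "float",
        "arh2_cm": "float",
        "arh3_cm": "float",
    },
    "sol_increments": {
        "profile_id": "str",
        "group_id": "str",   # site-level grouping key for the mixed model
        "plot_id": "str",    # NA for unburned reference profiles
        "point_id": "str",   # measurement point the monolith was taken at (or NA)
        "composition": "str",
        "regime": "str",
        "top_depth_cm": "float",
        "bottom_depth_cm": "float",
        "fine_dry_mass_g": "float",
        "sample_length_cm": "float",
        "sample_width_cm": "float",
        "rock_volume_cm3": "float",
        "c_fraction": "float",
    },
    "quadrats": {
        "quadrat_id": "str",
        "plot_id": "str",
        "area_m2": "float",
        "species": "str",
        "count": "int",
        "bd1_cm": "float",
        "bd2_cm": "float",
        "bd3_cm": "float",
        "search_quadrat": "int",
    },
}

DECAY_CLASSES = ("hard", "crumbly", "soft")


@dataclass
class Dataset:
    """In-memory field campaign: one DataFrame per CSV schema."""

    fires: pd.DataFrame
    sites: pd.DataFrame
    plots: pd.DataFrame
    trees: pd.DataFrame
    shrubs: pd.DataFrame
    cwd: pd.DataFrame
    points: pd.DataFrame
    sol_increments: pd.DataFrame
    quadrats: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    def counts(self) -> dict[str, int]:
        return {name: len(df) for name, df in self.tables().items()}

    def __eq__(self, other: object) -> bool:  # value equality for round-trips
        if not isinstance(other, Dataset):
            return NotImplemented
        for name, df in self.tables().items():
            odf = other.tables()[name]
            try:
                pd.testing.assert_frame_equal(
                    df.reset_index(drop=True), odf.reset_index(drop=True),
                    check_dtype=False)
            except AssertionError:
                return False
        return True


@dataclass
class ValidationReport:
    """All violations found in a dataset; empty means valid."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, msg: str) -> None:
        self.violations.append(msg)


def empty_table(name: str) -> pd.DataFrame:
    cols = SCHEMAS[name]
    return pd.DataFrame({c: pd.Series(dtype="float64" if t == "float" else "object")
                         for c, t in cols.items()})


def _coerce(df: pd.DataFrame, name: str) -> pd.DataFrame:
    out = df.copy()
    for col, typ in SCHEMAS[name].items():
        if typ == "float":
            out[col] = pd.to_numeric(out[col], errors="coerce")
        elif typ == "int":
            out[col] = pd.to_numeric(out[col], errors="coerce").astype("Int64")
        else:
            out[col] = out[col].astype("object")
            out.loc[out[col].notna(), col] = out.loc[out[col].notna(), col].astype(str)
    return out[list(SCHEMAS[name])]


def _read_csv(path: Path, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype="object", na_values=[NA_TOKEN],
                     keep_default_na=False, encoding="utf-8")
    missing = set(SCHEMAS[name]) - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path.name}: missing column(s) {sorted(missing)}")
    return _coerce(df, name)


def load_dataset(directory: str | Path, strict: bool = True) -> Dataset:
    """Read all campaign CSVs from *directory*, validate and link them.

    Raises :class:`SchemaError` for malformed files and, when *strict*,
    :class:`DatasetValidationError` carrying the full violation report.
    Absent optional tables load as empty.
    """
    directory = Path(directory)
    frames = {}
    for name in SCHEMAS:
        path = directory / f"{name}.csv"
        if path.exists():
            frames[name] = _read_csv(path, name)
        else:
            frames[name] = empty_table(name)
    ds = Dataset(**frames)
    report = validate(ds)
    for name, n in ds.counts().items():
        logger.info("loaded %-16s %6d records", name, n)
    if strict and not report.ok:
        raise DatasetValidationError(report)
    return ds


def write_dataset(ds: Dataset, directory: str | Path) -> None:
    """Write every table of *ds* as CSV under *directory* (NA token ``NA``)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in ds.tables().items():
        df.to_csv(directory / f"{name}.csv", index=False, na_rep=NA_TOKEN,
                  encoding="utf-8")


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

def _check_fk(report: ValidationReport, child: pd.DataFrame, col: str,
              parent_ids: set, table: str) -> None:
    vals = child[col].dropna()
    orphans = sorted(set(vals) - parent_ids)
    for o in orphans[:10]:
        report.add(f"{table}: orphan {col} '{o}' does not resolve")
    if len(orphans) > 10:
        report.add(f"{table}: ... {len(orphans) - 10} more orphan {col}")


def validate(ds: Dataset) -> ValidationReport:
    """Check referential integrity and all field-level invariants."""
    rep = ValidationReport()
    fire_ids = set(ds.fires["fire_id"].dropna())
    site_ids = set(ds.sites["site_id"].dropna())
    plot_ids = set(ds.plots["plot_id"].dropna())

    _check_fk(rep, ds.sites, "fire_id", fire_ids, "sites")
    _check_fk(rep, ds.plots, "site_id", site_ids, "plots")
    for tname in ("trees", "shrubs", "cwd", "points", "quadrats"):
        _check_fk(rep, getattr(ds, tname), "plot_id", plot_ids, tname)
    burned = ds.sol_increments[
        ds.sol_increments["regime"] == SOLRegime.RESIDUAL_BURNED.value]
    _check_fk(rep, burned, "plot_id", plot_ids, "sol_increments")

    # fires: prior burn years strictly increasing and < burn_year
    for _, row in ds.fires.iterrows():
        prior = parse_year_list(row["prior_burn_years"])
        if prior and (sorted(prior) != prior or len(set(prior)) != len(prior)):
            rep.add(f"fires: {row['fire_id']} prior_burn_years not strictly "
                    "increasing")
        if prior and row["burn_year"] is not pd.NA and prior[-1] >= row["burn_year"]:
            rep.add(f"fires: {row['fire_id']} prior burn not before burn_year")

    fri_values = {c.value for c in FRIClass}
    bad = ds.sites[~ds.sites["fri_class_final"].isin(fri_values)]
    for sid in bad["site_id"]:
        rep.add(f"sites: {sid} fri_class_final not one of {sorted(fri_values)}")
    bad = ds.sites[(ds.sites["drainage_class"] < 1) | (ds.sites["drainage_class"] > 6)]
    for sid in bad["site_id"]:
        rep.add(f"sites: {sid} drainage_class outside 1..6")
    bad = ds.sites[ds.sites["stand_age_at_fire"] <= 0]
    for sid in bad["site_id"]:
        rep.add(f"sites: {sid} stand_age_at_fire must be > 0")

    # trees/shrubs: positive diameters, discrete combustion classes
    for tname, comps, dcol in (("trees", TREE_COMPONENTS, "diameter_cm"),
                               ("shrubs", SHRUB_COMPONENTS, "basal_diameter_cm")):
        df = getattr(ds, tname)
        for rid in df.loc[df[dcol] <= 0, f"{tname[:-1]}_id"]:
            rep.add(f"{tname}: {rid} non-positive diameter")
        for comp in comps:
            col = f"comb_{comp}"
            vals = df[col].dropna()
            bad_mask = ~vals.round(6).isin([round(c, 6) for c in COMBUSTION_CLASSES])
            for rid in df.loc[vals[bad_mask].index, f"{tname[:-1]}_id"]:
                rep.add(f"{tname}: {rid} combustion {col} not in "
                        f"{{0, 0.25, 0.5, 0.75, 1.0}}")

    bad = ds.trees[~ds.trees["pre_fire_status"].isin(["live", "snag"])]
    for rid in bad["tree_id"]:
        rep.add(f"trees: {rid} pre_fire_status must be live or snag")

    # CWD: diameter > 2 cm, known decay class, combustion in [0,1]
    for rid in ds.cwd.loc[ds.cwd["diameter_cm"] <= 2, "piece_id"]:
        rep.add(f"cwd: {rid} diameter must exceed 2 cm")
    bad = ds.cwd[~ds.cwd["decay_class"].isin(DECAY_CLASSES)]
    for rid in bad["piece_id"]:
        rep.add(f"cwd: {rid} unknown decay class")
    bad = ds.cwd[(ds.cwd["combustion_fraction"] < 0) |
                 (ds.cwd["combustion_fraction"] > 1)]
    for rid in bad["piece_id"]:
        rep.add(f"cwd: {rid} combustion_fraction outside [0, 1]")

    # points: non-negative depths and ARH
    for rid in ds.points.loc[ds.points["residual_sol_depth_cm"] < 0, "point_id"]:
        rep.add(f"points: {rid} residual_sol_depth_cm < 0")
    for col in ("arh1_cm", "arh2_cm", "arh3_cm"):
        for rid in ds.points.loc[ds.points[col] < 0, "point_id"]:
            rep.add(f"points: {rid} negative adventitious-root height ({col})")

    # SOL increments: contiguous from 0, bottom > top, sane geometry
    inc = ds.sol_increments
    for rid in inc.loc[inc["bottom_depth_cm"] <= inc["top_depth_cm"], "profile_id"]:
        rep.add(f"sol_increments: {rid} bottom_depth <= top_depth")
    regimes = {r.value for r in SOLRegime}
    for rid in inc.loc[~inc["regime"].isin(regimes), "profile_id"].unique():
        rep.add(f"sol_increments: {rid} unknown regime")
    for pid, grp in inc.groupby("profile_id"):
        grp = grp.sort_values("top_depth_cm")
        tops = grp["top_depth_cm"].to_numpy(float)
        bottoms = grp["bottom_depth_cm"].to_numpy(float)
        if len(tops) and abs(tops[0]) > 1e-9:
            rep.add(f"sol_increments: profile {pid} does not start at depth 0")
        if len(tops) > 1 and not np.allclose(tops[1:], bottoms[:-1], atol=1e-9):
            rep.add(f"sol_increments: profile {pid} increments not contiguous")

    # quadrats
    for rid in ds.quadrats.loc[ds.quadrats["area_m2"] <= 0, "quadrat_id"]:
        rep.add(f"quadrats: {rid} non-positive area")
    for rid in ds.quadrats.loc[ds.quadrats["count"] < 0, "quadrat_id"]:
        rep.add(f"quadrats: {rid} negative seedling count")

    return rep


def parse_year_list(token) -> list[int]:
    """Parse a semicolon-joined year list ('1950;1985'); NA/empty -> []."""
    if token is None or (isinstance(token, float) and np.isnan(token)) or token is pd.NA:
        return []
    s = str(token).strip()
    if not s or s == NA_TOKEN:
        return []
    return [int(x) for x in s.split(";")]


def format_year_list(years: Iterable[int]) -> str | None:
    years = list(years)
    return ";".join(str(y) for y in years) if years else None


# --------------------------------------------------------------------------
# Tree-ring corroboration of fire-history FRI classes
# --------------------------------------------------------------------------

def reclassify_fri(
    history_class: FRIClass | str,
    tree_ring_age: float,
    history_interval: float | None,
    *,
    abs_tolerance: float = 5.0,
    rel_tolerance: float = 0.10,
) -> FRIClass:
    """Resolve a site's final FRI class from fire history and tree rings.

    Stand age from tree-ring counts corroborates the fire-history interval
    when ``|rings - interval| <= max(abs_tolerance, rel_tolerance*interval)``;
    a corroborated history class is kept (including triple status).  Otherwise
    the tree-ring age is trusted (unburned patches make fire history
    unreliable) and the site is assigned the plain band class implied by the
    ring count: > 70 y long, 30-70 y mid, < 30 y short.  Sites with no
    recorded prior fire (``history_interval`` None) are corroborated only if
    the rings also imply a long interval.
    """
    history_class = FRIClass(history_class)
    if tree_ring_age <= 0:
        raise ValueError("tree_ring_age must be positive")
    if history_interval is None:
        corroborated = fri_band(tree_ring_age) == FRIClass.LONG
    else:
        tol = max(abs_tolerance, rel_tolerance * history_interval)
        corroborated = abs(tree_ring_age - history_interval) <= tol
    if corroborated:
        return history_class
    return fri_band(tree_ring_age)
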