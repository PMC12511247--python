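"""Allometry, combustion arithmetic, CWD line intercept, DI classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reburn.core_data import CompositionClass
from reburn.errors import AllometryLookupError
from reburn.vegetation import (
    AllometricTable,
    classify_composition,
    cwd_pools,
    deciduous_index,
    plot_aboveground_pools,
    plot_structure,
    stem_biomass,
    stem_combusted,
    tree_pools,
)


@pytest.fixture(scope="module")
def toy_table():
    return AllometricTable(
        trees={"sp": {"stem": (0.1, 2.0), "foliage": (0.02, 1.5)},
               "dec": {"stem": (0.1, 2.0), "foliage": (0.02, 1.5)}},
        shrubs={"willow": {"stem": (0.05, 2.0), "branches": (0.01, 2.0),
                           "foliage": (0.005, 1.5)}},
        seedlings={"sp": (0.03, 2.0)},
        cwd_density={"hard": 0.4, "crumbly": 0.3, "soft": 0.2},
        deciduous_species={"dec"},
    )


class TestStemBiomass:
    def test_power_law(self, toy_table):
        bm = stem_biomass("sp", 10.0, AllometricTable(
            trees={"sp": {"stem": (0.1, 2.0)}}, shrubs={}, seedlings={},
            cwd_density={"hard": 0.4}))
        assert bm == {"stem": pytest.approx(10.0)}

    def test_vanishes_with_diameter(self, toy_table):
        bm = stem_biomass("sp", 1e-6, toy_table)
        assert sum(bm.values()) < 1e-9

    def test_components_sum(self, toy_table):
        bm = stem_biomass("sp", 7.3, toy_table)
        expected = 0.1 * 7.3 ** 2 + 0.02 * 7.3 ** 1.5
        assert sum(bm.values()) == pytest.approx(expected)

    def test_unknown_species_without_fallback(self, toy_table):
        with pytest.raises(AllometryLookupError, match="mystery"):
            stem_biomass("mystery", 5.0, toy_table)

    def test_nonpositive_diameter(self, toy_table):
        with pytest.raises(ValueError):
            stem_biomass("sp", 0.0, toy_table)


class TestStemCombusted:
    def test_no_combustion(self):
        assert stem_combusted({"stem": 5.0, "foliage": 1.0},
                              {"stem": 0.0, "foliage": 0.0}) == 0.0

    def test_total_combustion(self):
        bm = {"stem": 5.0, "foliage": 1.0}
        assert stem_combusted(bm, {"stem": 1.0, "foliage": 1.0}) == \
            pytest.approx(6.0)

    def test_weighted_sum(self):
        bm = {"stem": 8.0, "foliage": 2.0}
        got = stem_combusted(bm, {"stem": 0.25, "foliage": 1.0})
        assert got == pytest.approx(8.0 * 0.25 + 2.0 * 1.0)

    def test_missing_component_burns_nothing(self):
        assert stem_combusted({"stem": 5.0}, {}) == 0.0


class TestCWD:
    def test_empty(self, toy_table):
        pools = cwd_pools(pd.DataFrame(columns=["diameter_cm", "decay_class",
                                                "combustion_fraction"]),
                          10.0, toy_table)
        assert pools == {"pre_fire": 0.0, "combusted": 0.0, "post_fire": 0.0}

    def test_hand_unit_conversion(self, toy_table):
        """One 10-cm hard piece on a 10-m transect, no combustion."""
        df = pd.DataFrame([{"diameter_cm": 10.0, "decay_class": "hard",
                            "combustion_fraction": 0.0}])
        pools = cwd_pools(df, 10.0, toy_table)
        vol_m3_m2 = math.pi ** 2 * 100.0 * 1e-4 / 80.0
        assert pools["pre_fire"] == pytest.approx(vol_m3_m2 * 400.0)
        assert pools["combusted"] == 0.0

    def test_full_combustion_empties_pool(self, toy_table):
        df = pd.DataFrame([
            {"diameter_cm": 5.0, "decay_class": "soft",
             "combustion_fraction": 1.0},
            {"diameter_cm": 8.0, "decay_class": "hard",
             "combustion_fraction": 1.0}])
        pools = cwd_pools(df, 10.0, toy_table)
        assert pools["post_fire"] == pytest.approx(0.0, abs=1e-12)

    def test_unknown_decay_class(self, toy_table):
        df = pd.DataFrame([{"diameter_cm": 5.0, "decay_class": "mushy",
                            "combustion_fraction": 0.0}])
        with pytest.raises(ValueError, match="mushy"):
            cwd_pools(df, 10.0, toy_table)


def _tree(plot, species, d, status="live", **comb):
    row = {"tree_id": f"t{d}", "plot_id": plot, "species": species,
           "pre_fire_status": status, "diameter_cm": d}
    for c in ("stem", "coarse_branches", "fine_branches", "foliage", "cones",
              "bark"):
        row[f"comb_{c}"] = comb.get(c, 0.0)
    return row


class TestPlotStructure:
    def test_density(self, toy_table):
        trees = pd.DataFrame([_tree("p", "sp", 5.0) for _ in range(20)])
        out = plot_structure(trees, 20.0, toy_table)
        assert out.loc[0, "density"] == pytest.approx(1.0)

    def test_empty_plot(self, toy_table):
        out = plot_structure(pd.DataFrame(columns=["species", "diameter_cm",
                                                   "tree_id", "plot_id",
                                                   "pre_fire_status"]),
                             20.0, toy_table)
        assert out.empty

    def test_per_species_hand_sums(self, toy_table):
        trees = pd.DataFrame([_tree("p", "sp", 4.0), _tree("p", "sp", 6.0),
                              _tree("p", "dec", 10.0)])
        out = plot_structure(trees, 20.0, toy_table).set_index("species")
        assert out.loc["sp", "density"] == pytest.approx(2 / 20.0)
        ba_sp = (math.pi * 4.0 ** 2 / 4 + math.pi * 6.0 ** 2 / 4) / 20.0
        assert out.loc["sp", "basal_area"] == pytest.approx(ba_sp)
        bm_dec = (0.1 * 100.0 + 0.02 * 10.0 ** 1.5) / 20.0
        assert out.loc["dec", "biomass"] == pytest.approx(bm_dec)


class TestComposition:
    @pytest.mark.parametrize("di, expected", [
        (0.0, CompositionClass.SPRUCE),
        (33.33, CompositionClass.SPRUCE),
        (33.34, CompositionClass.MIXED),
        (50.0, CompositionClass.MIXED),
        (66.65, CompositionClass.MIXED),
        (66.66, CompositionClass.DECIDUOUS),
        (100.0, CompositionClass.DECIDUOUS),
    ])
    def test_thresholds(self, di, expected):
        assert classify_composition(di, any_trees=True) is expected

    def test_treeless_is_open(self):
        assert classify_composition(0.0, any_trees=False) is \
            CompositionClass.OPEN
        assert classify_composition(90.0, any_trees=False) is \
            CompositionClass.OPEN

    @given(di=st.floats(0.0, 100.0), any_trees=st.booleans())
    @settings(max_examples=200, deadline=None)
    def test_partition_is_total(self, di, any_trees):
        """Every (DI, tree-presence) input maps to exactly one class."""
        assert classify_composition(di, any_trees) in CompositionClass

    def test_deciduous_index_hand_value(self, toy_table):
        # 1 of 2 live stems deciduous; biomass share from the power law
        trees = pd.DataFrame([_tree("p", "sp", 10.0), _tree("p", "dec", 10.0)])
        di = deciduous_index(trees, toy_table)
        assert di == pytest.approx((0.5 + 0.5) / 2 * 100)

    def test_deciduous_index_ignores_snags(self, toy_table):
        trees = pd.DataFrame([_tree("p", "sp", 10.0),
                              _tree("p", "dec", 10.0, status="snag")])
        assert deciduous_index(trees, toy_table) == pytest.approx(0.0)


class TestAbovegroundPools:
    PLOT = pd.Series({"belt_area_m2": 20.0, "shrub_subplot_area_m2": 10.0,
                      "transect_length_m": 10.0})

    def test_conservation_and_carbon_fraction(self, toy_table):
        trees = pd.DataFrame([_tree("p", "sp", 8.0, stem=0.25, foliage=1.0),
                              _tree("p", "dec", 5.0, status="snag", stem=0.5)])
        shrubs = pd.DataFrame([{
            "shrub_id": "s1", "plot_id": "p", "species": "willow",
            "basal_diameter_cm": 2.0, "comb_stem": 0.75, "comb_branches": 1.0,
            "comb_foliage": 1.0}])
        cwd = pd.DataFrame([{"piece_id": "w1", "plot_id": "p",
                             "species": None, "diameter_cm": 6.0,
                             "decay_class": "crumbly",
                             "combustion_fraction": 0.4}])
        out = plot_aboveground_pools(trees, shrubs, cwd, self.PLOT, toy_table)
        for comp in ("trees", "snags", "shrubs", "cwd", "aboveground"):
            assert out[f"{comp}_pre_fire"] == pytest.approx(
                out[f"{comp}_post_fire"] + out[f"{comp}_combusted"])
        # carbon is half of dry biomass: check the tree pool directly
        tp = tree_pools(trees, toy_table)
        live_kg = tp.loc[tp["pre_fire_status"] == "live", "pre_fire_kg"].sum()
        assert out["trees_pre_fire"] == pytest.approx(
            live_kg / 20.0 * 0.5 * 1000.0)

    def test_snags_are_a_separate_pool(self, toy_table):
        trees = pd.DataFrame([_tree("p", "sp", 8.0, status="snag")])
        out = plot_aboveground_pools(
            trees, pd.DataFrame(columns=["species", "basal_diameter_cm"]),
            pd.DataFrame(columns=["diameter_cm", "decay_class",
                                  "combustion_fraction"]),
            self.PLOT, toy_table)
        assert out["trees_pre_fire"] == 0.0
        assert out["snags_pre_fire"] > 0.0


def test_campaign_aboveground_conservation(small_campaign, allometry):
    """Pre-fire = post-fire + combusted for every plot of a campaign."""
    ds, _ = small_campaign
    plot = ds.plots.iloc[0]
    for pid in ds.plots["plot_id"].head(10):
        out = plot_aboveground_pools(
            ds.trees[ds.trees["plot_id"] == pid],
            ds.shrubs[ds.shrubs["plot_id"] == pid],
            ds.cwd[ds.cwd["plot_id"] == pid], plot, allometry)
        assert out["aboveground_pre_fire"] == pytest.approx(
            out["aboveground_post_fire"] + out["aboveground_combusted"])
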