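"""FRI-class means and the legacy-carbon accounting identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reburn.errors import AccountingError
from reburn.legacy import (
    class_mean_pools,
    legacy_rows,
    legacy_table,
    proportional_loss,
    reference_pool,
)


def _plot_pools(rows):
    return pd.DataFrame(rows, columns=["plot_id", "site_id", "fri_class",
                                       "belowground_pre_fire"])


class TestClassMeans:
    def test_single_plot_is_class_mean(self):
        df = _plot_pools([("p1", "s1", "long", 4.0)])
        out = class_mean_pools(df, ["belowground_pre_fire"])
        assert out.loc[0, "belowground_pre_fire"] == pytest.approx(4.0)

    def test_two_sites_average(self):
        df = _plot_pools([("p1", "s1", "long", 4.0), ("p2", "s2", "long", 6.0)])
        out = class_mean_pools(df, ["belowground_pre_fire"])
        assert out.loc[0, "belowground_pre_fire"] == pytest.approx(5.0)

    def test_sites_before_classes(self):
        """Unbalanced plots: plots average within sites, then sites within
        the class (hand-computed: (mean(2,4), 9) -> 6)."""
        df = _plot_pools([("p1", "s1", "mid", 2.0), ("p2", "s1", "mid", 4.0),
                          ("p3", "s2", "mid", 9.0)])
        out = class_mean_pools(df, ["belowground_pre_fire"])
        assert out.loc[0, "belowground_pre_fire"] == pytest.approx(6.0)
        assert out.loc[0, "n_sites"] == 2

    def test_empty_class_warns_and_drops(self):
        df = _plot_pools([("p1", "s1", "long", 4.0)])
        with pytest.warns(UserWarning, match="no plots"):
            out = class_mean_pools(df, ["belowground_pre_fire"])
        assert list(out["fri_class"]) == ["long"]


CLASS_POST = pd.DataFrame([
    {"fri_class": "long", "belowground_post_fire": 5083.0},
    {"fri_class": "mid", "belowground_post_fire": 3350.0}])


class TestReferencePool:
    @pytest.mark.parametrize("cls, expected", [
        ("short", 5083.0), ("mid", 5083.0), ("long", 5083.0),
        ("triple_mid", 3350.0), ("triple_short", 3350.0)])
    def test_mapping(self, cls, expected):
        assert reference_pool(cls, "belowground", CLASS_POST) == expected

    def test_missing_reference_class(self):
        with pytest.raises(AccountingError, match="mid"):
            reference_pool("triple_mid", "belowground", CLASS_POST.iloc[:1])


class TestAccountingRows:
    @pytest.mark.parametrize(
        "pre, ref, loss, acc, legacy, pct", [
            # hand-checked against the published class-level accounting
            (6039.0, 5083.0, 2689.0, 956.0, 1733.0, 64.45),   # mid below
            (6440.0, 6584.0, 3177.0, -144.0, 3321.0, 104.53),  # short total
            (6260.0, 3350.0, 2149.0, 2910.0, -761.0, -35.41),  # t-mid below
        ])
    def test_hand_examples(self, pre, ref, loss, acc, legacy, pct):
        rows = pd.DataFrame([{
            "fri_class": "x", "component": "belowground",
            "prefire_pool": pre, "postfire_reference_pool": ref,
            "loss": loss, "interval_years": 45.0}])
        out = legacy_rows(rows).iloc[0]
        assert out["accumulation"] == pytest.approx(acc)
        assert out["legacy_loss"] == pytest.approx(legacy)
        assert round(out["pct_legacy"], 2) == pct

    def test_long_self_reference_zeroes_legacy(self):
        rows = pd.DataFrame([{
            "fri_class": "long", "component": "belowground",
            "prefire_pool": 8240.0, "postfire_reference_pool": 5083.0,
            "loss": 3157.0, "interval_years": 102.0}])
        out = legacy_rows(rows).iloc[0]
        assert out["legacy_loss"] == pytest.approx(0.0)
        assert out["pct_legacy"] == pytest.approx(0.0)

    def test_zero_loss_gives_na(self):
        rows = pd.DataFrame([{
            "fri_class": "x", "component": "total", "prefire_pool": 5.0,
            "postfire_reference_pool": 5.0, "loss": 0.0,
            "interval_years": 10.0}])
        with pytest.warns(UserWarning, match="zero C loss"):
            out = legacy_rows(rows).iloc[0]
        assert np.isnan(out["pct_legacy"])

    @given(pre=st.floats(0, 1e4), ref=st.floats(0, 1e4),
           loss=st.floats(1.0, 1e4))
    @settings(max_examples=200, deadline=None)
    def test_accounting_identities(self, pre, ref, loss):
        """A + G = L exactly, and pct > 100 iff the interval accumulated a
        net pool decline (A < 0)."""
        rows = pd.DataFrame([{
            "fri_class": "x", "component": "total", "prefire_pool": pre,
            "postfire_reference_pool": ref, "loss": loss,
            "interval_years": 10.0}])
        out = legacy_rows(rows).iloc[0]
        assert out["accumulation"] + out["legacy_loss"] == pytest.approx(
            loss, rel=1e-12, abs=1e-9)
        if abs(out["accumulation"]) > 1e-6 * max(1.0, loss):
            assert (out["pct_legacy"] > 100.0) == (out["accumulation"] < 0.0)


class TestLegacyTable:
    def test_totals_sum_components(self):
        pools = pd.DataFrame([
            {"fri_class": "long", "belowground_pre_fire": 8000.0,
             "belowground_post_fire": 5000.0, "belowground_combusted": 3000.0,
             "aboveground_pre_fire": 2000.0, "aboveground_post_fire": 1500.0,
             "aboveground_combusted": 500.0},
            {"fri_class": "mid", "belowground_pre_fire": 6000.0,
             "belowground_post_fire": 3400.0, "belowground_combusted": 2600.0,
             "aboveground_pre_fire": 1900.0, "aboveground_post_fire": 1400.0,
             "aboveground_combusted": 500.0}])
        out = legacy_table(pools)
        tot = out[(out["fri_class"] == "mid") & (out["component"] == "total")]
        below = out[(out["fri_class"] == "mid") &
                    (out["component"] == "belowground")]
        above = out[(out["fri_class"] == "mid") &
                    (out["component"] == "aboveground")]
        for col in ("prefire_pool", "postfire_reference_pool", "loss",
                    "accumulation", "legacy_loss"):
            assert tot.iloc[0][col] == pytest.approx(
                below.iloc[0][col] + above.iloc[0][col])

    def test_mid_references_long_postfire(self):
        pools = pd.DataFrame([
            {"fri_class": "long", "belowground_pre_fire": 8240.0,
             "belowground_post_fire": 5083.0, "belowground_combusted": 3157.0,
             "aboveground_pre_fire": 1919.0, "aboveground_post_fire": 1501.0,
             "aboveground_combusted": 418.0},
            {"fri_class": "mid", "belowground_pre_fire": 6039.0,
             "belowground_post_fire": 3350.0, "belowground_combusted": 2689.0,
             "aboveground_pre_fire": 1931.0, "aboveground_post_fire": 1377.0,
             "aboveground_combusted": 554.0}])
        out = legacy_table(pools, tau={"long": 102.0, "mid": 45.0})
        row = out[(out["fri_class"] == "mid") &
                  (out["component"] == "belowground")].iloc[0]
        assert row["postfire_reference_pool"] == pytest.approx(5083.0)
        assert row["legacy_loss"] == pytest.approx(1733.0)
        assert row["annual_rate"] == pytest.approx(956.0 / 45.0)


class TestProportionalLoss:
    def test_published_magnitude(self):
        pools = pd.DataFrame([{"fri_class": "long",
                               "total_pre_fire": 10159.0,
                               "total_combusted": 3575.0}])
        out = proportional_loss(pools)
        assert out.loc[0, "pct_of_prefire_lost"] == pytest.approx(35.19,
                                                                  abs=0.01)

    @pytest.mark.parametrize("loss, expected", [(0.0, 0.0), (100.0, 100.0)])
    def test_limits(self, loss, expected):
        pools = pd.DataFrame([{"fri_class": "x", "total_pre_fire": 100.0,
                               "total_combusted": loss}])
        assert proportional_loss(pools).loc[0, "pct_of_prefire_lost"] == \
            pytest.approx(expected)
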