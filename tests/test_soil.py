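"""Increment pools, the depth-wise gamma mixed model, and SOL C prediction."""

import subprocess
import textwrap
import warnings

import numpy as np
import pandas as pd
import pytest

from reburn.core_data import SOLRegime
from reburn.errors import ConfigError
from reburn.soil import (
    DepthCModel,
    combusted_sol_c,
    depth_class,
    fit_depth_model,
    increment_c_pool,
    measured_profile_c,
    plot_soil_pools,
    predict_cumulative_c,
    prefire_sol_c,
    residual_sol_c,
)
from reburn.synthetic import SimConfig, simulate_sol_profile


class TestIncrementPool:
    def test_forced_arithmetic(self):
        # 5 cm at bulk density 0.05 g/cm3 and 40% C -> 1000 g C m^-2
        out = increment_c_pool(0.0, 5.0, fine_dry_mass_g=25.0,
                               sample_length_cm=10.0, sample_width_cm=10.0,
                               rock_volume_cm3=0.0, c_fraction=0.40)
        assert out["bulk_density"] == pytest.approx(0.05)
        assert out["c_pool"] == pytest.approx(1000.0)

    def test_zero_mass(self):
        out = increment_c_pool(0.0, 5.0, 0.0, 10.0, 10.0, 0.0, 0.4)
        assert out["c_pool"] == 0.0

    def test_rock_volume_oracle(self):
        """Net volume subtracts rocks; hand-computed bulk density."""
        out = increment_c_pool(5.0, 10.0, fine_dry_mass_g=30.0,
                               sample_length_cm=10.0, sample_width_cm=10.0,
                               rock_volume_cm3=100.0, c_fraction=0.5)
        bd = 30.0 / (10 * 10 * 5 - 100)
        assert out["bulk_density"] == pytest.approx(bd)
        assert out["c_pool"] == pytest.approx(5 * bd * 0.5 * 1e4)

    def test_rocks_exceeding_volume(self):
        with pytest.raises(ValueError, match="rock"):
            increment_c_pool(0.0, 5.0, 10.0, 10.0, 10.0, 500.0, 0.4)

    @pytest.mark.parametrize("mid, expected", [
        (5.0, "d0_10"), (9.99, "d0_10"), (10.0, "d10_20"), (19.9, "d10_20"),
        (20.0, "d20plus"), (35.0, "d20plus")])
    def test_depth_class_ties_go_deeper(self, mid, expected):
        assert depth_class(mid) == expected


def _constant_model(log_pool, regime="residual_burned_sites"):
    return DepthCModel(
        composition="spruce", regime=regime,
        coefficients={"intercept": log_pool, "depth": 0.0, "d10_20": 0.0,
                      "d20plus": 0.0, "depth:d10_20": 0.0,
                      "depth:d20plus": 0.0},
        site_intercept_sd=0.0, gamma_shape=2.0, converged=True, loglik=0.0,
        n_obs=0, n_groups=0)


def _sloped_model(regime="unburned_reference"):
    return DepthCModel(
        composition="spruce", regime=regime,
        coefficients={"intercept": 6.9, "depth": 0.03, "d10_20": 0.2,
                      "d20plus": 0.3, "depth:d10_20": -0.01,
                      "depth:d20plus": 0.005},
        site_intercept_sd=0.3, gamma_shape=2.0, converged=True, loglik=0.0,
        n_obs=0, n_groups=0)


class TestPrediction:
    def test_empty_interval(self):
        assert predict_cumulative_c(_constant_model(7.0), 4.0, 4.0) == 0.0

    def test_inverted_interval(self):
        with pytest.raises(ValueError):
            predict_cumulative_c(_constant_model(7.0), 5.0, 4.0)

    def test_constant_model_scales_linearly(self):
        m = _constant_model(np.log(1000.0))
        assert predict_cumulative_c(m, 0.0, 10.0) == pytest.approx(2000.0)
        assert predict_cumulative_c(m, 0.0, 2.5) == pytest.approx(500.0)

    def test_fine_grid_oracle(self):
        """5-cm discretization matches a 1-cm brute-force sum within 2%."""
        m = _sloped_model()
        for depth in (7.0, 12.5, 23.0):
            coarse = predict_cumulative_c(m, 0.0, depth)
            edges = np.arange(0.0, depth, 1.0)
            fine = sum(m.predict_increment(0.5 * (a + min(a + 1.0, depth)),
                                           thickness=min(a + 1.0, depth) - a)
                       for a in edges)
            assert coarse == pytest.approx(fine, rel=0.02)

    def test_additivity_on_grid(self):
        m = _sloped_model()
        total = predict_cumulative_c(m, 0.0, 12.5)
        split = predict_cumulative_c(m, 0.0, 5.0) + \
            predict_cumulative_c(m, 5.0, 12.5)
        assert split == pytest.approx(total, rel=1e-12)

    def test_monotone_in_depth(self):
        m = _sloped_model()
        depths = np.linspace(0.0, 30.0, 40)
        vals = [predict_cumulative_c(m, 0.0, d) for d in depths]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


def _simulate_increments(cfg, composition, regime, n_sites, depth_median,
                         seed):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sites):
        b = rng.normal(0.0, cfg.sol_site_sd)
        depth = depth_median * np.exp(rng.normal(0.0, 0.3))
        prof = simulate_sol_profile(depth, composition, b, rng, cfg, regime)
        prof["group_id"] = f"g{s:03d}"
        rows.append(prof)
    return pd.concat(rows, ignore_index=True)


class TestFit:
    def test_parameter_recovery_200_sites(self):
        cfg = SimConfig()
        truth = cfg.sol_curves["residual_burned_sites"]["spruce"]
        df = _simulate_increments(cfg, "spruce", "residual_burned_sites",
                                  200, 27.0, seed=0)
        m = fit_depth_model(df, "spruce", "residual_burned_sites")
        assert m.converged
        for name, tr in truth.items():
            assert abs(m.coefficients[name] - tr) <= 2 * m.se[name], name
        assert m.site_intercept_sd == pytest.approx(cfg.sol_site_sd, rel=0.35)
        assert m.gamma_shape == pytest.approx(cfg.sol_gamma_shape, rel=0.25)

    def test_zero_site_sd_matches_fixed_effects_glm(self):
        """With no site effect the GLMM collapses to a plain gamma GLM."""
        import statsmodels.api as sm

        cfg = SimConfig(sol_site_sd=0.0)
        df = _simulate_increments(cfg, "spruce", "residual_burned_sites",
                                  120, 27.0, seed=3)
        m = fit_depth_model(df, "spruce", "residual_burned_sites")
        assert m.site_intercept_sd < 0.1

        d = df["depth_mid"].to_numpy()
        i10 = ((d >= 10) & (d < 20)).astype(float)
        i20 = (d >= 20).astype(float)
        X = np.column_stack([np.ones_like(d), d, i10, i20, d * i10, d * i20])
        glm = sm.GLM(df["c_pool"], X,
                     family=sm.families.Gamma(sm.families.links.Log()),
                     offset=np.log(df["thickness"] / 5.0)).fit()
        for k, name in enumerate(["intercept", "depth", "d10_20", "d20plus",
                                  "depth:d10_20", "depth:d20plus"]):
            assert m.coefficients[name] == pytest.approx(glm.params[k],
                                                         abs=0.02), name

    def test_degenerate_constant_pools(self):
        rng = np.random.default_rng(1)
        rows = []
        for s in range(30):
            for mid in (2.5, 7.5, 12.5, 17.5, 22.5):
                rows.append({"group_id": f"g{s}", "depth_mid": mid,
                             "thickness": 5.0,
                             "c_pool": 800.0 * rng.gamma(400, 1 / 400)})
        m = fit_depth_model(pd.DataFrame(rows), "open", "unburned_reference")
        assert m.coefficients["intercept"] == pytest.approx(np.log(800.0),
                                                            abs=0.05)
        assert abs(m.coefficients["depth"]) < 0.01

    def test_single_depth_class_falls_back(self):
        rng = np.random.default_rng(2)
        rows = [{"group_id": f"g{s}", "depth_mid": mid, "thickness": 5.0,
                 "c_pool": float(rng.gamma(2.0, 500.0))}
                for s in range(10) for mid in (2.5, 7.5)]
        with pytest.warns(UserWarning, match="reduced"):
            m = fit_depth_model(pd.DataFrame(rows), "open",
                                "unburned_reference")
        assert m.reduced
        assert m.coefficients["d20plus"] == 0.0

    def test_too_little_data(self):
        rows = [{"group_id": "g0", "depth_mid": 2.5, "thickness": 5.0,
                 "c_pool": 100.0}] * 5
        with pytest.raises(ValueError, match="too little data"):
            fit_depth_model(pd.DataFrame(rows), "open", "unburned_reference")


def test_fit_matches_glmmTMB_oracle(tmp_path):
    """The Laplace fit agrees with glmmTMB on the same data."""
    cfg = SimConfig()
    df = _simulate_increments(cfg, "spruce", "unburned_reference", 60, 25.0,
                              seed=5)
    df = df[df["thickness"] == 5.0]  # keep the R formula simple (no offset)
    m = fit_depth_model(df, "spruce", "unburned_reference")

    d = df.assign(i10=((df["depth_mid"] >= 10) &
                       (df["depth_mid"] < 20)).astype(float),
                  i20=(df["depth_mid"] >= 20).astype(float))
    csv = tmp_path / "inc.csv"
    d.to_csv(csv, index=False)
    script = textwrap.dedent(f"""
        suppressMessages(library(glmmTMB))
        d <- read.csv("{csv}")
        m <- glmmTMB(c_pool ~ depth_mid + i10 + i20 + depth_mid:i10 +
                     depth_mid:i20 + (1 | group_id),
                     family = Gamma(link = "log"), data = d)
        co <- fixef(m)$cond
        cat(co, attr(VarCorr(m)$cond$group_id, "stddev"), sep = "\\n")
    """)
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True)
    vals = [float(x) for x in out.stdout.strip().splitlines()]
    r_coefs, r_sd = vals[:6], vals[6]
    names = ["intercept", "depth", "d10_20", "d20plus", "depth:d10_20",
             "depth:d20plus"]
    for name, rv in zip(names, r_coefs):
        assert m.coefficients[name] == pytest.approx(rv, abs=0.03), name
    assert m.site_intercept_sd == pytest.approx(r_sd, abs=0.03)


class TestSOLCAssembly:
    def test_zero_burn_means_zero_combusted(self):
        m = _constant_model(7.0, regime="unburned_reference")
        assert combusted_sol_c(0.0, m) == 0.0

    def test_regime_routing_enforced(self):
        with pytest.raises(ConfigError):
            residual_sol_c(5.0, _constant_model(7.0,
                                                regime="unburned_reference"))
        with pytest.raises(ConfigError):
            combusted_sol_c(5.0, _constant_model(7.0))

    def test_prefire_is_sum(self):
        assert prefire_sol_c(0.0, 0.0) == 0.0
        assert prefire_sol_c(5083.0, 3157.0) == pytest.approx(8240.0)
        with pytest.raises(ValueError):
            prefire_sol_c(-1.0, 0.0)

    def test_measured_point_overrides_modeled(self):
        """A plot with one monolithed and one modeled point averages the
        measured sum with the model prediction."""
        res_m = _constant_model(np.log(500.0))
        unb_m = _constant_model(np.log(500.0), regime="unburned_reference")
        pts = pd.DataFrame([
            {"point_id": "pt0", "plot_id": "p", "residual_sol_depth_cm": 10.0,
             "burn_depth_cm": 0.0},
            {"point_id": "pt1", "plot_id": "p", "residual_sol_depth_cm": 10.0,
             "burn_depth_cm": 0.0}])
        comp = pd.DataFrame([{"plot_id": "p", "composition": "spruce"}])
        measured = pd.DataFrame([{"profile_id": "m", "plot_id": "p",
                                  "point_id": "pt0", "measured_c": 1600.0}])
        out = plot_soil_pools(pts, {"spruce": res_m}, {"spruce": unb_m},
                              comp, measured)
        # modeled value is 2 * 500 = 1000; measured 1600 -> plot mean 1300
        assert out.loc[0, "belowground_post_fire"] == pytest.approx(1300.0)

    def test_measured_profile_sums(self, small_campaign):
        from reburn.soil import build_increment_table
        ds, _ = small_campaign
        inc = build_increment_table(ds.sol_increments)
        meas = measured_profile_c(inc)
        assert (meas["measured_c"] >= 0).all()
        one = meas.iloc[0]
        manual = inc[(inc["profile_id"] == one["profile_id"])]["c_pool"].sum()
        assert one["measured_c"] == pytest.approx(manual)
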