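"""Adjusted-difference models, Rubin pooling, ICER, bootstrap, CEAC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trialcea import inference, pipeline, schema, synthetic
from trialcea.inference import (
    BootstrapCloud,
    ModelSpec,
    bootstrap_cloud,
    ce_plane_summary,
    ceac,
    ceac_at,
    fit_adjusted_difference,
    icer,
    pool_rubin,
)

from conftest import make_config


def _toy_regression_data(n=4000, arm_effect=0.0, center_sd=0.0, seed=0):
    """Regression data with a known arm effect. ``center_sd=0`` produces
    *exactly* zero between-centre residual variability (noise is centred
    within centre), pinning the REML variance estimate to the boundary."""
    rng = np.random.default_rng(seed)
    center = rng.integers(0, 8, n)
    arm = np.where(rng.random(n) < 0.5, "intervention", "control")
    base = rng.normal(0, 1, n)
    noise = rng.normal(0, 1, n)
    if center_sd == 0:
        noise -= pd.Series(noise).groupby(center).transform("mean").to_numpy()
    y = (
        2.0
        + arm_effect * (arm == "intervention")
        + 0.5 * base
        + center_sd * rng.normal(size=8)[center]
        + noise
    )
    return pd.DataFrame(
        {
            "y": y,
            "baseline": base,
            "age": rng.normal(60, 9, n),
            "male": rng.integers(0, 2, n),
            "cvd_history": rng.integers(0, 2, n),
            "smoking": rng.integers(0, 2, n),
            "diabetes_duration": rng.gamma(2, 4, n),
            "arm": arm,
            "center": center,
        }
    )


class TestAdjustedDifference:
    def test_null_effect_recovered_within_three_se(self):
        df = _toy_regression_data(n=10_000, arm_effect=0.0, center_sd=0.3, seed=1)
        est, var = fit_adjusted_difference(df, ModelSpec("y", "baseline"))
        assert abs(est) < 3 * np.sqrt(var)

    def test_embedded_qaly_effect_recovered_across_seeds(self):
        """The generator embeds a 0.020 QALY increment; the adjusted model's
        95% CI covers it in nearly all repetitions."""
        hits = 0
        for seed in range(10):
            cfg = make_config(
                seed=seed, n_per_arm=(150, 150), effect_targets=(111.0, 0.020)
            )
            df, _ = synthetic.generate_trial(cfg)
            table = pipeline.prepare_analysis_table(df)
            table["qaly"] = (
                0.125 * table["u_0"] + 0.5 * table["u_3"] + 0.375 * table["u_12"]
            )
            table = table.dropna(subset=["qaly"])
            est, var = fit_adjusted_difference(
                table, ModelSpec("qaly", schema.utility_col(0))
            )
            se = np.sqrt(var)
            hits += est - 1.96 * se <= 0.020 <= est + 1.96 * se
        assert hits >= 8

    def test_zero_center_variance_matches_ols_oracle(self):
        import statsmodels.api as sm

        df = _toy_regression_data(n=3000, arm_effect=0.7, center_sd=0.0, seed=3)
        est, _ = fit_adjusted_difference(df, ModelSpec("y", "baseline"))
        covs = ["baseline", "age", "male", "cvd_history", "smoking",
                "diabetes_duration"]
        X = np.column_stack(
            [
                np.ones(len(df)),
                (df["arm"] == "intervention").astype(float),
                df[covs].to_numpy(),
            ]
        )
        ols = sm.OLS(df["y"].to_numpy(), X).fit().params[1]
        assert est == pytest.approx(ols, abs=1e-6)

    def test_single_center_rejected(self):
        df = _toy_regression_data(n=50)
        df["center"] = 0
        with pytest.raises(ValueError, match="2 centres"):
            fit_adjusted_difference(df, ModelSpec("y", "baseline"))

    def test_incomplete_copy_rejected(self):
        df = _toy_regression_data(n=50)
        df.loc[0, "baseline"] = np.nan
        with pytest.raises(ValueError, match="completed"):
            fit_adjusted_difference(df, ModelSpec("y", "baseline"))


class TestRubinPooling:
    def test_identical_estimates_pool_to_themselves(self):
        out = pool_rubin([2.5, 2.5, 2.5], [0.4, 0.4, 0.4])
        assert out.point == 2.5
        assert out.se == pytest.approx(np.sqrt(0.4))

    def test_hand_computed_total_variance(self):
        # estimates {1,2,3}: between-variance 1; within-mean 1
        out = pool_rubin([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert out.point == 2.0
        assert out.se**2 == pytest.approx(1.0 + (1 + 1 / 3) * 1.0)

    @given(
        qs=st.lists(st.floats(-50, 50), min_size=2, max_size=12),
        ws=st.lists(st.floats(0.01, 10), min_size=2, max_size=12),
    )
    def test_total_variance_never_below_mean_within(self, qs, ws):
        m = min(len(qs), len(ws))
        out = pool_rubin(qs[:m], ws[:m])
        assert out.se**2 >= np.mean(ws[:m]) - 1e-12

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            pool_rubin([], [])


class TestICER:
    def test_published_qaly_ratio(self):
        r = icer(111.0, 0.020)
        assert r.ratio == pytest.approx(5550.0)
        assert r.quadrant == "NE"

    def test_published_paid_ratio_to_nearest_pound(self):
        assert round(icer(111.0, 1.9).ratio) == 58

    def test_zero_cost_difference(self):
        assert icer(0.0, 0.5).ratio == 0.0

    def test_zero_effect_is_undefined_not_infinite(self):
        r = icer(100.0, 0.0)
        assert not r.defined
        assert np.isnan(r.ratio)

    @given(
        dc=st.floats(-1e4, 1e4),
        de=st.floats(0.001, 10),
        a=st.floats(0.01, 100),
    )
    def test_scale_invariance(self, dc, de, a):
        assert icer(a * dc, a * de).ratio == pytest.approx(
            icer(dc, de).ratio, rel=1e-9, abs=1e-9
        )


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(0)
    n = 400
    return pd.DataFrame(
        {
            "arm": ["intervention"] * (n // 2) + ["control"] * (n // 2),
            "cost": rng.gamma(2, 500, n),
            "eff": rng.normal(0.8, 0.2, n),
        }
    )


class TestBootstrap:
    @staticmethod
    def _mean_diff_pipeline(resample, rng):
        g = resample.groupby("arm")
        dc = g["cost"].mean()
        de = g["eff"].mean()
        return (
            dc["intervention"] - dc["control"],
            de["intervention"] - de["control"],
        )

    def test_identical_arms_center_cloud_at_origin(self):
        # both arms carry the same participant values, so the estimand is 0
        rng = np.random.default_rng(0)
        half = pd.DataFrame(
            {"cost": rng.gamma(2, 500, 150), "eff": rng.normal(0.8, 0.2, 150)}
        )
        toy = pd.concat(
            [half.assign(arm="intervention"), half.assign(arm="control")],
            ignore_index=True,
        )
        cloud = bootstrap_cloud(toy, self._mean_diff_pipeline, B=300, seed=4)
        assert abs(cloud.delta_cost.mean()) < 3 * cloud.delta_cost.std() / np.sqrt(300)
        assert abs(cloud.delta_effect.mean()) < 3 * cloud.delta_effect.std() / np.sqrt(300)

    def test_same_seed_same_cloud(self, toy):
        c1 = bootstrap_cloud(toy, self._mean_diff_pipeline, B=50, seed=9)
        c2 = bootstrap_cloud(toy, self._mean_diff_pipeline, B=50, seed=9)
        np.testing.assert_array_equal(c1.delta_cost, c2.delta_cost)
        np.testing.assert_array_equal(c1.delta_effect, c2.delta_effect)

    def test_invalid_replicate_count_rejected(self, toy):
        with pytest.raises(ValueError):
            bootstrap_cloud(toy, self._mean_diff_pipeline, B=0, seed=1)

    def test_percentile_ci_brackets_point_on_calibrated_data(self):
        """Resampling a trial with an embedded cost difference of 111 gives
        a percentile CI that brackets the embedded value."""
        cfg = make_config(
            seed=31, n_per_arm=(150, 150), effect_targets=(111.0, 0.020)
        )
        df, _ = synthetic.generate_trial(cfg)
        table = pipeline.prepare_analysis_table(df)
        table["cost"] = table[pipeline.TRIAL_COST_VARS].sum(axis=1) + np.where(
            table["arm"] == "intervention", 263.0, 0.0
        )
        table["eff"] = table["u_12"]
        cloud = bootstrap_cloud(
            table.dropna(subset=["eff"]), self._mean_diff_pipeline, B=400, seed=2
        )
        lo, hi = cloud.percentile_ci("cost")
        assert lo < 111.0 < hi


class TestPlaneAndCEAC:
    def test_all_northeast_cloud(self):
        cloud = BootstrapCloud(np.ones(10), np.ones(10), B=10, seed=0)
        assert ce_plane_summary(cloud) == {
            "NE": 1.0, "SE": 0.0, "NW": 0.0, "SW": 0.0
        }

    def test_mirrored_cloud_swaps_opposite_quadrants(self, rng):
        dc, de = rng.normal(50, 100, 500), rng.normal(0.01, 0.02, 500)
        a = ce_plane_summary(BootstrapCloud(dc, de, 500, 0))
        b = ce_plane_summary(BootstrapCloud(-dc, -de, 500, 0))
        assert a["NE"] == b["SW"] and a["SE"] == b["NW"]

    def test_ceac_limits_match_quadrant_shares(self, rng):
        dc = rng.normal(100, 150, 2000)
        de = rng.normal(0.02, 0.012, 2000)
        cloud = BootstrapCloud(dc, de, 2000, 0)
        plane = ce_plane_summary(cloud)
        curve = ceac(cloud, [0.0, 1e12])
        assert curve["probability"].iloc[0] == pytest.approx(
            plane["SE"] + plane["SW"]
        )
        assert curve["probability"].iloc[1] == pytest.approx(
            plane["NE"] + plane["SE"]
        )

    def test_probabilities_bounded_and_monotone_for_positive_effects(self, rng):
        dc = rng.normal(100, 150, 1000)
        de = np.abs(rng.normal(0.02, 0.012, 1000))  # all effects positive
        curve = ceac(BootstrapCloud(dc, de, 1000, 0), range(0, 50_001, 5000))
        p = curve["probability"]
        assert ((0 <= p) & (p <= 1)).all()
        assert (np.diff(p) >= 0).all()

    def test_negative_wtp_rejected(self):
        cloud = BootstrapCloud(np.ones(3), np.ones(3), 3, 0)
        with pytest.raises(ValueError):
            ceac(cloud, [-5.0])

    def test_lookup_on_grid(self):
        cloud = BootstrapCloud(np.array([-1.0, 1.0]), np.array([1.0, 1.0]), 2, 0)
        curve = ceac(cloud, [0, 20_000])
        assert ceac_at(curve, 20_000) == 1.0
        with pytest.raises(KeyError):
            ceac_at(curve, 12_345)
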