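"""Screens, standardization, moderated OLS, case bootstrap, FDR, probing."""

import numpy as np
import pandas as pd
import pytest

from devddm.cohort import generate_moderation_sample
from devddm.inference import (
    ModeratedRegression,
    bootstrap_inference,
    build_family,
    exclude_by_residuals,
    fdr_adjust,
    main_family_factors,
    probe_interaction,
    screen_outliers,
    standardize,
    supplementary_family_factors,
)


class TestScreenOutliers:
    def group_table(self, values):
        return pd.DataFrame({"x": values, "age_band": "6-7"})

    def test_identical_values_untouched(self):
        out, log = screen_outliers(self.group_table([5.0] * 10), ["x"])
        assert len(log) == 0 and not out["x"].isna().any()

    def test_planted_point_removed(self):
        base = list(np.tile([9.0, 10.0, 11.0], 10))
        mu, sd = np.mean(base), np.std(base, ddof=1)
        tbl = self.group_table(base + [mu + 4 * sd])
        out, log = screen_outliers(tbl, ["x"])
        assert log["index"].tolist() == [len(base)]
        assert out["x"].isna().sum() == 1

    def test_screening_is_idempotent_on_its_output(self):
        base = list(np.tile([9.0, 10.0, 11.0], 10))
        tbl = self.group_table(base + [50.0])
        once, _ = screen_outliers(tbl, ["x"])
        twice, log2 = screen_outliers(once, ["x"])
        pd.testing.assert_frame_equal(twice, once)
        assert len(log2) == 0

    def test_small_groups_skipped_with_warning(self):
        tbl = pd.DataFrame({"x": [1.0, 100.0], "age_band": "18+"})
        with pytest.warns(UserWarning, match="skipped"):
            out, log = screen_outliers(tbl, ["x"])
        assert len(log) == 0


class TestStandardize:
    def test_moments_and_idempotence(self, rng):
        tbl = pd.DataFrame({"x": rng.uniform(2, 9, 40)})
        z = standardize(tbl, ["x"])
        assert z["x"].mean() == pytest.approx(0.0, abs=1e-12)
        assert z["x"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        pd.testing.assert_frame_equal(standardize(z, ["x"]), z)

    def test_hand_computed_column(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        z = standardize(pd.DataFrame({"x": vals}), ["x"])
        expected = (vals - 3.0) / np.std(vals, ddof=1)
        assert z["x"].to_numpy() == pytest.approx(expected)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            standardize(pd.DataFrame({"x": [2.0, 2.0, 2.0]}), ["x"])


class TestModeratedRegression:
    def test_simple_standardized_slope_is_pearson_r(self, rng):
        x = rng.standard_normal(200)
        y = 0.6 * x + rng.standard_normal(200)
        df = pd.DataFrame({"y": y, "x": x})
        fit = ModeratedRegression("y", ["x"]).fit(df)
        assert fit.coef_["x"] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_orthogonal_predictor_leaves_focal_beta(self, rng):
        x = rng.standard_normal(150)
        y = 0.5 * x + rng.standard_normal(150)
        z = rng.standard_normal(150)
        X = np.column_stack([np.ones(150), x])
        z = z - X @ np.linalg.lstsq(X, z, rcond=None)[0]  # exactly orthogonal
        df = pd.DataFrame({"y": y, "x": x, "z": z})
        b1 = ModeratedRegression("y", ["x"]).fit(df).coef_["x"]
        b2 = ModeratedRegression("y", ["x", "z"]).fit(df).coef_["x"]
        assert b2 == pytest.approx(b1, abs=1e-10)

    def test_interaction_recovery_in_the_mean(self, rng):
        coeffs = {"nt": 0.1, "age": -0.3, "nt:age": 0.25, "c1": 0.1, "c2": 0.1}
        model = ModeratedRegression("y", ["nt", "age", "nt:age", "c1", "c2"])
        betas = [
            model.fit(generate_moderation_sample(500, coeffs, seed=rng)).coef_["nt:age"]
            for _ in range(200)
        ]
        assert np.mean(betas) == pytest.approx(0.25, abs=0.02)

    def test_interaction_type_i_error_rate(self, rng):
        coeffs = {"nt": 0.0, "age": 0.0, "nt:age": 0.0, "c1": 0.0, "c2": 0.0}
        model = ModeratedRegression("y", ["nt", "age", "nt:age", "c1", "c2"])
        rejections = 0
        for _ in range(1000):
            fit = model.fit(generate_moderation_sample(150, coeffs, seed=rng))
            rejections += fit.pvalues_["nt:age"] < 0.05
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_error_contracts(self, rng):
        x = rng.standard_normal(50)
        df = pd.DataFrame({"y": rng.standard_normal(50), "x": x, "x2": x})
        with pytest.raises(ValueError, match="rank-deficient"):
            ModeratedRegression("y", ["x", "x2"]).fit(df)
        with pytest.raises(ValueError, match="missing column"):
            ModeratedRegression("y", ["nope"]).fit(df)
        with pytest.raises(ValueError, match="main effect"):
            ModeratedRegression("y", ["x:x2"]).fit(df)


class TestBootstrap:
    def make_df(self, rng, n=120, beta=0.5):
        x = rng.standard_normal(n)
        y = beta * x + np.sqrt(1 - beta**2) * rng.standard_normal(n)
        return pd.DataFrame({"y": y, "x": x})

    def test_fixed_seed_reproducibility(self, rng):
        df = self.make_df(rng)
        model = ModeratedRegression("y", ["x"]).fit(df)
        r1 = bootstrap_inference(model, df, B=200, seed=5)
        r2 = bootstrap_inference(model, df, B=200, seed=5)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_deterministic_relation_collapses_interval(self, rng):
        x = rng.standard_normal(80)
        df = pd.DataFrame({"y": 2.0 * x + 1.0, "x": x})
        model = ModeratedRegression("y", ["x"]).fit(df)
        res = bootstrap_inference(model, df, B=200, seed=1)
        width = res.table.loc["x", "ci_high"] - res.table.loc["x", "ci_low"]
        assert width == pytest.approx(0.0, abs=1e-10)
        assert res.table.loc["x", "beta"] == pytest.approx(1.0)

    def test_percentile_interval_coverage(self):
        # a truly-zero coefficient at n=200: the 95% CI should cover zero in
        # 95% +/- 3% of correctly specified replicates
        outer = np.random.default_rng(2024)
        model = ModeratedRegression("y", ["x"])
        hits = 0
        n_outer = 300
        for _ in range(n_outer):
            df = self.make_df(outer, n=200, beta=0.0)
            res = bootstrap_inference(model.fit(df), df, B=499, seed=outer)
            lo, hi = res.table.loc["x", ["ci_low", "ci_high"]]
            hits += lo <= 0.0 <= hi
        assert 0.92 <= hits / n_outer <= 0.98

    def test_small_b_warns(self, rng):
        df = self.make_df(rng)
        model = ModeratedRegression("y", ["x"]).fit(df)
        with pytest.warns(UserWarning, match="small"):
            bootstrap_inference(model, df, B=50, seed=0)


class TestResidualExclusion:
    def test_clean_sample_is_left_alone(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(100)})
        df["y"] = 0.5 * df["x"] + 0.3 * rng.standard_normal(100)
        model = ModeratedRegression("y", ["x"]).fit(df)
        refit, excluded = exclude_by_residuals(model, df)
        assert excluded == []
        assert refit.n_used_ == model.n_used_

    def test_planted_outlier_removed_and_slope_recovers(self, rng):
        x = rng.standard_normal(150)
        y = 0.5 * x + 0.1 * rng.standard_normal(150)
        df = pd.DataFrame({"y": y, "x": x})
        df.loc[0, "y"] = 30.0  # gross contamination
        model = ModeratedRegression("y", ["x"]).fit(df)
        refit, excluded = exclude_by_residuals(model, df)
        assert excluded == [0]
        clean_r = np.corrcoef(x[1:], y[1:])[0, 1]
        assert abs(refit.coef_["x"] - clean_r) < abs(model.coef_["x"] - clean_r)
        assert refit.coef_["x"] == pytest.approx(clean_r, abs=1e-10)


class TestFamilies:
    def test_printed_multiplicities(self):
        assert len(build_family(main_family_factors())) == 36
        assert len(build_family(supplementary_family_factors())) == 180

    def test_degenerate_descriptors(self):
        assert len(build_family({"a": ["x"], "b": ["y"]})) == 1
        with pytest.raises(ValueError, match="no levels"):
            build_family({"a": []})


def bh_naive(p):
    """Naive quadratic-time BH: q_i = min over thresholds t >= p_i of
    m * t / #{p <= t}, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    return np.array(
        [
            min(1.0, min(m * t / np.sum(p <= t) for t in p if t >= pi))
            for pi in p
        ]
    )


class TestFDR:
    def test_matches_naive_oracle_exhaustively(self):
        grid = [0.005, 0.04, 0.2, 0.6, 1.0]
        from itertools import product

        for length in (1, 2, 3, 4):
            for combo in product(grid, repeat=length):
                p = np.array(combo)
                np.testing.assert_allclose(fdr_adjust(p), bh_naive(p), atol=1e-12)

    def test_matches_naive_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.uniform(0, 1, rng.integers(5, 7))
            np.testing.assert_allclose(fdr_adjust(p), bh_naive(p), atol=1e-12)

    def test_known_cases(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        assert fdr_adjust([0.37])[0] == pytest.approx(0.37)
        np.testing.assert_allclose(fdr_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestProbeInteraction:
    def fit_example(self, rng, n=300):
        x, w = rng.standard_normal((2, n))
        y = 0.1 * x + 0.3 * w - 0.2 * x * w + 0.1 * rng.standard_normal(n)
        df = pd.DataFrame({"y": y, "x": x, "w": w})
        return df, ModeratedRegression("y", ["x", "w", "x:w"]).fit(df)

    def test_simple_slope_arithmetic(self):
        model = ModeratedRegression("y", ["x", "w", "x:w"])
        model.coef_ = pd.Series({"x": 0.1, "w": 0.0, "x:w": -0.2})
        model.intercept_ = 0.0
        probe = probe_interaction(model, "x", "w")
        assert probe["slope"].tolist() == pytest.approx([0.3, 0.1, -0.1])
        model.coef_["x:w"] = 0.0
        probe = probe_interaction(model, "x", "w")
        assert probe["slope"].nunique() == 1

    def test_missing_product_term_raises(self, rng):
        df = pd.DataFrame({"y": rng.standard_normal(30),
                           "x": rng.standard_normal(30)})
        model = ModeratedRegression("y", ["x"]).fit(df)
        with pytest.raises(ValueError, match="product"):
            probe_interaction(model, "x", "w")

    def test_recentred_refit_reproduces_simple_slope(self, rng):
        # oracle: the slope at moderator level w0 equals the focal main
        # effect of a refit with the moderator shifted by w0
        x, w = rng.standard_normal((2, 200))
        y = 0.4 * x - 0.25 * w + 0.3 * x * w + 0.2 * rng.standard_normal(200)
        df = pd.DataFrame({"y": y, "x": x, "w": w})
        fit = ModeratedRegression("y", ["x", "w", "x:w"], standardize=False).fit(df)
        w0 = -fit.coef_["x"] / fit.coef_["x:w"]  # crossover level
        for level in (w0, 1.0, -1.0):
            shifted = df.assign(w=df["w"] - level)
            refit = ModeratedRegression(
                "y", ["x", "w", "x:w"], standardize=False
            ).fit(shifted)
            expected = fit.coef_["x"] + level * fit.coef_["x:w"]
            assert refit.coef_["x"] == pytest.approx(expected, abs=1e-10)
        assert fit.coef_["x"] + w0 * fit.coef_["x:w"] == pytest.approx(0, abs=1e-12)
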