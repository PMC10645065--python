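import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import skewconstraint as sc
from skewconstraint import DataError, ModelSpec


class TestNegLogLikelihood:
    def test_standard_normal_single_observation(self):
        df = pd.DataFrame({"y": [0.0]})
        spec = ModelSpec(response="y")
        val = sc.neg_log_likelihood(np.array([0.0, 0.0, 0.0]), df, spec)
        assert val == pytest.approx(-math.log(scipy.stats.norm.pdf(0.0)), abs=1e-10)

    def test_agrees_with_density_product_oracle(self, rng):
        # independent oracle: product of scipy skew-normal densities
        y = rng.standard_normal(10)
        df = pd.DataFrame({"y": y})
        mu, log_sigma, alpha = 0.3, -0.2, 2.0
        direct = sc.centered_to_direct(
            sc.SkewNormalParams(mu, math.exp(log_sigma), alpha, "centered")
        )
        oracle = -np.sum(
            scipy.stats.skewnorm.logpdf(
                y, direct.shape, loc=direct.location, scale=direct.scale
            )
        )
        val = sc.neg_log_likelihood(
            np.array([mu, log_sigma, alpha]), df, ModelSpec(response="y")
        )
        assert val == pytest.approx(oracle, abs=1e-8)

    def test_wrong_parameter_count(self):
        df = pd.DataFrame({"y": [0.0, 1.0]})
        with pytest.raises(DataError):
            sc.neg_log_likelihood(np.zeros(5), df, ModelSpec(response="y"))


class TestFit:
    def test_recovers_generating_parameters(self):
        truth = sc.SkewNormalParams(1.0, 2.0, 3.0, "centered")
        df = sc.generate_skewnormal_dataset(4000, truth, seed=8)
        f = sc.fit(df, ModelSpec(response="y"))
        assert f.converged
        assert f["intercept"] == pytest.approx(1.0, abs=0.1)
        assert f["sigma_intercept"] == pytest.approx(math.log(2.0), abs=0.05)
        assert f["alpha_intercept"] == pytest.approx(3.0, abs=1.0)

    def test_null_shape_interval_covers_zero(self):
        hits = 0
        for r in range(20):
            df = sc.generate_skewnormal_dataset(
                1000, sc.SkewNormalParams(0, 1, 0, "centered"), seed=r
            )
            f = sc.fit(df, ModelSpec(response="y"), seed=r)
            lo, hi = f.intervals["alpha_intercept"]
            hits += lo <= 0 <= hi
        assert hits >= 17

    def test_likelihood_nesting(self, rng):
        df = sc.generate_skewnormal_dataset(
            500, sc.SkewNormalParams(0, 1, 2, "centered"), seed=4
        )
        df["noise"] = rng.standard_normal(len(df))
        simple = sc.fit(df, ModelSpec(response="y"))
        richer = sc.fit(df, ModelSpec(response="y", mu_formula="~noise"))
        assert richer.loglik >= simple.loglik - 1e-6

    def test_shift_equivariance(self):
        df = sc.generate_skewnormal_dataset(
            800, sc.SkewNormalParams(0, 1, 3, "centered"), seed=5
        )
        f1 = sc.fit(df, ModelSpec(response="y"))
        f2 = sc.fit(df.assign(y=df.y + 7.0), ModelSpec(response="y"))
        assert f2["intercept"] - f1["intercept"] == pytest.approx(7.0, abs=1e-4)
        assert f2["sigma_intercept"] == pytest.approx(f1["sigma_intercept"], abs=1e-4)
        assert f2["alpha_intercept"] == pytest.approx(f1["alpha_intercept"], abs=1e-3)

    def test_two_condition_fit_is_stable_across_seeds(self, table1_spec):
        # misspecification stability: the generator is not truly skew
        # normal, but repeated fits agree closely
        ests = []
        for seed in (0, 1, 2):
            df = sc.generate_two_condition_dataset(2000, seed=seed)
            f = sc.fit(df, table1_spec, seed=seed)
            assert f.converged
            ests.append([f["intercept"], f["resource_high"], f["sigma_intercept"]])
        sd = np.std(ests, axis=0)
        assert np.all(sd < 0.1)

    def test_singular_design_rejected(self):
        df = pd.DataFrame({"y": np.random.default_rng(0).standard_normal(50)})
        df["a"] = 1.0
        df["b"] = 2.0  # collinear with intercept and a
        with pytest.raises(DataError, match="collinear"):
            sc.fit(df, ModelSpec(response="y", mu_formula="~a + b"))

    def test_small_sample_warns(self):
        df = sc.generate_skewnormal_dataset(
            20, sc.SkewNormalParams(0, 1, 1, "centered"), seed=0
        )
        with pytest.warns(UserWarning, match="observations"):
            sc.fit(df, ModelSpec(response="y"))

    def test_random_intercept_recovers_group_spread(self):
        # oracle: the realized SD of the generator's group-level shapes
        n_groups, n_per, a_mean, a_sd, seed = 20, 500, 2.0, 1.0, 1
        realized = np.random.default_rng(seed).normal(a_mean, a_sd, n_groups)
        df = sc.generate_hierarchical(n_groups, n_per, a_mean, a_sd, seed=seed)
        f = sc.fit(
            df, ModelSpec(response="y", alpha_formula="~1 + (1|ID)"), n_starts=2
        )
        assert f.converged
        tau = f.estimates["tau_ID"]
        target = realized.std(ddof=1)
        assert abs(tau - target) / target < 0.5
        assert f["alpha_intercept"] == pytest.approx(realized.mean(), abs=1.0)


class TestPredictParams:
    def test_resource_contrast_is_exact(self, two_condition_df, table1_spec):
        f = sc.fit(two_condition_df, table1_spec)
        new = pd.DataFrame({"resource": ["low", "high"]})
        p_low, p_high = sc.predict_params(f, new)
        assert p_high.location - p_low.location == pytest.approx(
            f["resource_high"], abs=1e-10
        )
        assert p_high.shape - p_low.shape == pytest.approx(
            f["alpha_resource_high"], abs=1e-10
        )
        assert p_low.scale == pytest.approx(math.exp(f["sigma_intercept"]), rel=1e-12)

    def test_unknown_fixed_level_rejected(self, two_condition_df, table1_spec):
        f = sc.fit(two_condition_df, table1_spec)
        with pytest.raises(DataError, match="medium"):
            sc.predict_params(f, pd.DataFrame({"resource": ["medium"]}))

    def test_group_deviations_respected(self):
        df = sc.generate_hierarchical(6, 200, 2.0, 1.5, seed=3)
        f = sc.fit(df, ModelSpec(response="y", alpha_formula="~1 + (1|ID)"), n_starts=2)
        new = pd.DataFrame({"ID": ["g01", "g02"]})
        with_g = sc.predict_params(f, new, include_groups=True)
        without_g = sc.predict_params(f, new, include_groups=False)
        # population-level predictions are identical across groups
        assert without_g[0].shape == without_g[1].shape
        # group predictions differ and equal intercept + deviation
        assert with_g[0].shape != with_g[1].shape
        assert with_g[0].shape == pytest.approx(
            f["alpha_intercept"] + f.estimates["u_alpha[ID:g01]"], abs=1e-10
        )
        with pytest.raises(DataError, match="g99"):
            sc.predict_params(
                f, pd.DataFrame({"ID": ["g99"]}), include_groups=True
            )


class TestGroupConstraintCurves:
    def test_identical_rows_identical_curves(self, two_condition_df, table1_spec):
        f = sc.fit(two_condition_df, table1_spec)
        new = pd.DataFrame({"resource": ["low", "low"]})
        c1, c2 = sc.group_constraint_curves(f, new, include_groups=False)
        assert np.array_equal(c1.constraint, c2.constraint)
        assert np.array_equal(c1.grid, c2.grid)

    def test_zero_shape_rows_return_none_with_warning(self, rng):
        df = pd.DataFrame({"y": rng.standard_normal(100)})
        f = sc.fit(df, ModelSpec(response="y", alpha_formula=None))
        with pytest.warns(UserWarning, match="shape is 0"):
            curves = sc.group_constraint_curves(f, pd.DataFrame({"dummy": [1]}))
        assert curves == [None]

    def test_weaker_shape_gives_shallower_curve(self, two_condition_df, table1_spec):
        f = sc.fit(two_condition_df, table1_spec)
        new = pd.DataFrame({"resource": ["low", "high"]})
        low, high = sc.group_constraint_curves(f, new, include_groups=False)
        # |alpha| is larger in the low-resource condition
        assert low.max_abs_slope() > high.max_abs_slope()


class TestCompareModels:
    def test_self_comparison_is_zero(self, rng):
        df = pd.DataFrame({"y": rng.standard_normal(200)})
        spec = ModelSpec(response="y")
        f = sc.fit(df, spec)
        res = sc.compare_models(f, f, df, k=4, seed=0)
        assert res.elpd_diff == 0.0
        assert res.method == "kfold_cv"

    def test_skew_model_beats_normal_on_constrained_data(self):
        df = sc.generate_two_condition_dataset(250, seed=6)
        skew_spec = ModelSpec(response="performance", alpha_formula="~1")
        norm_spec = ModelSpec(response="performance", alpha_formula=None)
        f_skew = sc.fit(df, skew_spec, seed=6)
        f_norm = sc.fit(df, norm_spec, seed=6)
        res = sc.compare_models(f_skew, f_norm, df, k=5, seed=6)
        assert res.elpd_diff > 0
        assert res.se_diff >= 0
        aic = sc.compare_models(
            f_skew, f_norm, df, method="information_criterion"
        )
        assert aic.elpd_diff > 0
        assert aic.se_diff == 0.0

    def test_covariate_model_beats_intercept_only(self, table1_spec):
        wins = 0
        for seed in range(8):
            df = sc.generate_two_condition_dataset(300, seed=seed)
            f_cov = sc.fit(df, table1_spec, seed=seed)
            f_int = sc.fit(
                df, ModelSpec(response="performance"), seed=seed
            )
            res = sc.compare_models(f_cov, f_int, df, k=4, seed=seed)
            wins += res.elpd_diff > 0
        assert wins >= 7

    def test_mismatched_data_rejected(self, rng):
        df = pd.DataFrame({"y": rng.standard_normal(100)})
        f = sc.fit(df, ModelSpec(response="y"))
        with pytest.raises(DataError):
            sc.compare_models(f, f, df.iloc[:50])
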