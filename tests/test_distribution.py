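import math

import numpy as np
import pytest
import scipy.integrate
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import skewconstraint as sc
from skewconstraint import DataError, SkewNormalParams


def numerical_moments(params: SkewNormalParams):
    """Independent quadrature oracle for mean, SD and skewness."""
    p = sc.centered_to_direct(params)
    lo, hi = p.location - 12 * p.scale, p.location + 12 * p.scale

    def moment(k, center=0.0):
        f = lambda y: (y - center) ** k * sc.density(y, params)
        return scipy.integrate.quad(f, lo, hi, limit=200)[0]

    m = moment(1)
    v = moment(2, m)
    m3 = moment(3, m)
    return m, math.sqrt(v), m3 / v**1.5


class TestDensity:
    def test_reduces_to_normal_at_zero_shape(self):
        p = SkewNormalParams(0, 1, 0, "direct")
        y = np.linspace(-5, 5, 41)
        assert np.allclose(sc.density(y, p), scipy.stats.norm.pdf(y), atol=1e-12)

    def test_large_shape_matches_half_normal(self):
        # alpha -> inf folds the density onto the positive half line
        p = SkewNormalParams(0, 1, 50, "direct")
        y = np.array([0.1, 0.5, 1.0, 2.0])
        half_normal = 2 * scipy.stats.norm.pdf(y)
        assert np.allclose(sc.density(y, p), half_normal, atol=1e-3)

    @pytest.mark.parametrize("alpha", [-10, -2, 0, 2, 10])
    def test_integrates_to_one(self, alpha):
        p = SkewNormalParams(1.0, 2.0, alpha, "direct")
        total = scipy.integrate.quad(
            lambda y: sc.density(y, p), 1.0 - 20.0, 1.0 + 20.0, limit=200
        )[0]
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_integrates_to_one_centered_negative_shape(self):
        p = SkewNormalParams(1.0, 2.0, -3.0, "centered")
        total = scipy.integrate.quad(
            lambda y: sc.density(y, p), -19.0, 21.0, limit=200
        )[0]
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_agrees_with_scipy_reference(self):
        p = SkewNormalParams(0.5, 1.5, -4.0, "direct")
        y = np.linspace(-6, 6, 25)
        ref = scipy.stats.skewnorm.pdf(y, -4.0, loc=0.5, scale=1.5)
        assert np.allclose(sc.density(y, p), ref, rtol=1e-12)

    def test_rejects_non_finite_input(self):
        p = SkewNormalParams(0, 1, 1, "direct")
        with pytest.raises(DataError):
            sc.density(np.nan, p)

    def test_rejects_invalid_scale(self):
        with pytest.raises(DataError):
            SkewNormalParams(0, 0.0, 1, "direct")
        with pytest.raises(DataError):
            SkewNormalParams(0, 1, math.inf, "direct")


class TestCdfComponent:
    def test_equals_one_at_location(self):
        p = SkewNormalParams(2.0, 3.0, 4.0, "direct")
        assert sc.cdf_component(2.0, p) == pytest.approx(1.0)

    def test_constant_one_when_symmetric(self):
        p = SkewNormalParams(0, 1, 0, "direct")
        assert np.allclose(sc.cdf_component(np.linspace(-5, 5, 11), p), 1.0)

    def test_limits_and_monotonicity(self):
        p = SkewNormalParams(0, 1, 2.0, "direct")
        assert sc.cdf_component(1e8, p) == pytest.approx(2.0)
        assert sc.cdf_component(-1e8, p) == pytest.approx(0.0)
        v = sc.cdf_component(np.linspace(-4, 4, 100), p)
        assert np.all(np.diff(v) > 0)
        v_neg = sc.cdf_component(np.linspace(-4, 4, 100), SkewNormalParams(0, 1, -2.0, "direct"))
        assert np.all(np.diff(v_neg) < 0)


class TestParameterizations:
    def test_symmetric_case_is_identity(self):
        c = SkewNormalParams(0, 1, 0, "centered")
        d = sc.centered_to_direct(c)
        assert (d.location, d.scale) == (0, 1)
        assert d.parameterization == "direct"

    def test_known_conversion_alpha5(self):
        # frozen from the delta = 0.98058 derivation; cross-checked by the
        # moment oracle below
        d = sc.centered_to_direct(SkewNormalParams(0, 1, 5, "centered"))
        assert d.location == pytest.approx(-1.2562, abs=2e-4)
        assert d.scale == pytest.approx(1.6056, abs=2e-4)

    def test_centered_params_are_true_moments(self):
        params = SkewNormalParams(0.7, 1.3, -2.5, "centered")
        mean, sd, _ = numerical_moments(params)
        assert mean == pytest.approx(0.7, abs=1e-6)
        assert sd == pytest.approx(1.3, abs=1e-6)

    @given(
        st.floats(-10, 10),
        st.floats(0.01, 10),
        st.floats(-20, 20),
        st.sampled_from(["direct", "centered"]),
    )
    @settings(derandomize=True, max_examples=60)
    def test_round_trip_identity(self, loc, scale, shape, form):
        p = SkewNormalParams(loc, scale, shape, form)
        if form == "centered":
            back = sc.direct_to_centered(sc.centered_to_direct(p))
        else:
            back = sc.centered_to_direct(sc.direct_to_centered(p))
        assert back.location == pytest.approx(loc, abs=1e-10)
        assert back.scale == pytest.approx(scale, abs=1e-10, rel=1e-10)
        assert back.shape == shape


class TestSkewnessMaps:
    def test_zero(self):
        assert sc.skewness_from_alpha(0.0) == 0.0
        assert sc.alpha_from_skewness(0.0) == 0.0

    def test_alpha_one_matches_moment_oracle(self):
        _, _, g1 = numerical_moments(SkewNormalParams(0, 1, 1, "direct"))
        assert sc.skewness_from_alpha(1.0) == pytest.approx(g1, abs=1e-6)
        assert sc.skewness_from_alpha(1.0) == pytest.approx(0.1369, abs=1e-3)

    def test_limit_approaches_bound(self):
        assert sc.skewness_from_alpha(1e8) == pytest.approx(0.9953, abs=1e-3)
        assert sc.MAX_SKEWNESS == pytest.approx(0.9953, abs=1e-4)

    def test_inverse_contract(self):
        assert sc.alpha_from_skewness(0.1369) == pytest.approx(1.0, abs=2e-3)
        a = sc.alpha_from_skewness(-0.5)
        assert a < 0
        assert sc.skewness_from_alpha(a) == pytest.approx(-0.5, abs=1e-8)

    def test_out_of_range_error_names_bound(self):
        with pytest.raises(DataError, match="0.995"):
            sc.alpha_from_skewness(0.9953)

    @given(st.floats(-0.99, 0.99))
    @settings(derandomize=True, max_examples=60)
    def test_round_trip(self, g):
        assert sc.skewness_from_alpha(sc.alpha_from_skewness(g)) == pytest.approx(
            g, abs=1e-8
        )


class TestSampling:
    def test_reproducible(self):
        p = SkewNormalParams(0, 1, 3, "centered")
        assert np.array_equal(sc.sample(p, 100, seed=7), sc.sample(p, 100, seed=7))

    def test_symmetric_sample_skewness(self):
        x = sc.sample(SkewNormalParams(0, 1, 0, "centered"), 100_000, seed=1)
        assert abs(sc.fisher_skewness(x)) < 3 * math.sqrt(6 / 100_000)

    def test_moments_match_centered_parameters(self):
        # 4-MC-SE tolerance on mean, SD and skewness at alpha = 5
        n = 100_000
        p = SkewNormalParams(0.0, 1.0, 5.0, "centered")
        x = sc.sample(p, n, seed=3)
        g1 = sc.skewness_from_alpha(5.0)
        assert g1 == pytest.approx(0.851, abs=2e-3)
        assert x.mean() == pytest.approx(0.0, abs=4 / math.sqrt(n))
        assert x.std() == pytest.approx(1.0, abs=4 / math.sqrt(2 * n))
        assert sc.fisher_skewness(x) == pytest.approx(g1, abs=4 * math.sqrt(6 / n))

    def test_rejects_empty(self):
        with pytest.raises(DataError):
            sc.sample(SkewNormalParams(0, 1, 1, "centered"), 0, seed=0)
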