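import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from orientpool import (
    OrientationDistribution,
    SkewedGaussianSpec,
    SkewedUniformSpec,
    build_skewed_gaussian,
    build_skewed_uniform,
    distribution_stats,
)


def half_gaussian_oracle(sigma, interval, truncation):
    """Independent construction of one normalized half via scipy.stats.norm."""
    x = np.arange(0.0, truncation + 1e-9, interval)
    if sigma == 0:
        w = (x == 0).astype(float)
    else:
        w = norm.pdf(x, scale=sigma) / norm.pdf(0, scale=sigma)
    return x, w / w.sum()


class TestSkewedGaussian:
    def test_symmetric_spec_gives_symmetric_distribution(self):
        spec = SkewedGaussianSpec(sigma_ccw=15, sigma_cw=15)
        d = build_skewed_gaussian(spec)
        stats = distribution_stats(d)
        np.testing.assert_allclose(stats, (0.0, 0.0, 0.0), atol=1e-12)
        np.testing.assert_allclose(d.mass, d.mass[::-1])

    def test_one_sided_distribution_mean(self):
        # sigma_cw = 0 with density-matched halves: all mass on the CCW grid
        d = build_skewed_gaussian(SkewedGaussianSpec(sigma_ccw=30, sigma_cw=0))
        x, w = half_gaussian_oracle(30, 2.5, 45)
        expected_mean = -(x * w).sum()
        assert d.support.max() == 0.0
        assert np.isclose(distribution_stats(d).mean, expected_mean, atol=1e-9)
        assert np.isclose(expected_mean, -18.27, atol=0.01)  # frozen oracle value

    def test_density_matched_half_masses_proportional_to_sds(self):
        d = build_skewed_gaussian(SkewedGaussianSpec(sigma_ccw=20, sigma_cw=10))
        _, w_ccw = half_gaussian_oracle(20, 2.5, 45)
        ccw_total = d.mass[d.support < 0].sum() + (2 / 3) * w_ccw[0]
        assert np.isclose(ccw_total, 2 / 3, atol=1e-12)

    def test_density_matched_equals_equal_mass_when_sds_match(self):
        kw = dict(sigma_ccw=12.5, sigma_cw=12.5, interval_ccw=2.5, interval_cw=2.5)
        a = build_skewed_gaussian(SkewedGaussianSpec(**kw, half_weighting="density-matched"))
        b = build_skewed_gaussian(SkewedGaussianSpec(**kw, half_weighting="equal-mass"))
        np.testing.assert_allclose(a.mass, b.mass, atol=1e-15)

    def test_matches_scipy_norm_oracle(self):
        spec = SkewedGaussianSpec(sigma_ccw=25, sigma_cw=5)
        d = build_skewed_gaussian(spec)
        x_ccw, w_ccw = half_gaussian_oracle(25, 2.5, 45)
        x_cw, w_cw = half_gaussian_oracle(5, 2.5, 45)
        expected = {}
        for xx, ww in zip(-x_ccw, (25 / 30) * w_ccw):
            expected[xx + 0.0] = expected.get(xx + 0.0, 0.0) + ww
        for xx, ww in zip(x_cw, (5 / 30) * w_cw):
            expected[xx + 0.0] = expected.get(xx + 0.0, 0.0) + ww
        sup = np.array(sorted(expected))
        np.testing.assert_allclose(d.support, sup)
        np.testing.assert_allclose(d.mass, [expected[s] for s in sup], atol=1e-12)

    def test_rejects_invalid_specs(self):
        with pytest.raises(ValueError):
            SkewedGaussianSpec(sigma_ccw=0, sigma_cw=0, half_weighting="equal-mass")
        with pytest.raises(ValueError):
            SkewedGaussianSpec(sigma_ccw=10, sigma_cw=10, interval_ccw=50, truncation_ccw=45)
        with pytest.raises(ValueError):
            SkewedGaussianSpec(sigma_ccw=-1, sigma_cw=10)


class TestSkewedUniform:
    def test_symmetric_ranges(self):
        d = build_skewed_uniform(SkewedUniformSpec(range_ccw=45, range_cw=45))
        stats = distribution_stats(d)
        assert stats.mean == pytest.approx(0.0, abs=1e-12)
        assert stats.median == 0.0

    @pytest.mark.parametrize("r_ccw,r_cw", [(75, 15), (65, 25), (55, 35), (45, 45)])
    def test_mean_and_median(self, r_ccw, r_cw):
        # uniform halves on +/-2.5-deg grids: mean = (r_cw - r_ccw) / 4, median = 0
        d = build_skewed_uniform(SkewedUniformSpec(range_ccw=r_ccw, range_cw=r_cw))
        stats = distribution_stats(d)
        assert np.isclose(stats.mean, (r_cw - r_ccw) / 4.0, atol=1e-9)
        assert stats.median == 0.0

    def test_junction_excluded_equal_mass_halves(self):
        d = build_skewed_uniform(SkewedUniformSpec(range_ccw=75, range_cw=15))
        assert 0.0 not in d.support
        assert np.isclose(d.mass[d.support < 0].sum(), 0.5, atol=1e-12)

    def test_rejects_interval_larger_than_range(self):
        with pytest.raises(ValueError):
            SkewedUniformSpec(range_ccw=75, range_cw=2, interval=2.5)


class TestDistributionStats:
    def test_experiment2_condition_same_mode_median_different_mean(self):
        spec = SkewedGaussianSpec(
            sigma_ccw=18, sigma_cw=45, interval_ccw=2.5, interval_cw=0.5,
            truncation_ccw=90, truncation_cw=90, half_weighting="equal-mass",
        )
        stats = distribution_stats(build_skewed_gaussian(spec))
        assert stats.mode == 0.0
        assert stats.median == 0.0
        # oracle: half means of the discrete half-Gaussians, equal-mass weighted
        x_cw, w_cw = half_gaussian_oracle(45, 0.5, 90)
        x_ccw, w_ccw = half_gaussian_oracle(18, 2.5, 90)
        expected = 0.5 * (x_cw * w_cw).sum() - 0.5 * (x_ccw * w_ccw).sum()
        assert np.isclose(stats.mean, expected, atol=0.05)  # junction shared between halves
        assert np.isclose(stats.mean, 10.0, atol=1.0)

    def test_mode_tie_broken_toward_zero(self):
        d = OrientationDistribution([-20.0, 5.0, 30.0], [0.4, 0.4, 0.2])
        assert distribution_stats(d).mode == 5.0


@st.composite
def random_distributions(draw):
    n = draw(st.integers(min_value=2, max_value=12))
    support = np.sort(draw(st.lists(
        st.floats(min_value=-89.0, max_value=89.0), min_size=n, max_size=n, unique=True
    )))
    raw = np.array(draw(st.lists(
        st.floats(min_value=0.01, max_value=1.0), min_size=n, max_size=n
    )))
    return OrientationDistribution(support, raw / raw.sum())


@settings(derandomize=True, max_examples=100, deadline=None)
@given(random_distributions())
def test_mirror_negates_stats(dist):
    s = distribution_stats(dist)
    m = distribution_stats(dist.mirrored())
    assert np.isclose(m.mean, -s.mean, atol=1e-9)
    assert np.isclose(m.mode, -s.mode, atol=1e-9)
    # median midpoint rule keeps mirror symmetry away from exact 0.5 ties
    cum = np.cumsum(dist.mass)
    if not np.any(np.abs(cum - 0.5) < 1e-9):
        assert np.isclose(m.median, -s.median, atol=1e-9)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    st.floats(min_value=0.5, max_value=60), st.floats(min_value=0.5, max_value=60),
    st.sampled_from(["density-matched", "equal-mass"]),
)
def test_built_masses_sum_to_one(sigma_ccw, sigma_cw, weighting):
    d = build_skewed_gaussian(
        SkewedGaussianSpec(sigma_ccw=sigma_ccw, sigma_cw=sigma_cw, half_weighting=weighting)
    )
    assert abs(d.mass.sum() - 1.0) < 1e-9
    assert np.all(d.mass >= 0)


def test_serialization_roundtrip():
    d = build_skewed_uniform(SkewedUniformSpec(range_ccw=75, range_cw=15), reference=92.5)
    d2 = OrientationDistribution.from_json(d.to_json())
    np.testing.assert_allclose(d2.support, d.support)
    np.testing.assert_allclose(d2.mass, d.mass)
    assert d2.reference == d.reference


def test_validation_rejects_bad_distributions():
    with pytest.raises(ValueError):
        OrientationDistribution([0.0, 1.0], [0.6, 0.6])  # mass sum != 1
    with pytest.raises(ValueError):
        OrientationDistribution([1.0, 0.0], [0.5, 0.5])  # not increasing
    with pytest.raises(ValueError):
        OrientationDistribution([-95.0, 0.0], [0.5, 0.5])  # outside (-90, 90]
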