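"""Exact trapezoidal treatment-effect distribution vs independent oracles.

The closed-form pdf/cdf are checked against scipy's trapezoidal
distribution (an independent parameterization of the same law) and
against brute-force Monte-Carlo sampling; the discrete variant is
checked against exhaustive enumeration of all grid-point pairs.
"""

import numpy as np
import pytest
from scipy import integrate, stats

from painintervals import (
    DifferenceDistribution,
    PainInterval,
    difference_cdf,
    difference_mean,
    difference_pdf,
    difference_support,
    discrete_difference_pmf,
    sample_difference,
)
from painintervals.interval_model import PointMassError

from conftest import random_interval


def scipy_trapezoid(dist: DifferenceDistribution):
    """Independent oracle: scipy's trapezoidal law on the same geometry."""
    scale = dist.support_max - dist.support_min
    return stats.trapezoid(
        (dist.plateau_lo - dist.support_min) / scale,
        (dist.plateau_hi - dist.support_min) / scale,
        loc=dist.support_min,
        scale=scale,
    )


class TestSupportAndMean:
    def test_worked_example_support(self, patient3_intervals):
        """Smallest change 0.1 (lowest post vs highest pre), largest 3.1."""
        lo, hi = difference_support(*patient3_intervals)
        assert lo == pytest.approx(0.1)
        assert hi == pytest.approx(3.1)

    def test_point_estimate_limit(self):
        lo, hi = difference_support(PainInterval(7.2, 7.2), PainInterval(3.6, 3.6))
        assert lo == hi == pytest.approx(-3.6)

    def test_mean_is_midpoint_difference(self, patient3_intervals):
        assert difference_mean(*patient3_intervals) == pytest.approx(1.6)
        # Patient 1's full intervals
        assert difference_mean(
            PainInterval(5.8, 7.3), PainInterval(3.3, 5.4)
        ) == pytest.approx(-2.2)

    def test_mean_matches_density_quadrature(self, patient3_intervals):
        dist = DifferenceDistribution.from_intervals(*patient3_intervals)
        quad_mean, _ = integrate.quad(
            lambda x: x * dist.pdf(x), dist.support_min, dist.support_max
        )
        assert quad_mean == pytest.approx(difference_mean(*patient3_intervals), abs=1e-9)


class TestDensity:
    def test_zero_outside_and_at_support_endpoints(self, patient3_intervals):
        dist = DifferenceDistribution.from_intervals(*patient3_intervals)
        assert difference_pdf(dist, dist.support_min) == 0.0
        assert difference_pdf(dist, dist.support_max) == 0.0
        assert difference_pdf(dist, dist.support_min - 0.5) == 0.0
        assert difference_pdf(dist, dist.support_max + 0.5) == 0.0

    def test_plateau_height_unequal_widths(self, patient3_intervals):
        """Widths 1.6 and 1.4 give a trapezoid with plateau 1/1.6 = 0.625."""
        dist = DifferenceDistribution.from_intervals(*patient3_intervals)
        assert dist.plateau_hi - dist.plateau_lo == pytest.approx(0.2)
        for x in np.linspace(dist.plateau_lo, dist.plateau_hi, 5):
            assert difference_pdf(dist, x) == pytest.approx(0.625)

    def test_normalization(self, patient3_intervals):
        dist = DifferenceDistribution.from_intervals(*patient3_intervals)
        total, _ = integrate.quad(dist.pdf, dist.support_min, dist.support_max)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_one_zero_width_gives_rectangle(self):
        dist = DifferenceDistribution.from_intervals(
            PainInterval(5.0, 5.0), PainInterval(2.0, 4.0)
        )
        assert difference_pdf(dist, -2.0) == pytest.approx(0.5)
        total, _ = integrate.quad(dist.pdf, dist.support_min, dist.support_max)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_point_mass_raises(self):
        dist = DifferenceDistribution.from_intervals(
            PainInterval(7.2, 7.2), PainInterval(3.6, 3.6)
        )
        assert dist.is_point_mass
        with pytest.raises(PointMassError, match="point"):
            difference_pdf(dist, 0.0)
        with pytest.raises(PointMassError):
            difference_cdf(dist, 0.0)

    def test_matches_scipy_trapezoid_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            pre, post = random_interval(rng), random_interval(rng)
            if pre.width == 0 and post.width == 0:
                continue
            dist = DifferenceDistribution.from_intervals(pre, post)
            oracle = scipy_trapezoid(dist)
            xs = np.linspace(dist.support_min - 1, dist.support_max + 1, 101)
            np.testing.assert_allclose(dist.pdf(xs), oracle.pdf(xs), atol=1e-10)
            np.testing.assert_allclose(dist.cdf(xs), oracle.cdf(xs), atol=1e-10)


class TestCDF:
    def test_boundary_values(self, patient3_intervals):
        dist = DifferenceDistribution.from_intervals(*patient3_intervals)
        assert difference_cdf(dist, dist.support_min) == 0.0
        assert difference_cdf(dist, dist.support_max) == 1.0

    def test_symmetric_triangle_median_at_zero(self):
        dist = DifferenceDistribution.from_intervals(
            PainInterval(0, 3), PainInterval(0, 3)
        )
        # equal widths: isosceles triangle centred at 0
        assert dist.plateau_lo == dist.plateau_hi == pytest.approx(0.0)
        assert difference_cdf(dist, 0.0) == pytest.approx(0.5)

    def test_monotone_nondecreasing(self, patient3_intervals):
        dist = DifferenceDistribution.from_intervals(*patient3_intervals)
        xs = np.linspace(dist.support_min - 1, dist.support_max + 1, 500)
        assert np.all(np.diff(dist.cdf(xs)) >= -1e-15)

    def test_matches_monte_carlo_empirical_cdf(self, patient3_intervals):
        dist = DifferenceDistribution.from_intervals(*patient3_intervals)
        rng = np.random.default_rng(7)
        draws = sample_difference(*patient3_intervals, n=200_000, rng=rng)
        stat = stats.kstest(draws, dist.cdf).statistic
        assert stat < 2e-3 * np.sqrt(1e6 / 200_000)  # scaled MC tolerance


class TestSampler:
    def test_point_intervals_draw_exactly_the_difference(self, patient1_points):
        rng = np.random.default_rng(0)
        draws = sample_difference(*patient1_points, n=100, rng=rng)
        np.testing.assert_allclose(draws, -3.6)

    def test_draws_within_support(self, patient3_intervals):
        rng = np.random.default_rng(1)
        draws = sample_difference(*patient3_intervals, n=10_000, rng=rng)
        lo, hi = difference_support(*patient3_intervals)
        assert draws.min() >= lo and draws.max() <= hi

    def test_seeded_determinism(self, patient3_intervals):
        a = sample_difference(*patient3_intervals, n=50, rng=np.random.default_rng(99))
        b = sample_difference(*patient3_intervals, n=50, rng=np.random.default_rng(99))
        np.testing.assert_array_equal(a, b)

    def test_rejects_nonpositive_n(self, patient3_intervals):
        with pytest.raises(ValueError, match="n must be"):
            sample_difference(*patient3_intervals, n=0, rng=np.random.default_rng(0))

    def test_degenerate_width_limit_concentrates_on_mean(self):
        """As widths shrink to zero the draws collapse to the mean effect."""
        rng = np.random.default_rng(3)
        for eps in (1e-3, 1e-6):
            pre = PainInterval(6.0 - eps, 6.0 + eps)
            post = PainInterval(4.0 - eps, 4.0 + eps)
            draws = sample_difference(pre, post, n=1000, rng=rng)
            assert np.max(np.abs(draws - (-2.0))) <= 2 * eps


class TestDiscretePMF:
    def test_point_masses(self):
        pmf = discrete_difference_pmf(PainInterval(3, 3), PainInterval(5, 5))
        assert pmf == {2.0: 1.0}

    def test_two_by_two_enumeration(self):
        pmf = discrete_difference_pmf(PainInterval(2, 3), PainInterval(4, 5))
        assert pmf == pytest.approx({1.0: 0.25, 2.0: 0.5, 3.0: 0.25})

    def test_symmetry_and_normalization(self):
        pmf = discrete_difference_pmf(PainInterval(0, 2), PainInterval(0, 2))
        assert sum(pmf.values()) == pytest.approx(1.0, abs=1e-12)
        for v, p in pmf.items():
            assert pmf[-v] == pytest.approx(p)

    def test_off_grid_bounds_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            discrete_difference_pmf(PainInterval(2.5, 3.5), PainInterval(4, 5))

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_enumeration_oracle(self, seed):
        """PMF equals direct enumeration over all grid-point pairs."""
        rng = np.random.default_rng(seed)
        step = rng.choice([0.5, 1.0])
        pre_lo = rng.integers(0, 8) * step
        pre_hi = pre_lo + rng.integers(0, 4) * step
        post_lo = rng.integers(0, 8) * step
        post_hi = post_lo + rng.integers(0, 4) * step
        pre, post = PainInterval(pre_lo, pre_hi), PainInterval(post_lo, post_hi)
        pmf = discrete_difference_pmf(pre, post, step=step)
        pre_grid = np.arange(pre.lower, pre.upper + step / 2, step)
        post_grid = np.arange(post.lower, post.upper + step / 2, step)
        expected = {}
        for a in post_grid:
            for b in pre_grid:
                key = round((a - b) / step) * step
                expected[key] = expected.get(key, 0.0) + 1.0 / (
                    len(pre_grid) * len(post_grid)
                )
        assert set(pmf) == set(expected)
        for k in expected:
            assert pmf[k] == pytest.approx(expected[k], abs=1e-12)
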