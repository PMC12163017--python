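"""Exact distribution of one patient's treatment effect.

When a patient's pre- and post-intervention pain intensities are
modelled as independent uniform random variables on their stated
uncertainty intervals, the treatment effect ``post - pre`` follows the
convolution of the two uniforms: a trapezoidal density supported on

    [post.lower - pre.upper,  post.upper - pre.lower]

with linear ramps of width ``min(pre_width, post_width)`` at both ends
and a flat plateau of height ``1 / max(pre_width, post_width)`` in
between.  Equal widths collapse the plateau to a point (the isosceles
triangle); one zero width gives a rectangle; two zero widths give a
point mass at the difference of the point estimates, which is handled
separately because it has no density.

All closed forms here are elementary; they are implemented directly so
that the Monte-Carlo sampler and the analytic model can cross-validate
each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort_io import PainInterval

__all__ = [
    "DifferenceDistribution",
    "difference_support",
    "difference_mean",
    "difference_pdf",
    "difference_cdf",
    "sample_difference",
    "discrete_difference_pmf",
]


class PointMassError(ValueError):
    """Raised when a density is requested for two zero-width intervals.

    The difference of two point estimates is a deterministic number
    (``post - pre``); use :func:`difference_mean` or compare supports
    instead of pdf/cdf machinery.
    """


@dataclass(frozen=True)
class DifferenceDistribution:
    """Trapezoidal law of (post - pre) for independent uniform intervals."""

    support_min: float
    support_max: float
    plateau_lo: float
    plateau_hi: float
    pre_width: float
    post_width: float

    @classmethod
    def from_intervals(
        cls, pre: PainInterval, post: PainInterval
    ) -> "DifferenceDistribution":
        lo, hi = difference_support(pre, post)
        ramp = min(pre.width, post.width)
        return cls(
            support_min=lo,
            support_max=hi,
            plateau_lo=lo + ramp,
            plateau_hi=hi - ramp,
            pre_width=pre.width,
            post_width=post.width,
        )

    @property
    def is_point_mass(self) -> bool:
        return self.pre_width == 0.0 and self.post_width == 0.0

    @property
    def mean(self) -> float:
        return 0.5 * (self.support_min + self.support_max)

    @property
    def plateau_height(self) -> float:
        if self.is_point_mass:
            raise PointMassError(
                "both intervals have zero width: the effect is the point "
                f"{self.mean}; no density exists"
            )
        return 1.0 / max(self.pre_width, self.post_width)

    def pdf(self, x):
        """Piecewise-linear trapezoid density (per NPS unit), vectorized."""
        h = self.plateau_height
        x = np.asarray(x, dtype=float)
        ramp = min(self.pre_width, self.post_width)
        out = np.zeros_like(x)
        inside = (x >= self.support_min) & (x <= self.support_max)
        if ramp > 0.0:
            slope = h / ramp
            rising = inside & (x < self.plateau_lo)
            falling = inside & (x > self.plateau_hi)
            flat = inside & ~rising & ~falling
            out[rising] = slope * (x[rising] - self.support_min)
            out[falling] = slope * (self.support_max - x[falling])
            out[flat] = h
        else:
            out[inside] = h
        return out if out.ndim else float(out)

    def cdf(self, x):
        """Exact integral of :meth:`pdf`; 0 below the support, 1 above."""
        h = self.plateau_height
        x = np.asarray(x, dtype=float)
        ramp = min(self.pre_width, self.post_width)
        out = np.zeros_like(x)
        out[x >= self.support_max] = 1.0
        inside = (x > self.support_min) & (x < self.support_max)
        if ramp > 0.0:
            slope = h / ramp
            rising = inside & (x <= self.plateau_lo)
            flat = inside & (x > self.plateau_lo) & (x <= self.plateau_hi)
            falling = inside & (x > self.plateau_hi)
            out[rising] = 0.5 * slope * (x[rising] - self.support_min) ** 2
            out[flat] = 0.5 * h * ramp + h * (x[flat] - self.plateau_lo)
            out[falling] = 1.0 - 0.5 * slope * (self.support_max - x[falling]) ** 2
        else:
            out[inside] = h * (x[inside] - self.support_min)
        return out if out.ndim else float(out)


def difference_support(pre: PainInterval, post: PainInterval) -> tuple[float, float]:
    """Range of possible treatment effects: extreme post minus extreme pre.

    The smallest possible change pairs the lowest post level with the
    highest pre level; the largest pairs the highest post level with the
    lowest pre level.
    """
    return (post.lower - pre.upper, post.upper - pre.lower)


def difference_mean(pre: PainInterval, post: PainInterval) -> float:
    """Expected treatment effect: midpoint(post) - midpoint(pre)."""
    return post.midpoint - pre.midpoint


def difference_pdf(dist: DifferenceDistribution, x):
    """Density of the treatment effect at ``x`` (scalar or array)."""
    return dist.pdf(x)


def difference_cdf(dist: DifferenceDistribution, x):
    """P(effect <= x) in closed form (scalar or array)."""
    return dist.cdf(x)


def sample_difference(
    pre: PainInterval, post: PainInterval, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` independent treatment effects (post draw minus pre draw).

    The post value is drawn before the pre value, matching the estimation
    procedure's documented draw order, so a fixed generator state yields
    a fixed sequence.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    post_draws = rng.uniform(post.lower, post.upper, size=n)
    pre_draws = rng.uniform(pre.lower, pre.upper, size=n)
    return post_draws - pre_draws


def discrete_difference_pmf(
    pre: PainInterval, post: PainInterval, step: float = 1.0
) -> dict[float, float]:
    """PMF of (post - pre) for discrete-uniform intervals on a grid.

    Adaptation of the continuous model to the discrete NRS: each
    interval places equal mass on the grid points it contains (step 1
    for the integer 0-10 NRS).  Bounds must lie on the step grid.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")

    def grid_count(interval: PainInterval, name: str) -> int:
        for bound in (interval.lower, interval.upper):
            k = bound / step
            if abs(k - round(k)) > 1e-9:
                raise ValueError(
                    f"{name} bound {bound} does not lie on the step-{step} grid"
                )
        return int(round(interval.width / step)) + 1

    n_pre = grid_count(pre, "pre")
    n_post = grid_count(post, "post")
    pmf: dict[float, float] = {}
    base = post.lower - pre.upper
    p = 1.0 / (n_pre * n_post)
    # value base + k*step is hit by min(k+1, n_pre, n_post, n_pre+n_post-1-k) pairs
    for k in range(n_pre + n_post - 1):
        count = min(k + 1, n_pre, n_post, n_pre + n_post - 1 - k)
        value = base + k * step
        pmf[round(value / step) * step if step != 1.0 else float(round(value))] = (
            count * p
        )
    return pmf
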