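"""Sensitivity analyses: sample-size sweep and interval-width shrink.

Two stress tests of the nested-bootstrap ATE estimator:

* **Sample-size sweep** — regenerate the proof-of-concept cohort at a
  range of sizes (5 to 1000 patients by default) with all other
  generator parameters fixed, and estimate the ATE at each size.  Small
  cohorts track their own sample ATE; large cohorts recover the
  population effect.

* **Width sweep** — fix one cohort and shrink every uncertainty interval
  about its midpoint by a fraction (100% of the reported width down to
  0%).  At 0% the data degenerate to traditional point estimates and the
  estimator is benchmarked against the paired Wilcoxon signed-rank
  procedure: the Hodges-Lehmann pseudomedian of the paired midpoint
  differences and its distribution-based confidence interval.

Sweep results are plain pandas DataFrames with one row per sweep point
(columns: sweep_value, mean_ate, ci_lower, ci_upper and, where a
benchmark applies, benchmark_estimate / benchmark_ci_lower /
benchmark_ci_upper), directly exportable as CSV.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ate_bootstrap import estimate_ate
from .cohort_io import Cohort, PainInterval, PatientRecord
from .simulate import SimulationConfig, simulate_cohort

__all__ = [
    "SWEEP_COLUMNS",
    "DEFAULT_SIZE_GRID",
    "DEFAULT_WIDTH_FRACTIONS",
    "shrink_widths",
    "wilcoxon_benchmark",
    "sample_size_sweep",
    "width_sweep",
    "plot_sweep",
]

SWEEP_COLUMNS = [
    "sweep_value",
    "mean_ate",
    "ci_lower",
    "ci_upper",
    "benchmark_estimate",
    "benchmark_ci_lower",
    "benchmark_ci_upper",
]

DEFAULT_SIZE_GRID: tuple[int, ...] = (5, 10, 20, 50, 100, 200, 500, 1000)
# 100% of the reported width down to the point-estimate limit, 10% steps
DEFAULT_WIDTH_FRACTIONS: tuple[float, ...] = tuple(
    round(f, 1) for f in np.arange(1.0, -0.05, -0.1)
)


def shrink_widths(cohort: Cohort, fraction: float) -> Cohort:
    """Scale every interval about its midpoint: midpoint +/- fraction*width/2.

    fraction 1 is the identity, fraction 0 collapses all intervals to
    their midpoints (the traditional point-estimate assessment).
    Midpoints — and hence the sample ATE — are preserved exactly.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if fraction == 1.0:
        return cohort

    def scaled(interval: PainInterval) -> PainInterval:
        mid = interval.midpoint
        half = fraction * interval.width / 2.0
        return PainInterval(mid - half, mid + half)

    records = tuple(
        PatientRecord(r.patient_id, scaled(r.pre), scaled(r.post))
        for r in cohort.records
    )
    return Cohort(records, cohort.scale_min, cohort.scale_max)


def _signrank_quantile(p: float, n: int) -> int:
    """Smallest q with P(W <= q) >= p for the signed-rank statistic W.

    Exact null distribution by dynamic programming (W = sum of a random
    subset of ranks 1..n) for n <= 25; Normal approximation with the
    standard signed-rank moments beyond.
    """
    m_total = n * (n + 1) // 2
    if n <= 25:
        counts = np.zeros(m_total + 1)
        counts[0] = 1.0
        for r in range(1, n + 1):
            counts[r:] += counts[: m_total + 1 - r]
        cdf = np.cumsum(counts) / 2.0**n
        return int(np.searchsorted(cdf, p - 1e-12))
    mu = n * (n + 1) / 4.0
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    return max(0, int(math.floor(mu + stats.norm.ppf(p) * sigma)))


def wilcoxon_benchmark(
    cohort: Cohort, ci_level: float = 0.95
) -> tuple[float, float, float]:
    """Paired Wilcoxon signed-rank benchmark on the midpoint differences.

    Returns the Hodges-Lehmann pseudomedian (median of all N(N+1)/2
    pairwise Walsh averages of the within-patient differences) and its
    signed-rank-distribution confidence interval — the location estimate
    and interval a standard paired Wilcoxon procedure reports.
    """
    n = len(cohort)
    if n < 2:
        raise ValueError("the Wilcoxon benchmark requires at least 2 patients")
    diffs = cohort.post_midpoints - cohort.pre_midpoints
    i, j = np.triu_indices(n)
    walsh = np.sort((diffs[i] + diffs[j]) / 2.0)
    estimate = float(np.median(walsh))
    if np.ptp(diffs) == 0.0:
        warnings.warn(
            "all paired differences identical: degenerate confidence interval",
            stacklevel=2,
        )
        return estimate, estimate, estimate
    alpha = 1.0 - ci_level
    qu = _signrank_quantile(alpha / 2.0, n)
    qu = max(qu, 1)
    m_total = walsh.size
    return estimate, float(walsh[qu - 1]), float(walsh[m_total - qu])


def _spawn_seeds(seed: int, k: int) -> list[int]:
    """Independent 31-bit sub-seeds, one per sweep point, from one master."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(k)]


def sample_size_sweep(
    config: SimulationConfig,
    n_values: Sequence[int] = DEFAULT_SIZE_GRID,
    *,
    seed: int,
    b_outer: int = 100,
    b_inner: int = 100,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Estimate the ATE on freshly simulated cohorts of each size.

    All generator parameters except the cohort size are taken from
    ``config``; each sweep point uses an independent sub-seed derived
    from ``seed`` for both simulation and estimation.
    """
    n_values = list(n_values)
    if not n_values:
        raise ValueError("n_values must be non-empty")
    if any(n < 2 for n in n_values):
        raise ValueError(f"every sweep size must be >= 2, got {n_values}")
    if any(b >= a for a, b in zip(n_values, n_values[1:])) and any(
        b <= a for a, b in zip(n_values, n_values[1:])
    ):
        raise ValueError(f"n_values must be strictly monotone, got {n_values}")
    seeds = _spawn_seeds(seed, 2 * len(n_values))
    rows = []
    for k, n in enumerate(n_values):
        cohort = simulate_cohort(replace(config, n_patients=n, seed=seeds[2 * k]))
        est = estimate_ate(
            cohort, b_outer, b_inner, ci_level, seed=seeds[2 * k + 1]
        )
        rows.append(
            {
                "sweep_value": n,
                "mean_ate": est.mean_ate,
                "ci_lower": est.ci_lower,
                "ci_upper": est.ci_upper,
                "benchmark_estimate": np.nan,
                "benchmark_ci_lower": np.nan,
                "benchmark_ci_upper": np.nan,
            }
        )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def width_sweep(
    cohort: Cohort,
    fractions: Sequence[float] = DEFAULT_WIDTH_FRACTIONS,
    *,
    seed: int,
    b_outer: int = 100,
    b_inner: int = 100,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Estimate the ATE on one fixed cohort at each interval-width fraction.

    The cohort is shrunk, never regenerated, so the sweep isolates the
    effect of measurement uncertainty.  At fraction 0 the paired
    Wilcoxon benchmark columns are filled.
    """
    fractions = list(fractions)
    if not fractions:
        raise ValueError("fractions must be non-empty")
    if any(not 0.0 <= f <= 1.0 for f in fractions):
        raise ValueError(f"fractions must lie in [0, 1], got {fractions}")
    seeds = _spawn_seeds(seed, len(fractions))
    rows = []
    for k, fraction in enumerate(fractions):
        shrunk = shrink_widths(cohort, fraction)
        est = estimate_ate(shrunk, b_outer, b_inner, ci_level, seed=seeds[k])
        row = {
            "sweep_value": fraction,
            "mean_ate": est.mean_ate,
            "ci_lower": est.ci_lower,
            "ci_upper": est.ci_upper,
            "benchmark_estimate": np.nan,
            "benchmark_ci_lower": np.nan,
            "benchmark_ci_upper": np.nan,
        }
        if fraction == 0.0 and len(cohort) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bench, blo, bhi = wilcoxon_benchmark(shrunk, ci_level)
            row.update(
                benchmark_estimate=bench,
                benchmark_ci_lower=blo,
                benchmark_ci_upper=bhi,
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def plot_sweep(result: pd.DataFrame, path, *, log_x: bool = False) -> None:
    """Point-and-ribbon plot of a sweep (mean ATE with CI band).

    Benchmark rows, if present, are overlaid as open markers with error
    bars.  Writes a standard image file; purely a convenience helper.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    x = result["sweep_value"].to_numpy(dtype=float)
    ax.fill_between(x, result["ci_lower"], result["ci_upper"], alpha=0.3, label="95% CI")
    ax.plot(x, result["mean_ate"], "o-", label="mean ATE")
    bench = result.dropna(subset=["benchmark_estimate"])
    if not bench.empty:
        ax.errorbar(
            bench["sweep_value"],
            bench["benchmark_estimate"],
            yerr=[
                bench["benchmark_estimate"] - bench["benchmark_ci_lower"],
                bench["benchmark_ci_upper"] - bench["benchmark_estimate"],
            ],
            fmt="s",
            mfc="none",
            capsize=3,
            label="Wilcoxon benchmark",
        )
    if log_x:
        ax.set_xscale("log")
    ax.set_xlabel("sweep value")
    ax.set_ylabel("ATE (NPS units)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
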