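"""Statistical layer: extrapolation, interval estimates, odds ratios.

Sample counts extrapolate to national per-100,000 rates through the design
factor ``100,000 × population_share / sample_size``: the study sample holds
``sample_size`` qualifying patients who represent ``population_share`` of
the national population with at least one qualifying prescription.

Proportions get Wilson score intervals; medians come with interquartile
ranges; 2×2 tables yield crude odds ratios with Woolf (log) intervals.
The multinomial logistic model of OCS exposure lives in
:mod:`rxrisk.association`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class ExtrapolationFactor:
    """Sample-to-population design factor.

    Defaults are the study design values: 82,714 sampled patients
    representing 45% of the national population with qualifying
    prescriptions.
    """

    sample_size: int = 82_714
    population_share: float = 0.45

    def __post_init__(self) -> None:
        if self.sample_size <= 0:
            raise ValueError("sample_size must be positive")
        if not (0 < self.population_share <= 1):
            raise ValueError("population_share must be in (0, 1]")

    @property
    def per_patient(self) -> float:
        return 100_000.0 * self.population_share / self.sample_size


def rate_per_100k(count: float, factor: ExtrapolationFactor = ExtrapolationFactor()) -> float:
    """Extrapolate a sample count to a national rate per 100,000 patients."""
    if not (0 <= count <= factor.sample_size):
        raise ValueError(
            f"count must be within [0, {factor.sample_size}], got {count}"
        )
    return count * factor.per_patient


def invert_rate(rate: float, factor: ExtrapolationFactor = ExtrapolationFactor()) -> int:
    """Nearest sample count producing a given per-100,000 rate.

    Exact inverse of :func:`rate_per_100k` on integer counts.
    """
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    return int(round(rate / factor.per_patient))


def wilson_ci(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, in percent.

    Symmetric under complement: ``ci(k, n) = 100 - reversed ci(n-k, n)``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= successes <= n):
        raise ValueError(f"successes must be within [0, {n}], got {successes}")
    lo, hi = proportion_confint(successes, n, alpha=1 - confidence, method="wilson")
    return 100.0 * lo, 100.0 * hi


def median_iqr(values) -> tuple[float, float, float]:
    """(median, 25th, 75th percentile) with linear interpolation."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr requires at least one value")
    med, p25, p75 = np.percentile(arr, [50, 25, 75])
    return float(med), float(p25), float(p75)


@dataclass(frozen=True)
class OddsRatio:
    """Crude odds ratio with a Woolf (log-scale) confidence interval."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool = False
    defined: bool = True


def crude_or(a: float, b: float, c: float, d: float, confidence: float = 0.95) -> OddsRatio:
    """Crude OR ``ad/bc`` from a 2×2 table with Woolf log CI.

    A 0.5 continuity correction is applied to every cell iff any cell is
    zero. When both cells of a row or column are zero the OR is undefined
    and the result is flagged (``defined=False``).
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("2x2 cells must be nonnegative")
    a_, b_, c_, d_ = cells
    if (a_ == 0 and b_ == 0) or (c_ == 0 and d_ == 0) or (a_ == 0 and c_ == 0) or (b_ == 0 and d_ == 0):
        return OddsRatio(np.nan, np.nan, np.nan, continuity_corrected=False, defined=False)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
        a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se = np.sqrt((1 / cells).sum())
    from scipy.stats import norm

    z = norm.ppf(0.5 + confidence / 2)
    lo, hi = np.exp(np.log(or_) - z * se), np.exp(np.log(or_) + z * se)
    return OddsRatio(float(or_), float(lo), float(hi), continuity_corrected=corrected)
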