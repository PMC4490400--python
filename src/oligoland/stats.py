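"""Exact mutation-frequency estimation and 2x2 categorical comparison.

Frequency confidence intervals are Clopper-Pearson exact (inversion of
the binomial tails via beta quantiles), the method that reproduces
published exact intervals such as 10/134 -> 3.6-13.3%. The 2x2 comparison
reports the closed-form chi-square statistic (optionally Yates-corrected)
and the two-sided Fisher exact p-value (point-probability convention).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import OligolandError


@dataclass(frozen=True)
class FrequencyEstimate:
    n_carriers: int
    n_total: int
    point: float
    ci_low: float
    ci_high: float
    level: float


def clopper_pearson_bounds(
    n_carriers: int, n_total: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact binomial CI bounds on the proportion scale.

    lower = Beta^-1(alpha/2; x, n-x+1), upper = Beta^-1(1-alpha/2; x+1, n-x),
    with the degenerate bounds exactly 0 at x=0 and 1 at x=n.
    """
    alpha = 1.0 - level
    x, n = n_carriers, n_total
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def frequency_with_ci(
    n_carriers: int, n_total: int, level: float = 0.95
) -> FrequencyEstimate:
    """Carrier-frequency point estimate with a Clopper-Pearson exact CI."""
    if n_total < 1:
        raise OligolandError("n_total must be >= 1")
    if not 0 <= n_carriers <= n_total:
        raise OligolandError(
            f"n_carriers {n_carriers} outside [0, {n_total}]"
        )
    if not 0 < level < 1:
        raise OligolandError("confidence level must be in (0, 1)")
    low, high = clopper_pearson_bounds(n_carriers, n_total, level)
    return FrequencyEstimate(
        n_carriers=n_carriers,
        n_total=n_total,
        point=n_carriers / n_total,
        ci_low=low,
        ci_high=high,
        level=level,
    )


@dataclass(frozen=True)
class TwoByTwoResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    chi2: float  # nan when a margin is zero
    p_chi2: float  # nan when chi2 undefined
    p_fisher: float
    continuity_corrected: bool


def two_by_two(
    a: int, b: int, c: int, d: int, correction: bool = False
) -> TwoByTwoResult:
    """Compare two proportions from the 2x2 table [[a, b], [c, d]].

    chi2 = N(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); the Yates variant
    replaces |ad - bc| by max(|ad - bc| - N/2, 0). A zero margin leaves
    chi2 undefined (nan); the Fisher exact two-sided p (sum of point
    probabilities <= the observed table's) is always computed.
    """
    if min(a, b, c, d) < 0:
        raise OligolandError("counts must be non-negative")
    N = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins) or N == 0:
        chi2 = p_chi2 = math.nan
    else:
        diff = abs(a * d - b * c)
        if correction:
            diff = max(diff - N / 2, 0.0)
        chi2 = N * diff**2 / math.prod(margins)
        p_chi2 = float(stats.chi2.sf(chi2, df=1))
    p_fisher = float(
        stats.fisher_exact(np.array([[a, b], [c, d]]), alternative="two-sided")[1]
    )
    return TwoByTwoResult(
        table=((a, b), (c, d)),
        chi2=chi2,
        p_chi2=p_chi2,
        p_fisher=min(p_fisher, 1.0),
        continuity_corrected=correction,
    )
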