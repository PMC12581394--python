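"""Confidence intervals for binomial proportions and paired differences.

The workhorse intervals of agreement studies: the Wilson score interval
(with and without continuity correction), the exact Clopper-Pearson
interval, and Newcombe's method 10 for the difference between two paired
proportions. All bounds are clipped to the unit interval; percentages are
a presentation concern handled elsewhere.
"""

from __future__ import annotations

import math

from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "proportion_ci",
    "wilson_ci",
    "wilson_cc_ci",
    "clopper_pearson_ci",
    "newcombe10_ci",
]

CI_METHODS = ("wilson", "clopper_pearson", "wilson_cc")


def _check_counts(successes: int, trials: int, level: float) -> None:
    if trials < 1:
        raise ValueError("trials must be >= 1 (undefined proportion for 0 trials)")
    if not 0 <= successes <= trials:
        raise ValueError(f"successes must be in [0, trials], got {successes}/{trials}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")


def wilson_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval without continuity correction.

    For ``successes == trials`` the lower limit is exactly
    ``n / (n + z**2)``, which reproduces the perfect-agreement bounds
    quoted in validation summary tables (14/14 -> 0.785, 4/4 -> 0.510).
    """
    _check_counts(successes, trials, level)
    low, high = proportion_confint(successes, trials, alpha=1 - level, method="wilson")
    # exact edges: statsmodels can return 1 - eps at x = n (and likewise at 0)
    low = 0.0 if successes == 0 else max(0.0, float(low))
    high = 1.0 if successes == trials else min(1.0, float(high))
    return low, high


def clopper_pearson_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial interval.

    Lower limit for ``successes == trials`` is ``(alpha/2) ** (1/n)``.
    """
    _check_counts(successes, trials, level)
    low, high = proportion_confint(successes, trials, alpha=1 - level, method="beta")
    # statsmodels returns NaN at the degenerate edges; the exact limits there
    # are 0 and 1 respectively.
    low = 0.0 if math.isnan(low) else float(low)
    high = 1.0 if math.isnan(high) else float(high)
    return max(0.0, low), min(1.0, high)


def wilson_cc_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval with continuity correction (Newcombe 1998, method 4)."""
    _check_counts(successes, trials, level)
    n = trials
    p = successes / n
    z = stats.norm.ppf(1 - (1 - level) / 2)
    z2 = z * z
    denom = 2 * (n + z2)
    if successes == 0:
        low = 0.0
    else:
        low = (2 * n * p + z2 - 1 - z * math.sqrt(z2 - 2 - 1 / n + 4 * p * (n * (1 - p) + 1))) / denom
    if successes == trials:
        high = 1.0
    else:
        high = (2 * n * p + z2 + 1 + z * math.sqrt(z2 + 2 - 1 / n + 4 * p * (n * (1 - p) - 1))) / denom
    return max(0.0, low), min(1.0, high)


_DISPATCH = {
    "wilson": wilson_ci,
    "clopper_pearson": clopper_pearson_ci,
    "wilson_cc": wilson_cc_ci,
}


def proportion_ci(
    successes: int, trials: int, method: str = "wilson", level: float = 0.95
) -> tuple[float, float]:
    """Two-sided CI for a binomial proportion by the named method."""
    try:
        fn = _DISPATCH[method]
    except KeyError:
        raise ValueError(f"unknown CI method {method!r}; expected one of {CI_METHODS}") from None
    return fn(successes, trials, level)


def newcombe10_ci(
    a: int, b: int, c: int, d: int, level: float = 0.95
) -> tuple[float, float, float]:
    """Difference between paired proportions, Newcombe (1998) method 10.

    The paired 2x2 table counts both-positive ``a``, first-only ``b``,
    second-only ``c`` and both-negative ``d`` discordances between two
    tests run on the same samples. The difference is
    ``p1 - p2 = (b - c) / n``. Method 10 combines continuity-corrected
    Wilson limits for each marginal proportion with a phi-corrected
    adjustment for the within-pair correlation.

    Returns ``(diff, low, high)``.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0:
            raise ValueError(f"count {name} must be non-negative")
    n = a + b + c + d
    if n < 2:
        raise ValueError("fewer than 2 paired observations")
    p1 = (a + b) / n
    p2 = (a + c) / n
    diff = p1 - p2

    l1, u1 = wilson_cc_ci(a + b, n, level)
    l2, u2 = wilson_cc_ci(a + c, n, level)

    # phi-hat with Newcombe's continuity correction on the covariance term;
    # set to 0 when any marginal vanishes.
    marg = (a + b) * (c + d) * (a + c) * (b + d)
    if marg == 0:
        phi = 0.0
    else:
        num = a * d - b * c
        if num > 0:
            num = max(num - n / 2, 0.0)
        phi = num / math.sqrt(marg)

    dl = math.sqrt(max(0.0, (p1 - l1) ** 2 - 2 * phi * (p1 - l1) * (u2 - p2) + (u2 - p2) ** 2))
    du = math.sqrt(max(0.0, (u1 - p1) ** 2 - 2 * phi * (u1 - p1) * (p2 - l2) + (p2 - l2) ** 2))
    low = max(-1.0, diff - dl)
    high = min(1.0, diff + du)
    return diff, low, high
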