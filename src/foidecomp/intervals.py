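"""Exact interval estimates for binomial proportions and Poisson counts.

The descriptive summaries of field infestation data use asymmetric exact
intervals: Clopper-Pearson for proportions (beta quantiles) and the classic
chi-square/gamma construction for Poisson means.
"""

from __future__ import annotations

from scipy import stats

from .records import IntervalEstimate

__all__ = ["binom_ci", "poisson_ci"]


def binom_ci(x: int, n: int, level: float = 0.95) -> IntervalEstimate:
    """Clopper-Pearson exact confidence interval for a binomial proportion.

    Parameters
    ----------
    x : number of successes, ``0 <= x <= n``.
    n : number of trials, ``n >= 1``.
    level : confidence level in (0, 1).

    The interval is asymmetric about ``x/n`` in general; the lower bound is 0
    exactly when ``x == 0`` and the upper bound is 1 exactly when ``x == n``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return IntervalEstimate(
        point=x / n, lower=lower, upper=upper, level=level, method="binomial_exact"
    )


def poisson_ci(count: int, level: float = 0.95) -> IntervalEstimate:
    """Exact (gamma/chi-square) confidence interval for a Poisson mean.

    The lower bound is 0 exactly when ``count == 0``; for zero counts the
    upper bound is ``-ln(alpha/2)``.
    """
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    lower = 0.0 if count == 0 else float(stats.chi2.ppf(alpha / 2, 2 * count) / 2)
    upper = float(stats.chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2)
    return IntervalEstimate(
        point=float(count), lower=lower, upper=upper, level=level, method="poisson_exact"
    )
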