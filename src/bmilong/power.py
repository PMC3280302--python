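"""Analytic power for a quantitative-trait association test by variance explained.

The test statistic for a genetic predictor explaining a fraction R^2 of trait
variance in a sample of n unrelated subjects is asymptotically noncentral
chi-square with noncentrality lambda = n * R^2 / (1 - R^2). Power at a per-test
type-I error alpha is the probability that this statistic exceeds the central
chi-square critical value. This is the plain cross-sectional calculation at the
subject-level n; the repeated-measures inflation of the observation count is
deliberately not folded in (use ``effective_sample_size`` to explore it).
"""

from __future__ import annotations

from scipy import optimize, stats


def bonferroni_threshold(alpha_family: float, m: int) -> float:
    """Per-test alpha controlling the family-wise error over m tests."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    if not 0 < alpha_family < 1:
        raise ValueError("family alpha must be in (0, 1)")
    return alpha_family / m


def noncentrality(n: int, variance_explained: float) -> float:
    """lambda = n * R^2 / (1 - R^2) for a predictor explaining R^2 of the trait."""
    if not 0 < variance_explained < 1:
        raise ValueError("variance_explained must be in (0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    return n * variance_explained / (1.0 - variance_explained)


def power_variance_explained(n: int, variance_explained: float, alpha: float,
                             df: int = 1) -> float:
    """Power of a df-degree chi-square test at per-test level alpha.

    Under the additive model df=1; a general (genotype-factor) test uses df=2.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    lam = noncentrality(n, variance_explained)
    crit = stats.chi2.ppf(1.0 - alpha, df)
    return float(stats.ncx2.sf(crit, df, lam))


def minimum_detectable_r2(n: int, alpha: float, target_power: float,
                          df: int = 1) -> float:
    """Smallest variance-explained fraction reaching ``target_power``.

    Solved by bracketing root search on the (strictly increasing) power curve.
    """
    if not 0 < target_power < 1:
        raise ValueError("target_power must be in (0, 1)")
    if target_power <= alpha:
        return 0.0
    lo, hi = 1e-10, 1.0 - 1e-10
    if power_variance_explained(n, lo, alpha, df) >= target_power:
        return lo
    if power_variance_explained(n, hi, alpha, df) < target_power:
        raise ValueError("target power unreachable at this n and alpha")
    return float(optimize.brentq(
        lambda r2: power_variance_explained(n, r2, alpha, df) - target_power,
        lo, hi, xtol=1e-12,
    ))


def effective_sample_size(n: int, m_visits: float, icc: float) -> float:
    """n * m / (1 + (m - 1) * icc): repeated-measures effective subject count."""
    if not 0 <= icc <= 1:
        raise ValueError("ICC must be in [0, 1]")
    if m_visits < 1:
        raise ValueError("mean visit count must be >= 1")
    return n * m_visits / (1.0 + (m_visits - 1.0) * icc)
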