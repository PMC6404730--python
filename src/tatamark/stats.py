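"""Dichotomy statistics: exact binomial tests and the equal-split χ².

Three tests cover every statistic the marker tables need:

* :func:`binom_equal_test` — exact binomial test of an a:b split against
  the equiprobable null p = ½ (two-sided by the doubling method, or
  one-sided "greater").
* :func:`binom_neutral_test` — exact two-sided binomial test against the
  4:1 neutral-drift null (≈800 site-damaging vs ≈200 site-improving SNPs
  per genome), i.e. p = 0.2 for the affinity-increasing count.
* :func:`chi2_equal_split` — 1-df goodness-of-fit χ² of an a:b split
  against a 50:50 expectation, without continuity correction.

:func:`all_concordant_p` gives the probability that n independent
coin-flip concordance checks all succeed, 0.5ⁿ — the closed form behind
the "all n validations matched" argument.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binom, chi2

from .errors import InputError


@dataclass(frozen=True)
class TestResult:
    """Outcome of one dichotomy test."""

    p_value: float
    null: str
    counts: tuple[int, int]
    statistic: float | None = None  # χ² where applicable

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise InputError(f"p-value {self.p_value} outside (0,1]")
        if self.statistic is not None and self.statistic < 0:
            raise InputError("negative test statistic")


def _check_counts(a: int, b: int) -> None:
    if a < 0 or b < 0:
        raise InputError("counts must be non-negative")
    if a + b == 0:
        raise InputError("a + b must be >= 1")


def _binom_two_sided(k: int, n: int, p: float) -> float:
    """Doubling method: 2 · min(P(X ≤ k), P(X ≥ k)), capped at 1."""
    lower = binom.cdf(k, n, p)
    upper = binom.sf(k - 1, n, p)
    return float(min(1.0, 2.0 * min(lower, upper)))


def binom_equal_test(a: int, b: int, alternative: str = "two_sided") -> TestResult:
    """Exact binomial test of ``a`` successes in ``a+b`` trials at p = ½."""
    _check_counts(a, b)
    n = a + b
    if alternative == "two_sided":
        p = _binom_two_sided(a, n, 0.5)
    elif alternative == "greater":
        p = float(binom.sf(a - 1, n, 0.5))
    else:
        raise InputError(f"unknown alternative {alternative!r}")
    return TestResult(
        p_value=p,
        null=f"equiprobable binomial, {alternative}",
        counts=(a, b),
    )


def binom_neutral_test(n_over: int, n_under: int) -> TestResult:
    """Exact two-sided binomial test against the 4:1 neutral-drift null.

    ``n_over`` (affinity-increasing SNPs) is tested at success probability
    0.2, equivalently ``n_under`` at 0.8.
    """
    _check_counts(n_over, n_under)
    p = _binom_two_sided(n_over, n_over + n_under, 0.2)
    return TestResult(
        p_value=p,
        null="4:1 neutral-drift binomial (p_over = 0.2), two_sided",
        counts=(n_over, n_under),
    )


def chi2_equal_split(a: int, b: int) -> TestResult:
    """1-df goodness-of-fit χ² of a:b against 50:50, no continuity correction."""
    _check_counts(a, b)
    n = a + b
    expected = n / 2.0
    stat = (a - expected) ** 2 / expected + (b - expected) ** 2 / expected
    return TestResult(
        p_value=float(max(chi2.sf(stat, df=1), 1e-300)) if stat > 0 else 1.0,
        null="equal-split chi-square, 1 df, uncorrected",
        counts=(a, b),
        statistic=float(stat),
    )


def all_concordant_p(n: int) -> float:
    """P(all n independent 50:50 concordance checks succeed) = 0.5ⁿ."""
    if n < 1:
        raise InputError("n must be >= 1")
    return 0.5**n
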