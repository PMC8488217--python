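"""Exact small-sample statistics used by every filter.

The Fisher exact test here is the workhorse of both the tumor-vs-WBC
somatic filter (keep if p < 0.01) and the CTC rescue rule.  It is computed
by direct summation over the hypergeometric support in log space, so tables
with up to ~10^6 reads per cell are handled without overflow.  Two-sided
p sums the probabilities of all tables (with the observed margins) whose
point probability does not exceed the observed one, with a relative tie
tolerance of 1e-7 so that float rounding cannot flip the inclusion of an
exactly tied table.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.special import gammaln
from scipy.stats import beta

#: Relative tolerance for point-probability ties in the two-sided sum.
TIE_RTOL = 1e-7


class FisherTable(NamedTuple):
    """2x2 table: row1 = (alt, ref) of sample 1, row2 = (alt, ref) of sample 2."""

    a: int
    b: int
    c: int
    d: int


class UndefinedTestError(ValueError):
    """The test statistic is undefined for the given input."""


def _log_pmf_support(r1: int, r2: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Log hypergeometric pmf over the support of the (1,1) cell.

    Margins: row sums r1, r2; first-column sum k.  Returns (support, logpmf).
    """
    n = r1 + r2
    lo = max(0, k - r2)
    hi = min(k, r1)
    a = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(r1 + 1) - gammaln(a + 1) - gammaln(r1 - a + 1)
        + gammaln(r2 + 1) - gammaln(k - a + 1) - gammaln(r2 - (k - a) + 1)
        - (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))
    )
    return a, logpmf


def fisher_exact(table: FisherTable | tuple[int, int, int, int],
                 alternative: str = "two-sided") -> float:
    """Fisher exact test p-value for a 2x2 table with fixed margins.

    alternative: "two-sided" (default) or "greater" (first row enriched in
    the first column, i.e. higher VAF in sample 1).
    """
    a, b, c, d = table
    if min(a, b, c, d) < 0:
        raise UndefinedTestError("negative cell in 2x2 table")
    if a + b + c + d == 0:
        raise UndefinedTestError("all-zero 2x2 table")
    if alternative == "two-sided":
        # p is invariant under row and column swaps; canonicalize so the
        # equality holds bit-exactly, not just mathematically
        a, b, c, d = min((a, b, c, d), (c, d, a, b), (b, a, d, c), (d, c, b, a))
    r1, r2, k = a + b, c + d, a + c
    support, logpmf = _log_pmf_support(r1, r2, k)
    obs = logpmf[np.searchsorted(support, a)]
    if alternative == "two-sided":
        mask = logpmf <= obs + np.log1p(TIE_RTOL)
    elif alternative == "greater":
        mask = support >= a
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = float(np.exp(logpmf[mask]).sum())
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def fisher_exact_two_sided(table: FisherTable | tuple[int, int, int, int]) -> float:
    return fisher_exact(table, alternative="two-sided")


def binomial_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact confidence interval for a binomial fraction."""
    if n < 1:
        raise UndefinedTestError("binomial interval needs n >= 1")
    if not 0 <= k <= n:
        raise UndefinedTestError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < conf < 1.0:
        raise UndefinedTestError(f"confidence level must be in (0,1), got {conf}")
    alpha = 1.0 - conf
    low = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high
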