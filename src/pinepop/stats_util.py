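"""Shared statistical primitives.

Chi-square upper tails, G-tests (plain and with the Williams small-sample
correction), Bonferroni adjustment and an overflow-safe log-mean-exp used by
the Monte-Carlo likelihood machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import chi2

__all__ = [
    "GofResult",
    "chisq_sf",
    "g_statistic",
    "williams_g",
    "bonferroni",
    "log_mean_exp",
]


@dataclass(frozen=True)
class GofResult:
    """Result of a goodness-of-fit G-test.

    Attributes
    ----------
    g_raw : float
        Unadjusted log-likelihood-ratio statistic ``2 * sum(O * ln(O/E))``.
    q : float
        Williams correction factor (>= 1); 1.0 when no correction applied.
    g_adj : float
        ``g_raw / q``.
    df : int
        Degrees of freedom used for the p-value.
    p : float
        Upper chi-square tail of ``g_adj`` at ``df``.
    """

    g_raw: float
    q: float
    g_adj: float
    df: int
    p: float


def chisq_sf(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution.

    For ``df == 2`` this equals ``exp(-x/2)`` exactly (regularized upper
    incomplete gamma function).
    """
    if x < 0:
        raise ValueError(f"chi-square statistic must be >= 0, got {x}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(chi2.sf(x, df))


def g_statistic(observed: np.ndarray, expected: np.ndarray) -> float:
    """Log-likelihood-ratio statistic ``2 * sum(O * ln(O/E))``.

    Cells with ``O == 0`` contribute 0 (the ``x ln x -> 0`` limit).  A cell
    with ``O > 0`` and ``E == 0`` yields ``inf``.
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must have the same shape")
    if np.any(observed < 0) or np.any(expected < 0):
        raise ValueError("counts must be non-negative")
    pos = observed > 0
    if np.any(expected[pos] == 0):
        return float("inf")
    with np.errstate(divide="ignore"):
        terms = observed[pos] * np.log(observed[pos] / expected[pos])
    return float(2.0 * terms.sum())


def williams_g(observed, expected_ratio) -> GofResult:
    """Goodness-of-fit G-test with the Williams correction.

    ``observed`` are counts over k classes, ``expected_ratio`` the null class
    probabilities (must sum to 1).  The correction factor is
    ``q = 1 + (k^2 - 1) / (6 N (k - 1))`` for N total observations, and the
    p-value uses ``df = k - 1``.
    """
    observed = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if observed.shape != ratio.shape:
        raise ValueError("observed and expected_ratio must have the same shape")
    if not np.isclose(ratio.sum(), 1.0):
        raise ValueError("expected_ratio must sum to 1")
    n_total = observed.sum()
    if n_total < 1:
        raise ValueError("need at least one observation")
    k = observed.size
    expected = n_total * ratio
    g_raw = g_statistic(observed, expected)
    q = 1.0 + (k**2 - 1) / (6.0 * n_total * (k - 1))
    g_adj = g_raw / q
    df = k - 1
    p = chisq_sf(g_adj, df) if np.isfinite(g_adj) else 0.0
    return GofResult(g_raw=g_raw, q=q, g_adj=g_adj, df=df, p=p)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value, ``min(1, p * m)``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return min(1.0, p * m)


def log_mean_exp(log_values: np.ndarray) -> float:
    """log of the arithmetic mean of exp(log_values), overflow-safe.

    ``-inf`` entries (zero-probability terms) are handled naturally; the
    result is ``-inf`` only if every entry is ``-inf``.
    """
    log_values = np.asarray(log_values, dtype=float)
    if log_values.size == 0:
        raise ValueError("log_mean_exp of empty array")
    if np.all(np.isneginf(log_values)):
        return float("-inf")
    return float(logsumexp(log_values) - np.log(log_values.size))
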