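"""Statistical primitives with explicit contracts.

Thin wrappers around scipy/statsmodels that pin down the exact conventions the
pipeline depends on: the *uncorrected* Pearson chi-square for 2x2 tables (no
Yates continuity correction — the continuity-corrected statistic does not
reproduce classical single-unit prevalence contrasts), exact binomial upper
tails, Benjamini–Hochberg step-up masks, the asymptotic two-sample KS test,
and classical (pooled-variance) t statistics with exact df bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "chi2_2x2",
    "binom_upper_tail",
    "bh_fdr",
    "bonferroni_threshold",
    "ks_two_sample",
    "t_two_sample",
    "t_paired",
    "t_one_sample",
    "spawn_rng",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``df`` holds degrees of freedom where defined, ``n`` the sample size(s)
    involved, and ``tail`` is one of ``{"two", "upper", "lower"}``.
    """

    statistic: float
    p_value: float
    df: float | None = None
    n: int | None = None
    tail: str = "two"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "df": None if self.df is None else float(self.df),
            "n": self.n,
            "tail": self.tail,
        }


def chi2_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square for the 2x2 table [[a, b], [c, d]], uncorrected.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), p from the df=1 upper tail.
    All four margins must be positive. No continuity correction is applied.
    """
    counts = np.array([a, b, c, d], dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    n = counts.sum()
    margins = [a + b, c + d, a + c, b + d]
    if any(m <= 0 for m in margins):
        raise ValueError("2x2 table has a zero margin; chi-square undefined")
    chi2 = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    p = float(sps.chi2.sf(chi2, df=1))
    return TestResult(statistic=float(chi2), p_value=p, df=1, n=int(n), tail="upper")


def binom_upper_tail(k: int, n: int, p0: float) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, p0).

    Computed via the regularized incomplete beta function (scipy's survival
    function), numerically stable into the far tail (< 1e-300).
    """
    if not (0 <= k <= n):
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"require p0 in (0, 1), got {p0}")
    if k == 0:
        return 1.0
    return float(sps.binom.sf(k - 1, n, p0))


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask at FDR level ``q``.

    Returns a boolean array aligned with the input. The mask is monotone in
    the sorted order: everything at or below the largest p(i) <= q*i/m is
    rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= q * (np.arange(1, m + 1) / m)
    mask = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))
        mask[order[: k + 1]] = True
    return mask


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha/m for a family of m tests."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return alpha / m


def ks_two_sample(x, y) -> TestResult:
    """Two-sided two-sample Kolmogorov–Smirnov test (asymptotic p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 samples per group for the KS test")
    res = sps.ks_2samp(x, y, method="asymp")
    return TestResult(statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)),
                      n=int(x.size + y.size), tail="two")


def _zero_variance_result(mean_diff: float, n: int, df: float) -> TestResult:
    # Degenerate samples: identical means -> no evidence (p=1); different
    # means with zero spread -> deterministic difference (p=0, flagged by inf t).
    if mean_diff == 0.0:
        return TestResult(statistic=0.0, p_value=1.0, df=df, n=n)
    return TestResult(statistic=float(np.sign(mean_diff) * np.inf), p_value=0.0, df=df, n=n)


def t_two_sample(x, y, pooled: bool = True) -> TestResult:
    """Two-tailed two-sample t test (pooled/classical variance by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 observations per sample")
    df = x.size + y.size - 2 if pooled else None
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        return _zero_variance_result(float(x.mean() - y.mean()), x.size + y.size,
                                     df if df is not None else float("nan"))
    res = sps.ttest_ind(x, y, equal_var=pooled)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      df=float(res.df), n=int(x.size + y.size))


def t_paired(x, y) -> TestResult:
    """Two-tailed paired t test; df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need >= 2 pairs")
    d = x - y
    if np.var(d) == 0.0:
        return _zero_variance_result(float(d.mean()), x.size, x.size - 1)
    res = sps.ttest_rel(x, y)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      df=float(x.size - 1), n=int(x.size))


def t_one_sample(x, mu: float = 0.0) -> TestResult:
    """Two-tailed one-sample t test against ``mu``; df = n - 1."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 observations")
    if np.var(x) == 0.0:
        return _zero_variance_result(float(x.mean() - mu), x.size, x.size - 1)
    res = sps.ttest_1samp(x, mu)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      df=float(x.size - 1), n=int(x.size))


def spawn_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child RNG (PCG64) for the given seed and integer key path.

    Every source of randomness in the pipeline is reached through this
    function so that a single master seed reproduces any stage in isolation.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))
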