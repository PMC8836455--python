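"""Group comparisons: randomization test, Student's t tests, Bonferroni gate.

The randomization (permutation) test uses the difference of group means as
its statistic and reports the two-tailed P as the fraction of label
arrangements whose absolute difference is at least the observed one (ties
count as extreme).  When the number of arrangements does not exceed the
iteration budget the enumeration is exhaustive and the P value exact;
otherwise Monte-Carlo resampling is used (without adding the observed
arrangement to the count).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import scipy.stats

__all__ = [
    "ComparisonResult",
    "randomization_test",
    "t_test",
    "bonferroni_significant",
    "normality_p",
]


@dataclass
class ComparisonResult:
    method: str  # randomization | t_paired | t_unpaired
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    iterations: int | None = None
    seed: int | None = None
    exhaustive: bool = False
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "iterations": self.iterations,
            "seed": self.seed,
            "exhaustive": self.exhaustive,
            "flags": list(self.flags),
        }


def randomization_test(group_a, group_b, iterations: int = 10000,
                       seed=None, force_monte_carlo: bool = False) -> ComparisonResult:
    """Two-tailed, non-paired randomization test on the difference of means.

    ``force_monte_carlo`` disables the automatic exhaustive enumeration
    (useful for validating the resampling mode against the exact P).
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    obs = float(a.mean() - b.mean())
    target = abs(obs)
    # absolute tolerance so exact ties in floating point count as extreme
    atol = 1e-12 * (1.0 + np.abs(pooled).max())

    total = comb(n, na)
    if total <= iterations and not force_monte_carlo:
        pooled_sum = pooled.sum()
        count = 0
        for idx in combinations(range(n), na):
            sa = pooled[list(idx)].sum()
            d = sa / na - (pooled_sum - sa) / (n - na)
            if abs(d) >= target - atol:
                count += 1
        return ComparisonResult(method="randomization", statistic=obs,
                                p_value=count / total, n_a=na, n_b=b.size,
                                iterations=total, seed=seed, exhaustive=True)

    rng = np.random.default_rng(seed)
    mat = rng.permuted(np.tile(pooled, (iterations, 1)), axis=1)
    d = mat[:, :na].mean(axis=1) - mat[:, na:].mean(axis=1)
    count = int(np.sum(np.abs(d) >= target - atol))
    return ComparisonResult(method="randomization", statistic=obs,
                            p_value=count / iterations, n_a=na, n_b=b.size,
                            iterations=iterations, seed=seed, exhaustive=False)


def t_test(group_a, group_b, paired: bool = False,
           welch: bool = False) -> ComparisonResult:
    """Classical two-tailed Student's t test (pooled variance when unpaired).

    Degenerate variance is flagged: identical paired samples give t=0,
    P=1; a constant non-zero paired difference gives P=0 with an
    infinite-statistic flag.  ``welch=True`` drops the equal-variance
    assumption for the unpaired test.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if paired:
        if a.size != b.size or a.size < 2:
            raise ValueError("paired test requires equal lengths >= 2")
        d = a - b
        if np.ptp(d) == 0.0:
            if d[0] == 0.0:
                return ComparisonResult(method="t_paired", statistic=0.0,
                                        p_value=1.0, n_a=a.size, n_b=b.size,
                                        flags=["zero-variance"])
            return ComparisonResult(method="t_paired",
                                    statistic=float(np.sign(d[0]) * np.inf),
                                    p_value=0.0, n_a=a.size, n_b=b.size,
                                    flags=["constant-difference"])
        res = scipy.stats.ttest_rel(a, b)
        return ComparisonResult(method="t_paired", statistic=float(res.statistic),
                                p_value=float(res.pvalue), n_a=a.size, n_b=b.size)

    if a.size < 2 or b.size < 2:
        raise ValueError("unpaired test requires at least 2 values per group")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        if a[0] == b[0]:
            return ComparisonResult(method="t_unpaired", statistic=0.0,
                                    p_value=1.0, n_a=a.size, n_b=b.size,
                                    flags=["zero-variance"])
        return ComparisonResult(method="t_unpaired",
                                statistic=float(np.sign(a[0] - b[0]) * np.inf),
                                p_value=0.0, n_a=a.size, n_b=b.size,
                                flags=["zero-variance"])
    res = scipy.stats.ttest_ind(a, b, equal_var=not welch)
    return ComparisonResult(method="t_unpaired", statistic=float(res.statistic),
                            p_value=float(res.pvalue), n_a=a.size, n_b=b.size)


def bonferroni_significant(p: float, comparisons: int = 3,
                           alpha: float = 0.05) -> bool:
    """Strict Bonferroni gate: significant iff p < alpha/comparisons."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if comparisons < 1:
        raise ValueError("comparisons must be >= 1")
    return p < alpha / comparisons


def normality_p(values) -> float:
    """Shapiro-Wilk P value (convenience wrapper for choosing a test)."""
    return float(scipy.stats.shapiro(np.asarray(list(values), dtype=float)).pvalue)
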