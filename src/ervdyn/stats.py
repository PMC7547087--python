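"""Statistics behind the violin/scatter/box comparisons.

Group comparisons of bin-level enrichment use the two-sided Wilcoxon rank
sum test (exact for small tie-free samples, normal approximation with tie
and continuity correction otherwise), Cohen's d with pooled standard
deviation for effect size, and the classical paired t test for per-locus
paired comparisons. Tukey's 1.5 IQR rule is available for trimming
distribution displays only; it is never applied before a test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import DegenerateTestError, ParameterError

__all__ = [
    "TestResult",
    "tukey_filter",
    "wilcoxon_rank_sum",
    "cohens_d",
    "cohens_d_bootstrap",
    "paired_t_test",
]

EXACT_N_MAX = 8


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    n1: int
    n2: int
    method: str
    effect_size: Optional[float] = None


def tukey_filter(values: Sequence[float]) -> Tuple[np.ndarray, int]:
    """Retain values within [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation (type-7), the convention of the
    source statistical environment, on which the bounds depend. Samples
    with fewer than 4 values are returned unchanged with a warning. The
    filter is idempotent on its own output only in the trivial sense of a
    single pass: it is applied once, for display trimming.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        warnings.warn(f"tukey_filter needs n >= 4, got {arr.size}; returning input")
        return arr, 0
    q1, q3 = np.percentile(arr, [25, 75])  # numpy default is type-7 (linear)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (arr >= lo) & (arr <= hi)
    return arr[keep], int((~keep).sum())


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank sum (Mann-Whitney) test.

    Uses the exact null distribution when min(n) <= 8 and there are no
    ties, otherwise the normal approximation with tie correction and
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = min(a.size, b.size) <= EXACT_N_MAX and not has_ties
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n1=int(a.size),
        n2=int(b.size),
        method="exact" if exact else "normal-approx",
    )


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Cohen's d with pooled SD; sign is mean(a) - mean(b).

    s_pooled^2 = ((n_a - 1) s_a^2 + (n_b - 1) s_b^2) / (n_a + n_b - 2),
    with sample (ddof=1) variances.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("cohens_d requires n >= 2 per group")
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        raise DegenerateTestError("pooled SD is zero; effect size undefined")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def cohens_d_bootstrap(
    a: Sequence[float],
    b: Sequence[float],
    n_boot: int = 200,
    seed: int = 0,
) -> Tuple[float, float]:
    """Point estimate and seeded bootstrap SD for Cohen's d.

    The bootstrap SD reproduces the "+/-" reported alongside effect
    sizes; only the point estimate is compared against reference values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = cohens_d(a, b)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        ra = a[rng.integers(0, a.size, a.size)]
        rb = b[rng.integers(0, b.size, b.size)]
        try:
            reps[i] = cohens_d(ra, rb)
        except DegenerateTestError:
            reps[i] = np.nan
    return d, float(np.nanstd(reps))


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Classical two-sided paired t test on per-locus differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("paired samples must have equal length")
    if a.size < 2:
        raise ParameterError("paired t test requires n >= 2")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0):
        raise DegenerateTestError(
            "differences have zero variance; paired t statistic undefined"
        )
    res = sps.ttest_rel(a, b)
    return TestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n1=int(a.size),
        n2=int(b.size),
        method="paired-t",
    )
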