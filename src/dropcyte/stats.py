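"""Statistical layer: paired two-sided t-tests, two-sample Kolmogorov-Smirnov
tests on secretion-rate distributions, significance stars, mean +/- SEM.

No multiple-testing correction is applied anywhere; every result carries a
provenance flag saying so. The KS test is invariant under strictly monotone
transforms, so log-scale display of rate distributions does not affect it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateTestError

#: Echoed in every result: the analysis reports raw, uncorrected p-values.
MULTIPLE_TESTING_CORRECTION = "none"


@dataclass(frozen=True)
class StatResult:
    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    stars: str
    correction: str = MULTIPLE_TESTING_CORRECTION

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def stars(p: float) -> str:
    """Significance stars: * [0.01, 0.05), ** [0.001, 0.01), *** [0.0001, 0.001),
    **** below 0.0001; 'ns' at or above 0.05."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def paired_t_test(a, b) -> StatResult:
    """Two-sided paired t-test; pairs matched by position (measurement identity).

    Raises :class:`DegenerateTestError` when the differences have zero
    variance (the t statistic is undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired test needs two equal-length 1-D samples")
    if a.size < 2:
        raise ValueError("paired test needs at least 2 pairs")
    diff = b - a
    if np.allclose(diff, diff[0]) and np.std(diff, ddof=1) == 0.0:
        raise DegenerateTestError("differences have zero variance")
    res = sps.ttest_rel(a, b)
    p = float(res.pvalue)
    return StatResult(
        test="paired_t",
        statistic=float(res.statistic),
        p_value=p,
        n=(a.size,),
        stars=stars(p),
    )


def ks_test(x, y, method: str | None = None) -> StatResult:
    """Two-sample, two-sided Kolmogorov-Smirnov test.

    Exact p-value when both samples have n <= 100, asymptotic otherwise
    (overridable via ``method``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS test needs two non-empty samples")
    if method is None:
        method = "exact" if (x.size <= 100 and y.size <= 100) else "asymp"
    res = sps.ks_2samp(x, y, alternative="two-sided", method=method)
    p = float(min(1.0, res.pvalue))
    return StatResult(
        test="ks_2samp",
        statistic=float(res.statistic),
        p_value=p,
        n=(x.size, y.size),
        stars=stars(p),
    )
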