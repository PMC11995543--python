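"""The three comparison tests used in the analysis, from first principles.

All tests are two-sided. The two-proportion z test uses the pooled standard
error without continuity correction; Welch's t test uses the
Welch-Satterthwaite degrees of freedom. Degenerate inputs with zero
standard error yield an undefined result (statistic/p-value ``None``)
rather than a division failure. p-values come from scipy's normal and t
distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float | None
    p_value: float | None
    df: float | None
    method: str

    def __post_init__(self) -> None:
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @property
    def undefined(self) -> bool:
        return self.statistic is None


def two_proportion_z_test(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Pooled two-proportion z test of H0: p1 == p2."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("successes must lie in [0, n]")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0.0:
        if p1 == p2:
            # all successes or all failures in both groups: no evidence
            # against H0, but the statistic itself is undefined
            return TestResult(None, None, None, "two_proportion_z")
        raise AssertionError("zero SE with unequal proportions")  # pragma: no cover
    z = (p1 - p2) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(statistic=z, p_value=p, df=None, method="two_proportion_z")


def welch_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Welch's unequal-variance t test of H0: mean_a == mean_b."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise ValueError("both samples have zero variance")
    sea2 = va / a.size
    seb2 = vb / b.size
    t = (a.mean() - b.mean()) / math.sqrt(sea2 + seb2)
    df = (sea2 + seb2) ** 2 / (
        sea2**2 / (a.size - 1) + seb2**2 / (b.size - 1)
    )
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=t, p_value=p, df=df, method="welch_t")


def one_sample_t_test(values: Sequence[float], mu0: float) -> TestResult:
    """One-sample t test of H0: mean == mu0."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero variance")
    t = (x.mean() - mu0) / (sd / math.sqrt(x.size))
    df = x.size - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=t, p_value=p, df=float(df), method="one_sample_t")
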