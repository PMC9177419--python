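"""Knockdown phenotype statistics from printed five-number summaries.

Published box plots with n = 4 per group report only the five-number
summary (min, Q1, median, Q3, max). Under the inclusive-median quartile
convention the four underlying values are exactly recoverable::

    x1 = min                x2 = 2 Q1 - min
    x4 = max                x3 = 2 Q3 - max

with the consistency check median = (x2 + x3) / 2. The reconstructed
groups are then compared with a two-sided two-sample Student's t-test
(pooled variance by default; Welch optional).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class FiveNumberSummary:
    """min <= Q1 <= median <= Q3 <= max for a sample of size n."""

    n: int
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        vals = (self.minimum, self.q1, self.median, self.q3, self.maximum)
        if any(a > b for a, b in zip(vals, vals[1:])):
            raise ValueError("summary must be non-decreasing")


def reconstruct_n4(
    summary: FiveNumberSummary, tolerance: float = 0.005
) -> np.ndarray:
    """Recover the four data points behind an n = 4 five-number summary.

    Uses the inclusive-median quartile convention (Q1 is the median of
    the lower half including nothing extra for even n: Q1 = (x1+x2)/2,
    Q3 = (x3+x4)/2). Raises if the implied values are out of order or the
    median check fails beyond ``tolerance``.
    """
    if summary.n != 4:
        raise ValueError("reconstruction defined only for n = 4")
    x1 = summary.minimum
    x4 = summary.maximum
    x2 = 2.0 * summary.q1 - summary.minimum
    x3 = 2.0 * summary.q3 - summary.maximum
    values = np.array([x1, x2, x3, x4])
    if not np.all(np.diff(values) >= -1e-12):
        raise ValueError(
            f"summary inconsistent under the inclusive-median convention: "
            f"implied values {values.tolist()} are out of order"
        )
    residual = abs((x2 + x3) / 2.0 - summary.median)
    if residual > tolerance:
        raise ValueError(
            f"median check failed: residual {residual:.6g} > {tolerance}"
        )
    return values


def two_sample_t(
    a: np.ndarray,
    b: np.ndarray,
    variant: str = "student_pooled",
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test.

    ``variant="student_pooled"`` (default) uses the pooled-variance
    Student statistic; ``"welch"`` the Welch--Satterthwaite correction.
    Returns ``(t, df, p)``. Two zero-variance groups with equal means
    yield t = 0, p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if variant not in {"student_pooled", "welch"}:
        raise ValueError(f"unknown variant {variant!r}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    equal_var = variant == "student_pooled"
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = (
        float(len(a) + len(b) - 2)
        if equal_var
        else float(res.df)
    )
    return float(res.statistic), df, float(res.pvalue)


def compare_summaries(
    group_a: FiveNumberSummary,
    group_b: FiveNumberSummary,
    variant: str = "student_pooled",
) -> dict:
    """Reconstruct both n = 4 groups and test their difference.

    Returns a dict with the reconstructed values, t, df, p and the
    quartile convention used.
    """
    a = reconstruct_n4(group_a)
    b = reconstruct_n4(group_b)
    t, df, p = two_sample_t(a, b, variant=variant)
    return {
        "group_a": a.tolist(),
        "group_b": b.tolist(),
        "t": t,
        "df": df,
        "p": p,
        "convention": "inclusive-median quartiles",
        "variant": variant,
    }
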