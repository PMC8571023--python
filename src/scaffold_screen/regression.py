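"""Pearson correlation / ordinary-least-squares regression with the t-test
on r used throughout the screen's exploratory analyses.

The significance test is the classical one: under the null of zero
correlation, t = r * sqrt((n - 2) / (1 - r^2)) follows a Student-t
distribution with n - 2 degrees of freedom; the reported p-value is
two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class RegressionResult:
    n: int
    slope: float
    intercept: float
    r: float
    r2: float
    p_two_tailed: float

    def as_dict(self) -> dict:
        return {"n": self.n, "slope": self.slope, "intercept": self.intercept,
                "r": self.r, "r2": self.r2, "p": self.p_two_tailed}


def pearson_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS fit of y on x with Pearson r and its two-tailed t-test p-value.

    Pairs with a missing value (NaN/None) in either variable are dropped
    (pairwise-complete). Requires >= 3 complete pairs and non-zero variance
    in both variables.
    """
    xa = np.asarray([np.nan if v is None else v for v in x], dtype=float)
    ya = np.asarray([np.nan if v is None else v for v in y], dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    n = int(xa.size)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("degenerate regression: zero variance in x or y")
    fit = stats.linregress(xa, ya)
    return RegressionResult(n=n, slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r=float(fit.rvalue), r2=float(fit.rvalue ** 2),
                            p_two_tailed=float(fit.pvalue))
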