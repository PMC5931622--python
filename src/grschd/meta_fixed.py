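"""Inverse-variance fixed-effects pooling of hazard ratios across strata.

Per-stratum hazard ratios (with 95% confidence intervals, typically as
printed to two decimals) are taken to the log scale, their standard errors
reconstructed from the interval width, and pooled with inverse-variance
weights under a common-effect assumption — appropriate when the strata are
ancestry groups drawn from one source cohort. Heterogeneity is assessed
with Cochran's Q and I².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: normal quantile for 95% intervals, kept at full precision internally
Z95 = 1.959964


@dataclass(frozen=True)
class StudyEstimate:
    """One stratum's hazard ratio with its 95% confidence bounds."""

    label: str
    hr: float
    lcl: float
    ucl: float

    def __post_init__(self) -> None:
        if not (0 < self.lcl < self.hr < self.ucl):
            raise ValueError(
                f"{self.label}: need 0 < lcl < hr < ucl, got "
                f"({self.lcl}, {self.hr}, {self.ucl})"
            )

    @property
    def lnhr(self) -> float:
        return float(np.log(self.hr))

    @property
    def se(self) -> float:
        return ci_to_se(self.hr, self.lcl, self.ucl)[1]


@dataclass(frozen=True)
class PooledResult:
    hr: float
    lcl: float
    ucl: float
    lnhr: float
    se: float
    q: float
    df: int
    p_heterogeneity: float
    i2: float


def ci_to_se(hr: float, lcl: float, ucl: float) -> tuple[float, float]:
    """Log hazard ratio and its standard error from a 95% interval."""
    if not (0 < lcl < hr < ucl):
        raise ValueError(f"need 0 < lcl < hr < ucl, got ({lcl}, {hr}, {ucl})")
    lnhr = float(np.log(hr))
    se = float((np.log(ucl) - np.log(lcl)) / (2.0 * Z95))
    return lnhr, se


def pool_fixed(estimates: list[StudyEstimate]) -> PooledResult:
    """Fixed-effects pooled hazard ratio with Cochran's Q heterogeneity test.

    Weights are the inverse squared standard errors on the log scale; the
    pooled estimate is their weighted mean, Q the weighted sum of squared
    deviations (chi-square with k-1 df under homogeneity), and
    I² = max(0, (Q - df) / Q).
    """
    if not estimates:
        raise ValueError("no estimates to pool")
    lnhr = np.array([e.lnhr for e in estimates])
    se = np.array([e.se for e in estimates])
    w = 1.0 / se**2
    pooled = float(np.sum(w * lnhr) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (lnhr - pooled) ** 2))
    df = len(estimates) - 1
    p_het = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    i2 = float(max(0.0, (q - df) / q)) if q > 0 else 0.0
    return PooledResult(
        hr=float(np.exp(pooled)),
        lcl=float(np.exp(pooled - Z95 * pooled_se)),
        ucl=float(np.exp(pooled + Z95 * pooled_se)),
        lnhr=pooled,
        se=pooled_se,
        q=q,
        df=df,
        p_heterogeneity=p_het,
        i2=i2,
    )


def pool_rows(rows) -> PooledResult:
    """Pool an iterable of (label, hr, lcl, ucl) tuples."""
    return pool_fixed([StudyEstimate(*r) for r in rows])
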