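"""Consistency assessment between paired measurement series.

Pearson correlation quantifies linear association between an estimate
and its reference; the Bland-Altman analysis summarizes the paired
differences d = estimate - reference by their mean and SD and the 95%
limits of agreement d_bar +/- 1.96 SD, which should contain about 95%
of the differences when they are normally distributed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["AgreementResult", "pearson", "bland_altman"]

Z_95 = 1.96


@dataclass
class AgreementResult:
    pearson_r: float
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pct_within: float
    n: int

    def as_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "pct_within": self.pct_within,
            "n": self.n,
        }


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    return x, y


def pearson(x, y) -> float:
    """Product-moment correlation; NaN when either series is constant."""
    x, y = _paired(x, y)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def bland_altman(x, y) -> AgreementResult:
    """Limits-of-agreement analysis of the differences x - y.

    The difference direction is fixed as (estimate - reference); the SD
    uses the n-1 denominator and points exactly on a limit count as
    within (closed interval).
    """
    x, y = _paired(x, y)
    d = x - y
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    loa_low = mean_diff - Z_95 * sd_diff
    loa_high = mean_diff + Z_95 * sd_diff
    within = (d >= loa_low) & (d <= loa_high)
    return AgreementResult(
        pearson_r=pearson(x, y),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=loa_low,
        loa_high=loa_high,
        pct_within=100.0 * float(np.mean(within)),
        n=int(d.size),
    )
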