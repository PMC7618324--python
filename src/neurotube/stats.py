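"""Two-group statistics shared by the AFM and tissue-shape modules.

Two-sided paired or independent t-tests with per-group Shapiro-Wilk
normality checks, reported against a fixed 0.05 significance threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .defaults import SIGNIFICANCE_ALPHA

__all__ = ["GroupComparison", "two_group_test"]


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    shapiro_p_a: float
    shapiro_p_b: float
    paired: bool
    alpha: float
    n_a: int
    n_b: int
    degenerate: bool = False  # zero-variance difference / identical groups

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_value < self.alpha


def _shapiro_p(x: np.ndarray, label: str) -> float:
    if x.size < 3:
        warnings.warn(
            f"group {label} has n={x.size} < 3; Shapiro-Wilk normality test skipped",
            stacklevel=3,
        )
        return math.nan
    if np.ptp(x) == 0:
        return math.nan
    return float(sps.shapiro(x).pvalue)


def two_group_test(values_a, values_b, paired: bool = False,
                   alpha: float = SIGNIFICANCE_ALPHA) -> GroupComparison:
    """Two-sided t-test between two groups.

    Parameters
    ----------
    values_a, values_b : array-like
        Group observations.  When ``paired`` they must be equal length and in
        matched (per-specimen) order.
    paired : bool
        Paired t-test (e.g. hindbrain vs spinal cord measured in the same
        embryo) versus independent two-sample t-test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("group values must be 1-D")
    if paired and a.size != b.size:
        raise ValueError(f"paired test requires equal lengths, got {a.size} and {b.size}")

    sh_a = _shapiro_p(a, "a")
    sh_b = _shapiro_p(b, "b")

    degenerate = False
    if paired:
        diff = a - b
        if np.ptp(diff) == 0:
            # zero-variance differences: t is 0/0; flag instead of deciding silently
            degenerate = True
            t_stat = math.nan
            p = math.nan
        else:
            res = sps.ttest_rel(a, b)
            t_stat, p = float(res.statistic), float(res.pvalue)
    else:
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            degenerate = True
            t_stat = math.nan
            p = math.nan
        else:
            res = sps.ttest_ind(a, b)
            t_stat, p = float(res.statistic), float(res.pvalue)

    return GroupComparison(
        statistic=t_stat, p_value=p, shapiro_p_a=sh_a, shapiro_p_b=sh_b,
        paired=paired, alpha=alpha, n_a=int(a.size), n_b=int(b.size),
        degenerate=degenerate,
    )
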