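"""Inter-rater agreement: the Friedman rank test.

Several raters segment the same set of neurons; per-neuron metrics
(volume, area, GU) or per-radius Sholl counts form an n-block × k-treatment
table (blocks = neurons or radii, treatments = raters). The Friedman test
ranks the k treatments within every block (mid-ranks on ties) and asks
whether the rank sums differ more than chance allows; a non-significant
result is the desired outcome when checking that raters agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = ["FriedmanResult", "friedman_test"]


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    df: int
    p_value: float

    def __iter__(self):
        return iter((self.statistic, self.df, self.p_value))


def friedman_test(table) -> FriedmanResult:
    """Tie-corrected Friedman chi-square test on an n×k table.

    Within each block the k values receive mid-ranks; with column rank
    sums R_j the uncorrected statistic is::

        chi2_F = 12 / (n k (k+1)) * sum_j R_j^2  -  3 n (k+1)

    divided by the tie-correction factor
    C = 1 - sum(t^3 - t) / (n k (k^2 - 1)) over all tie groups t. If every
    block is fully tied (C = 0) there is no information to rank:
    statistic 0, p = 1. The p-value is the chi-square upper tail on
    k - 1 degrees of freedom.

    Parameters
    ----------
    table : array-like or DataFrame, shape (n, k)
        Blocks (e.g. neurons) in rows, treatments (raters) in columns;
        no missing cells, n >= 2 and k >= 2.
    """
    if isinstance(table, pd.DataFrame):
        table = table.to_numpy()
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("table must be two-dimensional (blocks × treatments)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 blocks and 2 treatments, got {n}×{k}")
    if not np.isfinite(x).all():
        raise ValueError("table has missing or non-finite cells")

    ranks = np.apply_along_axis(_sps.rankdata, 1, x)  # mid-ranks within blocks
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * (rank_sums**2).sum() - 3.0 * n * (k + 1)

    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    if correction <= 0.0:
        return FriedmanResult(statistic=0.0, df=k - 1, p_value=1.0)

    statistic = chi2 / correction
    p = float(_sps.chi2.sf(statistic, k - 1))
    return FriedmanResult(statistic=float(statistic), df=k - 1, p_value=p)
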