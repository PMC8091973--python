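"""Inferential summaries: t-tests, Fisher overlap tests, LFC correlations.

Thin, contract-preserving wrappers over scipy/pandas that return tidy
results: the two-sample test is the classical pooled-variance Student form
(not Welch), the Fisher overlap test is one-sided enrichment by default,
and correlation matrices report the pairwise n behind every cell.
"""

from __future__ import annotations

from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["TTestResult", "t_test", "fisher_overlap", "lfc_correlation_matrix"]


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float


def t_test(
    x: Sequence[float],
    y: Optional[Sequence[float]] = None,
    mu0: float = 0.0,
    paired: bool = False,
    alternative: str = "two-sided",
) -> TTestResult:
    """Student's t-test in one-sample, paired and pooled two-sample forms.

    ``alternative`` is one of ``two-sided``, ``less``, ``greater`` and
    refers to x (vs mu0, or vs y).  Zero variance makes the statistic
    undefined; NaNs are returned rather than raising, so callers can report
    the failure.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    if y is None:
        res = sps.ttest_1samp(x, mu0, alternative=alternative)
        df = x.size - 1
    elif paired:
        y = np.asarray(y, dtype=float)
        res = sps.ttest_rel(x, y, alternative=alternative)
        df = x.size - 1
    else:
        y = np.asarray(y, dtype=float)
        if y.size < 2:
            raise ValueError("need n >= 2")
        res = sps.ttest_ind(x, y, equal_var=True, alternative=alternative)
        df = x.size + y.size - 2
    return TTestResult(float(res.statistic), float(df), float(res.pvalue))


def fisher_overlap(
    set_a: set,
    set_b: set,
    universe: set,
    alternative: str = "greater",
) -> tuple[float, float, pd.DataFrame]:
    """Fisher's exact test for the overlap of two gene sets in a universe.

    One-sided by default: p = P(overlap >= observed) under the
    hypergeometric null — the enrichment question behind Venn overlaps.
    Returns (odds ratio, p, 2x2 table).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set(set_a), set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("sets must be subsets of the universe")
    both = len(a & b)
    a_only = len(a - b)
    b_only = len(b - a)
    neither = len(universe) - both - a_only - b_only
    table = pd.DataFrame(
        [[both, a_only], [b_only, neither]],
        index=["in_B", "not_B"],
        columns=["in_A", "not_A"],
    )
    odds, p = sps.fisher_exact(table.to_numpy(), alternative=alternative)
    return float(odds), float(p), table


def lfc_correlation_matrix(
    tables: Mapping[str, pd.Series], min_n: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations between named LFC vectors.

    Vectors are aligned on their region/gene index; missing values are
    dropped pairwise.  Cells with fewer than ``min_n`` shared regions are
    NA.  Returns (r matrix, n matrix).
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 LFC tables")
    names = list(tables)
    r = pd.DataFrame(np.nan, index=names, columns=names)
    n = pd.DataFrame(0, index=names, columns=names)
    for i, ni in enumerate(names):
        for j, nj in enumerate(names):
            a, b = tables[ni].align(tables[nj], join="inner")
            ok = a.notna() & b.notna()
            n.iloc[i, j] = int(ok.sum())
            if ok.sum() >= min_n:
                r.iloc[i, j] = float(np.corrcoef(a[ok], b[ok])[0, 1])
    return r, n
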