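"""Shared statistical primitives used across the pipeline.

Every module that corrects for multiple testing goes through
:func:`bh_adjust` so the step-up procedure has a single source of truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "inverse_rank_normalize", "spearman_grid"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    NaN p-values are passed through as NaN and excluded from the
    correction (they do not count toward the number of tests).
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def inverse_rank_normalize(x, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Blom inverse-rank normal transform.

    Maps value ``x_i`` to ``Phi^{-1}((r_i - 3/8) / (n + 1/4))`` where
    ``r_i`` is its average rank. Rank-based, hence invariant to any
    strictly monotone transform of the input.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-d vector")
    n = x.size
    if n < 2:
        raise ValueError("inverse rank normalization needs n >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    ranks = sps.rankdata(x, method="average")
    return sps.norm.ppf((ranks - offset) / (n + 1.0 - 2.0 * offset))


def spearman_grid(left: pd.DataFrame, right: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation between every column of ``left`` and ``right``.

    Both frames are indexed by sample; only shared samples are used.
    Returns a tidy frame with columns (left, right, n, rho, p, q); BH
    correction is applied across the whole grid. Constant columns give
    NaN rho/p and are excluded from the correction.
    """
    shared = left.index.intersection(right.index)
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared samples, got {len(shared)}")
    lf, rf = left.loc[shared], right.loc[shared]
    rows = []
    for a in lf.columns:
        for b in rf.columns:
            x, y = lf[a].to_numpy(float), rf[b].to_numpy(float)
            mask = np.isfinite(x) & np.isfinite(y)
            if mask.sum() < 3 or np.ptp(x[mask]) == 0 or np.ptp(y[mask]) == 0:
                rho, p = np.nan, np.nan
            else:
                rho, p = sps.spearmanr(x[mask], y[mask])
            rows.append({"left": a, "right": b, "n": int(mask.sum()), "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
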