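"""Differential expression with precision weights and empirical-Bayes
moderation, and attribution of treatment effects to cell composition.

The pipeline mirrors the standard voom/limma workflow:

1. ``log_cpm``: y = log2((count + 0.5) / (lib + 1) * 1e6).
2. ``estimate_precision_weights``: per-gene OLS residual SDs define a
   mean-variance trend (lowess of sqrt(SD) on mean log-count); each
   observation's weight is the trend value at its fitted log-count, to the
   power -4.
3. ``fit_moderated``: per-gene weighted least squares; residual variances
   are shrunk toward a common prior estimated by method of moments on
   log s_g^2 (trigamma inversion), giving the posterior variance
   s~^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g) and a moderated t with
   d0 + d_g degrees of freedom.
4. ``run_attribution``: the treatment contrast is fitted twice on identical
   samples — without (model A) and with (model B) cell-contribution
   covariates — and every gene is classified at an FDR threshold as
   significant in both, before adjustment only, after adjustment only, or
   neither. The explained fraction (N_before - N_both) / N_before
   summarizes how much treatment-associated expression change is
   attributable to cell-composition change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess

from .stats import bh_adjust

__all__ = [
    "log_cpm",
    "estimate_precision_weights",
    "ModeratedStats",
    "fit_moderated",
    "AttributionTable",
    "run_attribution",
    "attribution_summary",
]


def log_cpm(counts: pd.DataFrame, lib_sizes: np.ndarray | None = None) -> pd.DataFrame:
    """log2 counts-per-million with the 0.5 / +1 offsets."""
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.integer):
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")
    if lib_sizes is None:
        lib_sizes = vals.sum(axis=0)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if (lib_sizes <= 0).any():
        raise ValueError("zero or negative library size")
    y = np.log2((vals + 0.5) / (lib_sizes + 1.0) * 1e6)
    return pd.DataFrame(y, index=counts.index, columns=counts.columns)


def _batched_wls(Y: np.ndarray, X: np.ndarray, W: np.ndarray):
    """Weighted least squares for every gene at once.

    Y: genes x samples responses; X: samples x p design; W: genes x samples
    positive weights. Returns (beta, fitted, sigma2, df, unscaled_cov_diag)
    where unscaled_cov_diag[g, j] is [(X' W_g X)^-1]_jj.
    """
    G, n = Y.shape
    p = X.shape[1]
    # A[g] = X' W_g X  (G x p x p);  b[g] = X' W_g y_g
    WX = W[:, :, None] * X[None, :, :]          # G x n x p
    A = np.einsum("np,gnq->gpq", X, WX)         # G x p x p
    b = np.einsum("gnp,gn->gp", WX, Y)          # G x p
    beta = np.linalg.solve(A, b[..., None])[..., 0]  # G x p
    fitted = beta @ X.T                         # G x n
    resid = Y - fitted
    df = n - p
    sigma2 = np.einsum("gn,gn->g", W * resid, resid) / df
    Ainv = np.linalg.inv(A)
    cov_diag = np.einsum("gpp->gp", Ainv)
    return beta, fitted, sigma2, df, cov_diag


def estimate_precision_weights(
    y: pd.DataFrame,
    design: np.ndarray,
    span: float = 0.5,
) -> pd.DataFrame:
    """Mean-variance precision weights (voom-style).

    Fits per-gene OLS on ``design``, smooths sqrt(residual SD) against mean
    log2-count with lowess, and assigns each observation the trend value at
    its fitted log2-count raised to -4. With fewer than 10 genes the trend
    is unreliable and constant weights are returned with a warning.
    """
    Y = y.to_numpy(float)
    X = np.asarray(design, float)
    G, n = Y.shape
    if n - X.shape[1] < 1:
        raise ValueError("need residual df >= 1 to estimate weights")
    if G < 10:
        warnings.warn("fewer than 10 genes: mean-variance trend unreliable, using constant weights")
        return pd.DataFrame(np.ones_like(Y), index=y.index, columns=y.columns)
    ones = np.ones_like(Y)
    beta, fitted, sigma2, df, _ = _batched_wls(Y, X, ones)
    sx = Y.mean(axis=1)
    sy = np.sqrt(np.sqrt(np.maximum(sigma2, 1e-12)))  # quarter-root variance = sqrt(SD)
    trend = lowess(sy, sx, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-6)
    w = np.interp(fitted, tx, ty) ** -4.0
    return pd.DataFrame(w, index=y.index, columns=y.columns)


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    x = np.asarray(x, float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) < 1e-8 * y):
            break
    return y


def _squeeze_var(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of a scaled inverse-chi-square prior to the
    observed residual variances; returns (prior df d0, prior variance s0^2).

    Works on z = log(s^2): E[z] and Var[z] under the hierarchical model are
    digamma/trigamma expressions whose inversion yields the prior. When the
    observed spread is no larger than expected from chi-square sampling
    alone, d0 is infinite and every posterior variance equals s0^2.
    """
    z = np.log(np.maximum(sigma2, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0 or not np.isfinite(evar):
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * float(_trigamma_inverse(np.array([evar]))[0])
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


@dataclass
class ModeratedStats:
    """Per-gene moderated test results for one contrast coefficient."""

    table: pd.DataFrame  # gene-indexed: coef, sigma2, df, s2_post, t, p, q
    d0: float
    s02: float
    coef_name: str

    def significant(self, fdr: float = 0.05) -> pd.Index:
        return self.table.index[self.table["q"] < fdr]


def fit_moderated(
    y: pd.DataFrame,
    weights: pd.DataFrame | None,
    design: np.ndarray,
    coef_index: int,
    coef_name: str = "treatment",
    prior_df: float | None = None,
) -> ModeratedStats:
    """Weighted least squares per gene with empirical-Bayes moderation.

    ``coef_index`` selects the design column tested. ``prior_df`` forces d0
    (``np.inf`` gives the fully-pooled limit); by default d0 and s0^2 come
    from the method-of-moments fit on the residual variances.
    """
    X = np.asarray(design, float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    Y = y.to_numpy(float)
    W = np.ones_like(Y) if weights is None else weights.to_numpy(float)
    if (W <= 0).any():
        raise ValueError("weights must be positive")
    beta, fitted, sigma2, df, cov_diag = _batched_wls(Y, X, W)

    if prior_df is None:
        d0, s02 = _squeeze_var(sigma2, df)
    else:
        d0 = float(prior_df)
        _, s02 = _squeeze_var(sigma2, df)
    if np.isinf(d0):
        s2_post = np.full_like(sigma2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df * sigma2) / (d0 + df)
        df_total = d0 + df
    coef = beta[:, coef_index]
    unscaled_se = np.sqrt(np.maximum(cov_diag[:, coef_index], 0.0))
    se = unscaled_se * np.sqrt(s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    table = pd.DataFrame(
        {
            "coef": coef,
            "sigma2": sigma2,
            "df": float(df),
            "s2_post": s2_post,
            "t": t,
            "p": p,
            "q": bh_adjust(p),
        },
        index=y.index,
    )
    return ModeratedStats(table=table, d0=d0, s02=s02, coef_name=coef_name)


@dataclass
class AttributionTable:
    """Gene-level significance before/after cell adjustment plus summary."""

    table: pd.DataFrame  # gene-indexed: q_before, q_after, category
    fdr: float

    @property
    def summary(self) -> dict:
        cats = self.table["category"]
        n_before = int((cats.isin(["both", "pre-only"])).sum())
        n_both = int((cats == "both").sum())
        n_gained = int((cats == "post-only").sum())
        return attribution_summary(n_before, n_both, n_gained)


def attribution_summary(n_before: int, n_both: int, n_gained: int = 0) -> dict:
    """Explained-fraction arithmetic from significant-gene counts.

    ``n_before`` genes significant without cell covariates, of which
    ``n_both`` stay significant with them: the fraction of
    treatment-associated genes explained by composition change is
    (n_before - n_both) / n_before.
    """
    if n_both > n_before:
        raise ValueError("n_both cannot exceed n_before")
    if n_before > 0:
        explained = (n_before - n_both) / n_before
    else:
        explained = np.nan
    return {
        "n_before": int(n_before),
        "n_after_overlap": int(n_both),
        "n_gained": int(n_gained),
        "explained_fraction": explained,
    }


def _design_from_cohort(
    cohort: pd.DataFrame,
    covariates: list[str],
    cell_scores: pd.DataFrame | None,
    adjust_cells: list[str],
) -> tuple[np.ndarray, list[str], pd.Index]:
    meta = cohort.copy()
    counts = meta.groupby("subject")["timepoint"].agg(lambda t: sorted(t))
    keep = counts[counts.apply(lambda t: t == ["post", "pre"])].index
    meta = meta[meta["subject"].isin(keep)]
    subjects = sorted(meta["subject"].unique())
    cols = ["intercept"] + [f"subject[{s}]" for s in subjects[1:]] + list(covariates)
    mats = [np.ones((len(meta), 1))]
    mats += [(meta["subject"] == s).to_numpy(float)[:, None] for s in subjects[1:]]
    mats += [meta[c].to_numpy(float)[:, None] for c in covariates]
    if cell_scores is not None:
        for cell in adjust_cells:
            if cell not in cell_scores.columns:
                raise KeyError(f"adjustment cell type {cell!r} not in scores")
            mats.append(cell_scores.loc[meta.index, cell].to_numpy(float)[:, None])
            cols.append(f"cells[{cell}]")
    mats.append((meta["timepoint"] == "post").to_numpy(float)[:, None])
    cols.append("treatment")
    X = np.hstack(mats)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = [cols[j] for j in range(X.shape[1])
                   if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise ValueError(f"collinear design; aliased columns: {aliased}")
    return X, cols, meta.index


DEFAULT_ADJUST_CELLS = ["memory CD4+ abT", "classical monocyte", "plasma cell"]


def run_attribution(
    counts: pd.DataFrame,
    cohort: pd.DataFrame,
    cell_scores: pd.DataFrame,
    adjust_cells: list[str] | None = None,
    covariates: list[str] = ["gc_score", "pct_dup"],
    fdr: float = 0.05,
    share_weights: bool = False,
) -> AttributionTable:
    """Fit the treatment contrast with and without cell covariates and
    classify every gene.

    Model A: gene ~ subject + GC score + percent-duplicates + treatment.
    Model B: model A + the contribution scores of the adjustment cell types
    (defaults: a CD4 T-cell, a monocyte, and the plasma-cell population).
    Both models use the same samples; weights are re-estimated per model
    unless ``share_weights``.
    """
    if adjust_cells is None:
        adjust_cells = [c for c in DEFAULT_ADJUST_CELLS if c in cell_scores.columns]
        if len(adjust_cells) < 3:
            adjust_cells = list(cell_scores.columns[:3])
    XA, colsA, idx = _design_from_cohort(cohort, covariates, None, [])
    XB, colsB, idxB = _design_from_cohort(cohort, covariates, cell_scores, adjust_cells)
    assert list(idx) == list(idxB), "models must use identical samples"
    y = log_cpm(counts[idx])

    wA = estimate_precision_weights(y, XA)
    wB = wA if share_weights else estimate_precision_weights(y, XB)
    fitA = fit_moderated(y, wA, XA, colsA.index("treatment"))
    fitB = fit_moderated(y, wB, XB, colsB.index("treatment"))

    qa = fitA.table["q"]
    qb = fitB.table["q"]
    sig_a, sig_b = qa < fdr, qb < fdr
    category = np.select(
        [sig_a & sig_b, sig_a & ~sig_b, ~sig_a & sig_b],
        ["both", "pre-only", "post-only"],
        default="neither",
    )
    table = pd.DataFrame(
        {
            "coef_before": fitA.table["coef"],
            "q_before": qa,
            "coef_after": fitB.table["coef"],
            "q_after": qb,
            "category": category,
        },
        index=y.index,
    )
    return AttributionTable(table=table, fdr=fdr)
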