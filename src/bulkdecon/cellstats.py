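"""Cell-contribution statistics: disease contrasts, paired treatment models,
treatment x response interactions, and baseline clinical correlations.

The paired treatment model per cell type is an ordinary least squares fit

    cells ~ subject + GC_signature + treatment

with subjects as fixed-effect indicators (absorbing all stable
between-subject differences), the glucocorticoid ssGSEA score as a
covariate, and a pre/post indicator whose coefficient is the treatment
effect. Response enters only through a treatment:response interaction
(response is subject-constant, so its main effect is absorbed by the
subject indicators). All families of tests are Benjamini-Hochberg
corrected across cell types.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, spearman_grid

__all__ = [
    "wilcoxon_contrast",
    "treatment_effect",
    "response_interaction",
    "baseline_correlations",
    "direction_table",
]


def wilcoxon_contrast(
    scores: pd.DataFrame,
    groups: pd.Series,
    paired: bool = False,
    order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-cell-type two-group rank test with BH correction.

    ``groups`` maps sample -> one of exactly two labels; ``order`` gives
    (reference, comparison) labels (default: sorted label order), with
    estimate = median(comparison) - median(reference). Unpaired uses
    the two-sided Wilcoxon rank-sum (exact where SciPy allows); paired uses
    the signed-rank test on per-pair differences aligned by position within
    each group. All-tied inputs give p = 1 with a warning.
    """
    labels = sorted(groups.dropna().unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    if order is not None:
        if sorted(order) != labels:
            raise ValueError(f"order {order} does not match group labels {labels}")
        labels = list(order)
    a_idx = groups[groups == labels[0]].index
    b_idx = groups[groups == labels[1]].index
    min_n = 2
    if len(a_idx) < min_n or len(b_idx) < min_n:
        raise ValueError("need >=2 samples per group")
    if paired and len(a_idx) != len(b_idx):
        raise ValueError("paired mode needs equal-length groups")
    rows = []
    for cell in scores.columns:
        x = scores.loc[a_idx, cell].to_numpy(float)
        y = scores.loc[b_idx, cell].to_numpy(float)
        est = float(np.median(y) - np.median(x))
        if paired:
            d = y - x
            if np.all(d == 0):
                warnings.warn(f"{cell}: all paired differences zero; p=1")
                p = 1.0
            else:
                p = float(sps.wilcoxon(y, x, alternative="two-sided").pvalue)
        else:
            if np.ptp(np.concatenate([x, y])) == 0:
                warnings.warn(f"{cell}: all values tied; p=1")
                p = 1.0
            else:
                p = float(sps.mannwhitneyu(y, x, alternative="two-sided").pvalue)
        rows.append(
            {
                "cell_type": cell,
                "estimate": est,
                "p": p,
                "direction": "up" if est > 0 else ("down" if est < 0 else "none"),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def _paired_design(
    cohort: pd.DataFrame,
    covariates: tuple[str, ...],
    interaction: bool = False,
) -> tuple[np.ndarray, list[str], pd.Index]:
    """Fixed-effect design: intercept, subject indicators (reference =
    first subject), covariates, post indicator, optional post x responder."""
    meta = cohort.copy()
    counts = meta.groupby("subject")["timepoint"].agg(lambda t: sorted(t))
    keep = counts[counts.apply(lambda t: t == ["post", "pre"])].index
    dropped = set(meta["subject"]) - set(keep)
    if dropped:
        warnings.warn(f"dropping unpaired subjects: {sorted(dropped)}")
    meta = meta[meta["subject"].isin(keep)]
    subjects = sorted(meta["subject"].unique())
    cols: list[str] = ["intercept"]
    mats = [np.ones((len(meta), 1))]
    for s in subjects[1:]:
        mats.append((meta["subject"] == s).to_numpy(float)[:, None])
        cols.append(f"subject[{s}]")
    for cov in covariates:
        mats.append(meta[cov].to_numpy(float)[:, None])
        cols.append(cov)
    post = (meta["timepoint"] == "post").to_numpy(float)
    mats.append(post[:, None])
    cols.append("treatment")
    if interaction:
        resp = (meta["response"] == "responder").to_numpy(float)
        mats.append((post * resp)[:, None])
        cols.append("treatment:response")
    X = np.hstack(mats)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name aliased columns by checking rank drop when removed
        aliased = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                aliased.append(cols[j])
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    return X, cols, meta.index


def _ols_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS coefficients, their standard errors, and residual df."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    xtx_inv = np.linalg.inv(X.T @ X)
    if df > 0:
        s2 = float(resid @ resid) / df
    else:
        s2 = np.nan
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * s2, 0.0))
    return beta, se, df


def _coef_tests(X, cols, y, terms) -> dict[str, dict[str, float]]:
    beta, se, df = _ols_fit(X, y)
    out = {}
    for term in terms:
        j = cols.index(term)
        if se[j] == 0 or df <= 0 or not np.isfinite(se[j]):
            t = np.inf if beta[j] != 0 else 0.0
            p = 0.0 if beta[j] != 0 else 1.0
        else:
            t = beta[j] / se[j]
            p = float(2 * sps.t.sf(abs(t), df))
        out[term] = {"estimate": float(beta[j]), "t": float(t), "p": p, "df": df}
    return out


def treatment_effect(
    scores: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = ("gc_score",),
) -> pd.DataFrame:
    """Paired pre/post treatment effect per cell type.

    Fits ``cells ~ subject + covariates + treatment`` by OLS within one
    treated arm and returns the treatment (post-vs-pre) coefficient with
    t-test p and BH q across cell types.
    """
    X, cols, idx = _paired_design(cohort, covariates, interaction=False)
    rows = []
    for cell in scores.columns:
        res = _coef_tests(X, cols, scores.loc[idx, cell].to_numpy(float), ["treatment"])["treatment"]
        rows.append({"cell_type": cell, **res})
    out = pd.DataFrame(rows)
    out["direction"] = np.where(out["estimate"] > 0, "up", np.where(out["estimate"] < 0, "down", "none"))
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def response_interaction(
    scores: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = ("gc_score",),
    stratified_fdr: float = 0.1,
) -> dict[str, pd.DataFrame]:
    """Treatment x response interaction plus responder/non-responder strata.

    Returns ``{"model": ..., "responder": ..., "non-responder": ...}``. The
    model table reports both the treatment main effect (post-vs-pre in
    non-responders under this coding) and the interaction coefficient, BH
    corrected per term across cell types. The strata tables are paired
    signed-rank contrasts within each response class, flagged significant
    at ``q < stratified_fdr``.
    """
    classes = sorted(set(cohort["response"].dropna()) - {""})
    if len(classes) < 2:
        warnings.warn("single response class: interaction skipped")
        return {"model": pd.DataFrame(), "responder": pd.DataFrame(), "non-responder": pd.DataFrame()}
    X, cols, idx = _paired_design(cohort, covariates, interaction=True)
    rows = []
    for cell in scores.columns:
        res = _coef_tests(
            X, cols, scores.loc[idx, cell].to_numpy(float), ["treatment", "treatment:response"]
        )
        for term, d in res.items():
            rows.append({"cell_type": cell, "term": term, **d})
    model = pd.DataFrame(rows)
    model["q"] = np.nan
    for term in model["term"].unique():
        mask = model["term"] == term
        model.loc[mask, "q"] = bh_adjust(model.loc[mask, "p"].to_numpy())

    strata = {}
    for cls in ("responder", "non-responder"):
        sub = cohort[cohort["response"] == cls].sort_values(["subject", "timepoint"])
        paired_subj = sub.groupby("subject")["timepoint"].count()
        sub = sub[sub["subject"].isin(paired_subj[paired_subj == 2].index)]
        if sub["subject"].nunique() < 2:
            warnings.warn(f"too few paired {cls} subjects for stratified contrast")
            strata[cls] = pd.DataFrame()
            continue
        tbl = wilcoxon_contrast(
            scores.loc[sub.index],
            sub["timepoint"],
            paired=True,
            order=("pre", "post"),
        )
        tbl["significant"] = tbl["q"] < stratified_fdr
        strata[cls] = tbl
    return {"model": model, **strata}


def baseline_correlations(
    scores: pd.DataFrame,
    cohort: pd.DataFrame,
    variables: tuple[str, ...] = ("gc_score", "age"),
) -> pd.DataFrame:
    """Spearman correlation of baseline (pre) cell scores with clinical
    variables, BH corrected across the whole (cell x variable) grid."""
    base = cohort[cohort["timepoint"] == "pre"]
    if len(base) < 3:
        raise ValueError("need >=3 baseline samples")
    grid = spearman_grid(scores.loc[base.index], base[list(variables)])
    return grid.rename(columns={"left": "cell_type", "right": "variable"})


def direction_table(tables: dict[str, pd.DataFrame], fdr: float = 0.05) -> pd.DataFrame:
    """Heatmap-ready up/down/no-change calls per cell type across contrasts."""
    out = {}
    for contrast, tbl in tables.items():
        calls = np.where(tbl["q"] < fdr, tbl["direction"], "no-change")
        out[contrast] = pd.Series(calls, index=tbl["cell_type"].to_numpy())
    return pd.DataFrame(out)
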