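"""Treatment non-response prediction from baseline cell contributions.

An elastic-net-penalized logistic regression is tuned and evaluated under
nested cross-validation: each of ``outer_repeats`` repeats draws a
stratified 4/5 training split, tunes (l1_ratio, C) by mean AUC over
``inner_folds`` stratified folds of the training set, refits the winning
model on the full training set, and scores the held-out fifth by AUC-ROC
and precision-recall AUC. Features are inverse-rank normalized; the
positive class is non-response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .stats import inverse_rank_normalize

__all__ = [
    "PredictionConfig",
    "PredictionReport",
    "encode_labels",
    "prevalence",
    "rank_normalize_features",
    "nested_cv_elastic_net",
]


@dataclass(frozen=True)
class PredictionConfig:
    """Nested-CV settings; defaults follow the 4/5 split, tenfold inner CV,
    100-repeat scheme with AUC as the inner selection metric."""

    test_fraction: float = 0.2
    outer_repeats: int = 100
    inner_folds: int = 10
    l1_ratios: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))
    strengths: tuple[float, ...] = tuple(np.logspace(-2, 2, 20))
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_repeats < 1:
            raise ValueError("outer_repeats must be >= 1")
        if not self.l1_ratios or not self.strengths:
            raise ValueError("hyperparameter grids must be non-empty")


@dataclass
class PredictionReport:
    """Per-repeat and summary discrimination metrics.

    ``summary`` mirrors the usual report layout: mean/min/max AUC-ROC and
    PR-AUC plus sensitivity, specificity, precision, recall and F measure
    at the probability threshold.
    """

    per_repeat: pd.DataFrame
    summary: dict
    config: PredictionConfig = field(repr=False)


def encode_labels(response: pd.Series) -> pd.Series:
    """EULAR response labels -> binary non-responder flag (positive class).

    Accepts 'responder'/'non-responder' (case-insensitive) or the raw EULAR
    classes: Good/Moderate count as responder, None as non-responder.
    """
    mapping = {
        "responder": 0,
        "non-responder": 1,
        "good": 0,
        "moderate": 0,
        "none": 1,
    }
    out = response.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = sorted(response[out.isna()].astype(str).unique())
        raise ValueError(f"unrecognized response labels: {bad}")
    return out.astype(int)


def prevalence(labels: pd.Series | np.ndarray) -> float:
    """Fraction of positive (non-responder) labels."""
    arr = np.asarray(labels, dtype=float)
    if arr.size == 0:
        raise ValueError("empty label vector")
    return float(arr.mean())


def rank_normalize_features(features: pd.DataFrame) -> pd.DataFrame:
    """Inverse-rank normalize each feature column; constant columns are
    dropped with a warning (they carry no rank information)."""
    keep, dropped = {}, []
    for col in features.columns:
        x = features[col].to_numpy(float)
        if np.ptp(x) == 0:
            dropped.append(col)
            continue
        keep[col] = inverse_rank_normalize(x)
    if dropped:
        warnings.warn(f"dropping constant features: {dropped}")
    if not keep:
        raise ValueError("no non-constant features left")
    return pd.DataFrame(keep, index=features.index)


def _fit_enet(X, ylab, l1_ratio, C, seed) -> LogisticRegression:
    model = LogisticRegression(
        penalty="elasticnet",
        solver="saga",
        l1_ratio=l1_ratio,
        C=C,
        max_iter=5000,
        tol=1e-4,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", FutureWarning)  # sklearn penalty-arg deprecation
        model.fit(X, ylab)
    return model


def _inner_select(X, ylab, cfg: PredictionConfig, rng_seed: int) -> tuple[float, float]:
    """Mean inner-CV AUC per grid point; returns the winning (l1_ratio, C)."""
    n_folds = min(cfg.inner_folds, int(np.bincount(ylab).min()))
    n_folds = max(n_folds, 2)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rng_seed)
    folds = list(skf.split(X, ylab))
    # strengths scanned weakest-penalty first so AUC ties (e.g. perfectly
    # separable data) resolve to the least-regularized model
    strengths = sorted(cfg.strengths, reverse=True)
    best, best_auc = (cfg.l1_ratios[0], strengths[0]), -np.inf
    for l1 in cfg.l1_ratios:
        for C in strengths:
            aucs = []
            for tr, va in folds:
                if len(np.unique(ylab[va])) < 2:
                    continue
                model = _fit_enet(X[tr], ylab[tr], l1, C, rng_seed)
                prob = model.predict_proba(X[va])[:, 1]
                aucs.append(roc_auc_score(ylab[va], prob))
            mean_auc = float(np.mean(aucs)) if aucs else -np.inf
            if mean_auc > best_auc:
                best_auc, best = mean_auc, (l1, C)
    return best


def nested_cv_elastic_net(
    features: pd.DataFrame,
    labels: pd.Series,
    cfg: PredictionConfig = PredictionConfig(),
    pre_normalized: bool = False,
) -> PredictionReport:
    """Nested cross-validated elastic-net non-response classifier.

    ``features``: baseline samples x cell contributions. ``labels``: binary
    non-responder flags (1 = non-responder) aligned to ``features``.
    Deterministic given ``cfg.seed``.
    """
    X_df = features if pre_normalized else rank_normalize_features(features)
    X = X_df.to_numpy(float)
    ylab = np.asarray(labels.loc[X_df.index] if isinstance(labels, pd.Series) else labels, int)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    if len(np.unique(ylab)) < 2:
        raise ValueError("both classes must be present")

    outer = StratifiedShuffleSplit(
        n_splits=cfg.outer_repeats, test_size=cfg.test_fraction, random_state=cfg.seed
    )
    rows = []
    for rep, (tr, te) in enumerate(outer.split(X, ylab)):
        if len(np.unique(ylab[te])) < 2:  # guaranteed by stratification, guard anyway
            continue
        l1, C = _inner_select(X[tr], ylab[tr], cfg, rng_seed=cfg.seed + rep)
        model = _fit_enet(X[tr], ylab[tr], l1, C, cfg.seed + rep)
        prob = model.predict_proba(X[te])[:, 1]
        pred = (prob >= cfg.threshold).astype(int)
        tp = int(((pred == 1) & (ylab[te] == 1)).sum())
        tn = int(((pred == 0) & (ylab[te] == 0)).sum())
        fp = int(((pred == 1) & (ylab[te] == 0)).sum())
        fn = int(((pred == 0) & (ylab[te] == 1)).sum())
        rows.append(
            {
                "repeat": rep,
                "l1_ratio": l1,
                "C": C,
                "auc_roc": roc_auc_score(ylab[te], prob),
                "auc_pr": average_precision_score(ylab[te], prob),
                "tp": tp,
                "tn": tn,
                "fp": fp,
                "fn": fn,
                "n_nonzero_coef": int(np.sum(model.coef_ != 0)),
            }
        )
    per_repeat = pd.DataFrame(rows)
    tp, tn = per_repeat["tp"].sum(), per_repeat["tn"].sum()
    fp, fn = per_repeat["fp"].sum(), per_repeat["fn"].sum()
    se = tp / (tp + fn) if tp + fn else np.nan
    sp = tn / (tn + fp) if tn + fp else np.nan
    pr = tp / (tp + fp) if tp + fp else np.nan
    f = 2 * pr * se / (pr + se) if pr + se and np.isfinite(pr) and np.isfinite(se) else np.nan
    summary = {
        "auc_roc_mean": float(per_repeat["auc_roc"].mean()),
        "auc_roc_min": float(per_repeat["auc_roc"].min()),
        "auc_roc_max": float(per_repeat["auc_roc"].max()),
        "auc_pr_mean": float(per_repeat["auc_pr"].mean()),
        "auc_pr_min": float(per_repeat["auc_pr"].min()),
        "auc_pr_max": float(per_repeat["auc_pr"].max()),
        "sensitivity": float(se),
        "specificity": float(sp),
        "precision": float(pr),
        "recall": float(se),
        "f_measure": float(f),
        "prevalence": prevalence(ylab),
    }
    return PredictionReport(per_repeat=per_repeat, summary=summary, config=cfg)
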