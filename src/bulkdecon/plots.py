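"""The three standard figures: flow-vs-deconvolution correlation heatmap,
attribution scatter (-log10 q before vs after cell adjustment), and ROC /
precision-recall curves for the response classifier."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

_CATEGORY_COLORS = {"both": "tab:red", "pre-only": "tab:blue", "post-only": "tab:green",
                    "neither": "0.7"}


def flow_correlation_heatmap(grid: pd.DataFrame, path: str) -> None:
    """Heatmap of Spearman rho between scored and flow populations."""
    mat = grid.pivot(index="left", columns="right", values="rho")
    fig, ax = plt.subplots(figsize=(1.2 * mat.shape[1] + 2, 1.0 * mat.shape[0] + 1))
    im = ax.imshow(mat.to_numpy(float), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=45, ha="right")
    ax.set_yticks(range(mat.shape[0]), mat.index)
    ax.set_xlabel("flow population")
    ax.set_ylabel("deconvolved population")
    fig.colorbar(im, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def attribution_scatter(table: pd.DataFrame, path: str, fdr: float = 0.05) -> None:
    """-log10 q before vs after cell adjustment, colored by category."""
    eps = 1e-300
    x = -np.log10(table["q_before"].to_numpy(float) + eps)
    y = -np.log10(table["q_after"].to_numpy(float) + eps)
    fig, ax = plt.subplots(figsize=(5, 5))
    for cat, color in _CATEGORY_COLORS.items():
        mask = (table["category"] == cat).to_numpy()
        ax.scatter(x[mask], y[mask], s=8, c=color, label=cat, alpha=0.7)
    thr = -np.log10(fdr)
    ax.axvline(thr, ls=":", c="k", lw=0.8)
    ax.axhline(thr, ls=":", c="k", lw=0.8)
    ax.set_xlabel("-log10 FDR, technical covariates only")
    ax.set_ylabel("-log10 FDR, cell-adjusted")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def roc_pr_curves(y_true: np.ndarray, y_prob: np.ndarray, path: str) -> None:
    """ROC and precision-recall curves for one pooled prediction run."""
    from sklearn.metrics import precision_recall_curve, roc_curve

    fpr, tpr, _ = roc_curve(y_true, y_prob)
    prec, rec, _ = precision_recall_curve(y_true, y_prob)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(fpr, tpr)
    ax1.plot([0, 1], [0, 1], ls=":", c="0.5")
    ax1.set_xlabel("false positive rate")
    ax1.set_ylabel("true positive rate")
    ax1.set_title("ROC")
    ax2.plot(rec, prec)
    ax2.axhline(np.mean(y_true), ls=":", c="0.5")
    ax2.set_xlabel("recall")
    ax2.set_ylabel("precision")
    ax2.set_title("Precision-recall")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
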