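"""Marker-based cell-type deconvolution of bulk expression.

The cell contribution score is the coefficient of a non-negative least
squares fit of a sample's linear-scale CPM on unit-sum marker-gene
signature columns: an arbitrary-unit proxy for the RNA mass each cell type
contributes, comparable across samples normalized together. Validation
against flow cytometry uses rank (Spearman) correlation, since the score
and a measured proportion share only a monotone relationship.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .stats import spearman_grid

__all__ = ["MarkerSet", "select_markers", "cpm", "deconvolve", "correlate_with_flow"]


@dataclass
class MarkerSet:
    """Per-cell-type marker genes with their fold over the second-best type.

    A gene is a marker of at most one cell type. Cell types that end up
    with no markers are flagged unscoreable (and skipped by the solver).
    """

    markers: dict[str, pd.DataFrame]  # cell type -> frame(gene, fold) sorted
    unscoreable: list[str]

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for frame in self.markers.values():
            out.extend(frame["gene"])
        return out

    @property
    def scoreable_types(self) -> list[str]:
        return [t for t in self.markers if len(self.markers[t])]


def select_markers(
    ref: pd.DataFrame,
    min_fold: float = 4.0,
    max_per_type: int = 50,
    min_expr: float = 1.0,
) -> MarkerSet:
    """Pick marker genes: signature >= min_fold x the second-highest type.

    Fold is infinite when all other types are exactly zero. Per type the top
    ``max_per_type`` genes by (fold desc, gene id asc) are kept. Emits a
    warning for any type left without markers.
    """
    if min_fold <= 1:
        raise ValueError("min_fold must exceed 1")
    sig = ref.to_numpy(float)
    order = np.argsort(sig, axis=1)
    top_idx = order[:, -1]
    second = sig[np.arange(sig.shape[0]), order[:, -2]]
    top = sig[np.arange(sig.shape[0]), top_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(second > 0, top / second, np.inf)
    is_marker = (fold >= min_fold) & (top >= min_expr)

    markers: dict[str, pd.DataFrame] = {}
    unscoreable: list[str] = []
    for k, cell in enumerate(ref.columns):
        mask = is_marker & (top_idx == k)
        frame = pd.DataFrame({"gene": ref.index[mask], "fold": fold[mask]})
        frame = frame.sort_values(["fold", "gene"], ascending=[False, True], kind="stable")
        frame = frame.head(max_per_type).reset_index(drop=True)
        markers[cell] = frame
        if frame.empty:
            unscoreable.append(cell)
            warnings.warn(f"cell type {cell!r} has no markers at min_fold={min_fold}")
    return MarkerSet(markers=markers, unscoreable=unscoreable)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Linear-scale counts per million, per sample."""
    lib = counts.sum(axis=0).to_numpy(float)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    return counts / lib * 1e6


def deconvolve(
    expr: pd.DataFrame,
    ref: pd.DataFrame,
    markers: MarkerSet | None = None,
    normalize: str | None = None,
    is_cpm: bool = False,
) -> pd.DataFrame:
    """Estimate cell contribution scores by NNLS on marker genes.

    Parameters
    ----------
    expr
        Genes x samples counts (converted to CPM internally) or, with
        ``is_cpm=True``, an already linear-scale normalized matrix.
    ref
        Genes x cell-types signature matrix.
    markers
        Marker selection; defaults to :func:`select_markers` on ``ref``.
    normalize
        ``None`` leaves raw NNLS coefficients (arbitrary units, scale
        equivariant with the input); ``"sum1"`` projects each sample's
        scores onto the simplex.

    Returns samples x cell-types scores; unscoreable types get 0.
    """
    if markers is None:
        markers = select_markers(ref)
    marker_genes = [g for g in markers.genes if g in expr.index]
    dropped = len(markers.genes) - len(marker_genes)
    if dropped:
        warnings.warn(f"{dropped} marker genes missing from expression matrix; dropped")
    if not marker_genes:
        raise ValueError("no overlap between marker genes and expression matrix")

    x = expr if is_cpm else cpm(expr)
    x = x.loc[marker_genes]
    types = markers.scoreable_types
    A = ref.loc[marker_genes, types].to_numpy(float)
    colsum = A.sum(axis=0)
    if (colsum <= 0).any():
        bad = [t for t, s in zip(types, colsum) if s <= 0]
        raise ValueError(f"signature columns sum to zero on marker genes: {bad}")
    A = A / colsum  # unit-sum columns: coefficients are RNA-mass proxies

    scores = np.zeros((x.shape[1], len(ref.columns)))
    type_pos = [list(ref.columns).index(t) for t in types]
    for j, sample in enumerate(x.columns):
        coef, _ = nnls(A, x[sample].to_numpy(float))
        scores[j, type_pos] = coef
    out = pd.DataFrame(scores, index=x.columns, columns=ref.columns)
    if normalize == "sum1":
        total = out.sum(axis=1).replace(0, np.nan)
        out = out.div(total, axis=0).fillna(0.0)
    elif normalize is not None:
        raise ValueError(f"unknown normalize mode {normalize!r}")
    return out


def correlate_with_flow(
    scores: pd.DataFrame,
    flow: pd.DataFrame,
    aggregation_map: dict[str, tuple[str, ...]],
) -> dict[str, pd.DataFrame]:
    """Compare contribution scores with flow-cytometry proportions.

    Returns ``{"matrix": ..., "matched": ...}``: the full Spearman grid
    between every aggregated scored population and every flow population,
    and the per-matched-pair diagonal (population, n, rho, p, q).
    """
    missing = [t for members in aggregation_map.values() for t in members if t not in scores.columns]
    if missing:
        raise KeyError(f"aggregation map references unscored cell types: {sorted(set(missing))}")
    agg = pd.DataFrame(
        {pop: scores[list(members)].sum(axis=1) for pop, members in aggregation_map.items()}
    )
    grid = spearman_grid(agg, flow)
    matched = grid[grid["left"] == grid["right"]].copy()
    matched = matched.rename(columns={"left": "population"}).drop(columns="right")
    return {"matrix": grid, "matched": matched.reset_index(drop=True)}
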