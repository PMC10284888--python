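"""Random-effects meta-analysis of per-study cell-contribution differences.

Each study contributes a standardized mean difference (Hedges' g, the
small-sample-corrected Cohen's d) per cell type for the RA-vs-control
contrast. Studies are pooled per cell type with the DerSimonian-Laird
estimator: the between-study variance tau^2 is the method-of-moments
solution from Cochran's Q, and the pooled effect is the inverse-variance
weighted mean with weights 1 / (v_i + tau^2). BH correction runs across
cell types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

__all__ = ["StudyEffect", "hedges_g", "study_effects_from_scores", "random_effects_pool"]


@dataclass(frozen=True)
class StudyEffect:
    """One study's standardized effect for one cell type."""

    study: str
    cell_type: str
    effect: float  # Hedges' g
    variance: float
    n1: int
    n0: int

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("effect variance must be positive")
        if min(self.n1, self.n0) < 2:
            raise ValueError("need >=2 samples per arm")


def hedges_g(mean1: float, mean0: float, sd_pooled: float, n1: int, n0: int,
             study: str = "study", cell_type: str = "cell") -> StudyEffect:
    """Small-sample-corrected standardized mean difference.

    g = J * (mean1 - mean0) / sd_pooled with J = 1 - 3/(4*(n1+n0-2) - 1);
    sampling variance v = (n1+n0)/(n1*n0) + g^2 / (2*(n1+n0-2)).
    """
    if sd_pooled <= 0:
        raise ValueError("sd_pooled must be positive")
    if min(n1, n0) < 2:
        raise ValueError("need >=2 samples per arm")
    m = n1 + n0 - 2
    J = 1.0 - 3.0 / (4.0 * m - 1.0)
    g = J * (mean1 - mean0) / sd_pooled
    v = (n1 + n0) / (n1 * n0) + g**2 / (2.0 * m)
    return StudyEffect(study=study, cell_type=cell_type, effect=float(g),
                       variance=float(v), n1=int(n1), n0=int(n0))


def study_effects_from_scores(
    scores: pd.DataFrame,
    is_case: pd.Series,
    study: str,
) -> list[StudyEffect]:
    """Convert one cohort's contribution scores into per-cell-type study
    effects (case vs control Hedges' g with pooled SD)."""
    case_idx = is_case[is_case.astype(bool)].index
    ctrl_idx = is_case[~is_case.astype(bool)].index
    n1, n0 = len(case_idx), len(ctrl_idx)
    out = []
    for cell in scores.columns:
        x1 = scores.loc[case_idx, cell].to_numpy(float)
        x0 = scores.loc[ctrl_idx, cell].to_numpy(float)
        sp = np.sqrt(((n1 - 1) * x1.var(ddof=1) + (n0 - 1) * x0.var(ddof=1)) / (n1 + n0 - 2))
        if sp == 0:
            warnings.warn(f"{cell}: zero pooled SD in {study}; skipped")
            continue
        out.append(hedges_g(x1.mean(), x0.mean(), sp, n1, n0, study=study, cell_type=cell))
    return out


def _pool_one(y: np.ndarray, v: np.ndarray) -> dict:
    """DerSimonian-Laird pooling of one cell type's study effects."""
    k = y.size
    w = 1.0 / v
    y_fe = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - y_fe) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    pooled = float(np.sum(w_star * y) / np.sum(w_star))
    se = float(np.sum(w_star) ** -0.5)
    z = pooled / se
    p = float(2.0 * sps.norm.sf(abs(z)))
    return {
        "k": k,
        "pooled": pooled,
        "se": se,
        "z": float(z),
        "p": p,
        "Q": Q,
        "tau2": float(tau2),
        "weights": w_star / w_star.sum(),
    }


def random_effects_pool(effects: list[StudyEffect]) -> pd.DataFrame:
    """Pool study effects per cell type (DerSimonian-Laird random effects).

    Returns a cell-type-indexed frame with pooled effect, SE, z, p, BH q,
    heterogeneity Q, tau^2 and the number of studies k. Cell types with a
    single study are passed through with tau^2 marked NaN (undefined).
    """
    if not effects:
        raise ValueError("no study effects supplied")
    frame = pd.DataFrame(
        [{"study": e.study, "cell_type": e.cell_type, "y": e.effect, "v": e.variance} for e in effects]
    )
    rows = []
    for cell, grp in frame.groupby("cell_type", sort=True):
        y, v = grp["y"].to_numpy(), grp["v"].to_numpy()
        if len(grp) == 1:
            warnings.warn(f"{cell}: single study; pooled = study effect, tau2 undefined")
            se = float(np.sqrt(v[0]))
            z = y[0] / se
            rows.append(
                {
                    "cell_type": cell,
                    "k": 1,
                    "pooled": float(y[0]),
                    "se": se,
                    "z": float(z),
                    "p": float(2 * sps.norm.sf(abs(z))),
                    "Q": np.nan,
                    "tau2": np.nan,
                }
            )
            continue
        res = _pool_one(y, v)
        res.pop("weights")
        rows.append({"cell_type": cell, **res})
    out = pd.DataFrame(rows).set_index("cell_type")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
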