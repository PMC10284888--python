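"""Synthetic paired pre/post PBMC cohort generator with known ground truth.

Emulates the structure of a rheumatoid-arthritis treatment cohort: healthy
controls plus two treated arms (methotrexate in early disease, TNF inhibitor
in established disease), each subject sampled at two timepoints, with

* per-sample true cell fractions on the simplex over K blood cell types,
  drawn Dirichlet around group/timepoint-tilted means with a subject-level
  random effect so paired samples correlate;
* planted composition shifts (disease tilts, treatment tilts, and
  responder-specific treatment tilts);
* optional cell-intrinsic treatment effects: designated genes change
  expression within designated cell types after treatment, independently of
  composition;
* a latent glucocorticoid exposure per RA sample that multiplicatively
  scales a designated gene set;
* negative-binomial counts at a target library size; and
* a matched noisy flow-cytometry table over aggregated populations.

All randomness flows from explicit integer seeds; identical seed + config
gives byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CELL_TYPES",
    "DEFAULT_FLOW_MAP",
    "CohortDesign",
    "SampleTruth",
    "default_base_mean",
    "default_shift_spec",
    "default_response_spec",
    "generate_reference",
    "simulate_fractions",
    "simulate_counts",
    "simulate_flow",
    "simulate_cohort",
    "SyntheticCohort",
]

# 29-type blood roster. The subtype names follow the conventions of blood
# immune-cell deconvolution references (monocyte/Th/B/NK subsets); the exact
# roster is a documented stand-in, not a reconstruction of any proprietary
# signature collection.
DEFAULT_CELL_TYPES: tuple[str, ...] = (
    "classical monocyte",
    "non-classical monocyte",
    "intermediate monocyte",
    "Th1",
    "Th2",
    "Th17",
    "Treg",
    "naive CD4+ abT",
    "memory CD4+ abT",
    "naive CD8+ abT",
    "memory CD8+ abT",
    "effector CD8+ abT",
    "gamma-delta T",
    "MAIT",
    "NKT",
    "follicular helper T",
    "naive B",
    "memory B",
    "mature B",
    "plasma cell",
    "mature NK",
    "CD56bright NK",
    "plasmacytoid DC",
    "myeloid DC",
    "neutrophil",
    "eosinophil",
    "basophil",
    "platelet",
    "hematopoietic progenitor",
)

# Flow-cytometry populations -> constituent reference cell types.
DEFAULT_FLOW_MAP: dict[str, tuple[str, ...]] = {
    "Mature B cells": ("mature B",),
    "CD4+ T cells": (
        "Th1",
        "Th2",
        "Th17",
        "Treg",
        "naive CD4+ abT",
        "memory CD4+ abT",
        "follicular helper T",
    ),
    "Mature NK cells": ("mature NK",),
    "Monocytes": ("classical monocyte", "non-classical monocyte", "intermediate monocyte"),
    "CD8+ T cells": ("naive CD8+ abT", "memory CD8+ abT", "effector CD8+ abT"),
}

_BASE_WEIGHTS = {
    "classical monocyte": 0.15,
    "non-classical monocyte": 0.03,
    "intermediate monocyte": 0.03,
    "Th1": 0.04,
    "Th2": 0.03,
    "Th17": 0.02,
    "Treg": 0.02,
    "naive CD4+ abT": 0.12,
    "memory CD4+ abT": 0.08,
    "naive CD8+ abT": 0.06,
    "memory CD8+ abT": 0.05,
    "effector CD8+ abT": 0.03,
    "gamma-delta T": 0.03,
    "MAIT": 0.02,
    "NKT": 0.01,
    "follicular helper T": 0.01,
    "naive B": 0.05,
    "memory B": 0.03,
    "mature B": 0.04,
    "plasma cell": 0.005,
    "mature NK": 0.08,
    "CD56bright NK": 0.02,
    "plasmacytoid DC": 0.01,
    "myeloid DC": 0.01,
    "neutrophil": 0.02,
    "eosinophil": 0.005,
    "basophil": 0.005,
    "platelet": 0.01,
    "hematopoietic progenitor": 0.005,
}

GROUPS = ("healthy", "early-RA", "established-RA")
_GROUP_TREATMENT = {"healthy": "none", "early-RA": "MTX", "established-RA": "TNFi"}


@dataclass(frozen=True)
class CohortDesign:
    """Subject counts and per-arm non-responder fractions.

    Defaults mirror a cohort of 53 early-RA subjects starting methotrexate,
    37 established-RA subjects starting a TNF inhibitor, and 30 healthy
    controls, all sampled pre and ~3 months post; non-responder fractions
    of roughly 22% (MTX) and 29% (TNFi).
    """

    n_healthy: int = 30
    n_mtx: int = 53
    n_tnfi: int = 37
    nonresponder_frac_mtx: float = 13.0 / 60.0
    nonresponder_frac_tnfi: float = 12.0 / 42.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_healthy", "n_mtx", "n_tnfi"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("nonresponder_frac_mtx", "nonresponder_frac_tnfi"):
            f = getattr(self, name)
            if not 0.0 < f < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class SampleTruth:
    """Ground truth for one simulated cohort.

    fractions: samples x cell types, each row on the simplex.
    meta: per-sample metadata (subject, group, timepoint, treatment,
        response, age, pct_dup, gc_exposure).
    intrinsic_effects: rows (gene, lfc, cell_types) applied to post-treatment
        samples; ``cell_types`` is a tuple of type names or ``("all",)``.
    shift_spec: the (group, timepoint) -> {cell: tilt} map actually used.
    """

    fractions: pd.DataFrame
    meta: pd.DataFrame
    intrinsic_effects: pd.DataFrame
    shift_spec: dict = field(default_factory=dict)

    def validate(self) -> None:
        sums = self.fractions.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise AssertionError("fractions must sum to 1 per sample")
        if (self.fractions.to_numpy() < 0).any():
            raise AssertionError("fractions must be non-negative")


def default_base_mean(cell_types=DEFAULT_CELL_TYPES) -> pd.Series:
    """Baseline PBMC composition prior (normalized to the simplex)."""
    w = np.array([_BASE_WEIGHTS.get(c, 0.01) for c in cell_types], float)
    return pd.Series(w / w.sum(), index=list(cell_types))


def default_shift_spec() -> dict[tuple[str, str], dict[str, float]]:
    """Planted composition tilts per (group, timepoint), relative to the
    healthy baseline mean.

    Disease: monocytes (classical and non-classical) and Th1/Th2 up in both
    RA groups; mature NK down in both; B cells down in established RA but
    memory B up in early RA. Treatment: memory B / plasma cells and Th1/Th17
    down after MTX; mature B up after TNFi.
    """
    ra_common = {
        "classical monocyte": 1.6,
        "non-classical monocyte": 1.5,
        "Th1": 1.4,
        "Th2": 1.35,
        "mature NK": 0.7,
    }
    early_pre = dict(ra_common, **{"memory B": 1.3})
    est_pre = dict(ra_common, **{"naive B": 0.7, "mature B": 0.65, "memory B": 0.75})
    early_post = dict(early_pre)
    for cell, mult in {"memory B": 0.75, "plasma cell": 0.7, "Th1": 0.8, "Th17": 0.8}.items():
        early_post[cell] = early_post.get(cell, 1.0) * mult
    est_post = dict(est_pre)
    est_post["mature B"] = est_post["mature B"] * 1.45
    return {
        ("healthy", "pre"): {},
        ("healthy", "post"): {},
        ("early-RA", "pre"): early_pre,
        ("early-RA", "post"): early_post,
        ("established-RA", "pre"): est_pre,
        ("established-RA", "post"): est_post,
    }


def default_response_spec() -> dict[tuple[str, str], dict[str, float]]:
    """Extra post-treatment tilts applied only to responders: the treatment
    composition changes concentrate in the responding subjects (plasma-cell
    decrease under MTX; mature-B increase and monocyte decrease under TNFi).
    """
    return {
        ("early-RA", "post"): {"plasma cell": 0.8, "memory B": 0.85},
        ("established-RA", "post"): {"mature B": 1.2, "classical monocyte": 0.85},
    }


def generate_reference(
    n_genes: int,
    n_cell_types: int = 29,
    markers_per_type: int = 10,
    seed: int = 0,
    marker_fold: float = 8.0,
    cell_types: list[str] | None = None,
) -> pd.DataFrame:
    """Build a genes x cell-types signature matrix with planted markers.

    Background expression is drawn from a shared log-normal; each type then
    receives ``markers_per_type`` exclusive genes whose signature value is
    raised strictly above ``marker_fold`` times the second-highest type.
    """
    if cell_types is None:
        cell_types = list(DEFAULT_CELL_TYPES[:n_cell_types])
        if len(cell_types) < n_cell_types:
            cell_types += [f"cell type {i + 1}" for i in range(len(cell_types), n_cell_types)]
    if len(cell_types) != n_cell_types:
        raise ValueError("cell_types length must equal n_cell_types")
    if markers_per_type * n_cell_types > n_genes:
        raise ValueError(
            f"marker budget infeasible: {markers_per_type} markers x "
            f"{n_cell_types} types > {n_genes} genes"
        )
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    sig = rng.lognormal(mean=np.log(5.0), sigma=1.0, size=(n_genes, n_cell_types))
    # plant exclusive markers: first markers_per_type * K genes, round-robin free
    for k in range(n_cell_types):
        rows = range(k * markers_per_type, (k + 1) * markers_per_type)
        for g in rows:
            others = np.delete(sig[g], k)
            sig[g, k] = marker_fold * 1.5 * others.max()
    return pd.DataFrame(sig, index=genes, columns=cell_types)


def _subject_table(design: CohortDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    arms = [
        ("healthy", "H", design.n_healthy, None),
        ("early-RA", "M", design.n_mtx, design.nonresponder_frac_mtx),
        ("established-RA", "T", design.n_tnfi, design.nonresponder_frac_tnfi),
    ]
    for group, prefix, n, nr_frac in arms:
        for i in range(n):
            if nr_frac is None:
                response = ""
            else:
                response = "non-responder" if rng.random() < nr_frac else "responder"
            rows.append(
                {
                    "subject": f"{prefix}{i + 1:03d}",
                    "group": group,
                    "treatment": _GROUP_TREATMENT[group],
                    "response": response,
                    "age": float(np.clip(np.round(rng.normal(55.0, 12.0)), 20, 85)),
                }
            )
    return pd.DataFrame(rows)


def simulate_fractions(
    design: CohortDesign,
    shift_spec: dict | None = None,
    response_spec: dict | None = None,
    base_mean: pd.Series | None = None,
    subject_concentration: float = 12.0,
    sample_concentration: float = 300.0,
    gc_lognorm_mean: float = -0.5,
    gc_lognorm_sigma: float = 0.5,
    intrinsic_effects: pd.DataFrame | None = None,
    freeze_pairs: bool = False,
) -> SampleTruth:
    """Draw per-sample true cell fractions and cohort metadata.

    Fractions for subject *s* at timepoint *t* are Dirichlet with mean
    ``normalize(u_s * tilt(group, t) * response_tilt)`` where the subject
    deviation ``u_s`` is itself Dirichlet around the baseline composition;
    the shared ``u_s`` makes pre/post fractions of one subject correlate.
    Glucocorticoid exposure is log-normal for RA samples and zero for
    healthy controls. ``freeze_pairs`` copies each subject's pre fractions
    onto the post sample exactly (the intrinsic-effects-only regime, where
    any post-treatment expression change is cell-intrinsic by construction).
    """
    if base_mean is None:
        base_mean = default_base_mean()
    cells = list(base_mean.index)
    if shift_spec is None:  # default spec: silently restricted to the roster in use
        shift_spec = {
            key: {c: t for c, t in tilts.items() if c in cells}
            for key, tilts in default_shift_spec().items()
        }
    if response_spec is None:
        response_spec = {
            key: {c: t for c, t in tilts.items() if c in cells}
            for key, tilts in default_response_spec().items()
        }
    for spec in (shift_spec, response_spec):
        for key, tilts in spec.items():
            for cell, t in tilts.items():
                if cell not in cells:
                    raise KeyError(f"tilt references unknown cell type {cell!r} in {key}")
                if t < 0:
                    raise ValueError(f"negative tilt for {cell} in {key}")
    base = base_mean.to_numpy(float)
    base = base / base.sum()
    rng = np.random.default_rng(design.seed)
    subjects = _subject_table(design, rng)

    rows, meta_rows = [], []
    for _, subj in subjects.iterrows():
        u = rng.dirichlet(subject_concentration * base)
        for tp in ("pre", "post"):
            tilt = np.ones(len(cells))
            for cell, mult in shift_spec.get((subj["group"], tp), {}).items():
                tilt[cells.index(cell)] *= mult
            if subj["response"] == "responder":
                for cell, mult in response_spec.get((subj["group"], tp), {}).items():
                    tilt[cells.index(cell)] *= mult
            mean_t = u * tilt
            mean_t = mean_t / mean_t.sum()
            if freeze_pairs and tp == "post":
                frac = rows[-1]  # identical to this subject's pre sample
            else:
                frac = rng.dirichlet(sample_concentration * mean_t)
            gc = 0.0
            if subj["group"] != "healthy":
                gc = float(rng.lognormal(gc_lognorm_mean, gc_lognorm_sigma))
            rows.append(frac)
            meta_rows.append(
                {
                    "sample": f"{subj['subject']}_{tp}",
                    "subject": subj["subject"],
                    "group": subj["group"],
                    "timepoint": tp,
                    "treatment": subj["treatment"],
                    "response": subj["response"],
                    "age": subj["age"],
                    "pct_dup": float(np.clip(rng.normal(0.18, 0.04), 0.05, 0.6)),
                    "gc_exposure": gc,
                }
            )
    meta = pd.DataFrame(meta_rows).set_index("sample")
    fractions = pd.DataFrame(rows, index=meta.index, columns=cells)
    if intrinsic_effects is None:
        intrinsic_effects = pd.DataFrame(columns=["gene", "lfc", "cell_types"])
    truth = SampleTruth(
        fractions=fractions,
        meta=meta,
        intrinsic_effects=intrinsic_effects,
        shift_spec=shift_spec,
    )
    truth.validate()
    return truth


def simulate_counts(
    truth: SampleTruth,
    ref: pd.DataFrame,
    lib_size_mean: float = 1e6,
    lib_size_sigma: float = 0.25,
    dispersion: float = 0.1,
    gc_gene_set: list[str] | None = None,
    gc_loading: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw negative-binomial counts from the mixture forward model.

    Per-sample expected expression is the fraction-weighted sum of the
    signature columns; cell-intrinsic log2 effects are applied to the
    designated genes (within the designated cell types) of post-treatment
    samples; glucocorticoid-set genes are scaled by
    ``exp(loading * exposure)``; counts are then drawn NB with a shared
    dispersion at a log-normal library size. ``dispersion=0`` gives Poisson.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if gc_gene_set:
        missing = set(gc_gene_set) - set(ref.index)
        if missing:
            raise KeyError(f"gc_gene_set genes absent from reference: {sorted(missing)[:5]}")
    missing_intr = set(truth.intrinsic_effects.get("gene", pd.Series(dtype=str))) - set(ref.index)
    if missing_intr:
        raise KeyError(f"intrinsic-effect genes absent from reference: {sorted(missing_intr)[:5]}")

    rng = np.random.default_rng(seed)
    S = ref.to_numpy(float)  # genes x K
    cells = list(ref.columns)
    gene_pos = {g: i for i, g in enumerate(ref.index)}
    counts = np.zeros((S.shape[0], truth.fractions.shape[0]))

    for j, (sample, frac) in enumerate(truth.fractions.iterrows()):
        f = frac.to_numpy(float)
        mu = S @ f
        row = truth.meta.loc[sample]
        treated_post = row["timepoint"] == "post" and row["treatment"] != "none"
        if treated_post and len(truth.intrinsic_effects):
            for _, eff in truth.intrinsic_effects.iterrows():
                g = gene_pos[eff["gene"]]
                types = eff["cell_types"]
                scale = 2.0 ** float(eff["lfc"])
                if types == ("all",) or types == "all":
                    mu[g] *= scale
                else:
                    idx = [cells.index(c) for c in types]
                    base = S[g] @ f
                    bumped = base + (scale - 1.0) * (S[g, idx] @ f[idx])
                    mu[g] = bumped
        if gc_gene_set and row["gc_exposure"] > 0:
            for g in gc_gene_set:
                mu[gene_pos[g]] *= np.exp(gc_loading * row["gc_exposure"])
        lib = rng.lognormal(np.log(lib_size_mean), lib_size_sigma) if lib_size_sigma > 0 else lib_size_mean
        mean = mu / mu.sum() * lib
        if dispersion == 0:
            counts[:, j] = rng.poisson(mean)
        else:
            size = 1.0 / dispersion
            counts[:, j] = rng.negative_binomial(size, size / (size + mean))
    return pd.DataFrame(counts.astype(np.int64), index=ref.index, columns=truth.fractions.index)


def simulate_flow(
    truth: SampleTruth,
    aggregation_map: dict | None = None,
    cv_noise: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy flow-cytometry proportions for aggregated populations.

    measured = (sum of true fractions over the population's cell types)
    times a mean-one log-normal factor with coefficient of variation
    ``cv_noise``, clipped to [0, 1].
    """
    if cv_noise < 0:
        raise ValueError("cv_noise must be >= 0")
    if aggregation_map is None:  # default map restricted to the roster in use
        have = set(truth.fractions.columns)
        aggregation_map = {
            pop: tuple(m for m in members if m in have)
            for pop, members in DEFAULT_FLOW_MAP.items()
        }
        aggregation_map = {p: m for p, m in aggregation_map.items() if m}
    if not aggregation_map:
        warnings.warn("empty aggregation map: returning empty flow table")
        return pd.DataFrame(index=truth.fractions.index)
    known = set(truth.fractions.columns)
    for pop, members in aggregation_map.items():
        unknown = set(members) - known
        if unknown:
            raise KeyError(f"aggregation map for {pop!r} references unknown cell types: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out = {}
    for pop, members in aggregation_map.items():
        agg = truth.fractions[list(members)].sum(axis=1).to_numpy()
        if cv_noise > 0:
            noise = rng.lognormal(-0.5 * cv_noise**2, cv_noise, size=agg.size)
        else:
            noise = 1.0
        out[pop] = np.clip(agg * noise, 0.0, 1.0)
    return pd.DataFrame(out, index=truth.fractions.index)


@dataclass
class SyntheticCohort:
    """Bundle of everything one simulated cohort produces."""

    reference: pd.DataFrame
    truth: SampleTruth
    counts: pd.DataFrame
    flow: pd.DataFrame
    gc_gene_set: list[str]


def simulate_cohort(
    design: CohortDesign | None = None,
    n_genes: int = 2000,
    n_cell_types: int = 29,
    markers_per_type: int = 10,
    n_gc_genes: int = 40,
    n_intrinsic_genes: int = 0,
    intrinsic_lfc: float = 1.0,
    dispersion: float = 0.1,
    lib_size_mean: float = 1e6,
    cv_noise: float = 0.2,
    seed: int | None = None,
    **fraction_kwargs,
) -> SyntheticCohort:
    """End-to-end convenience: reference, truth, counts, flow, GC gene set.

    The glucocorticoid set and any intrinsic-effect genes are drawn from the
    non-marker background so they do not collide with deconvolution markers.
    """
    if design is None:
        design = CohortDesign(seed=0 if seed is None else seed)
    if seed is None:
        seed = design.seed
    ref = generate_reference(n_genes, n_cell_types, markers_per_type, seed=seed)
    rng = np.random.default_rng(seed + 1)
    background = list(ref.index[markers_per_type * n_cell_types:])
    gc_genes = list(rng.choice(background, size=min(n_gc_genes, len(background)), replace=False))
    remaining = [g for g in background if g not in set(gc_genes)]
    intrinsic = pd.DataFrame(columns=["gene", "lfc", "cell_types"])
    if n_intrinsic_genes > 0:
        picked = rng.choice(remaining, size=min(n_intrinsic_genes, len(remaining)), replace=False)
        intrinsic = pd.DataFrame(
            {"gene": picked, "lfc": intrinsic_lfc, "cell_types": [("all",)] * len(picked)}
        )
    fraction_kwargs.setdefault("base_mean", default_base_mean(ref.columns))
    truth = simulate_fractions(design, intrinsic_effects=intrinsic, **fraction_kwargs)
    counts = simulate_counts(
        truth,
        ref,
        lib_size_mean=lib_size_mean,
        dispersion=dispersion,
        gc_gene_set=gc_genes,
        seed=seed + 2,
    )
    flow = simulate_flow(truth, cv_noise=cv_noise, seed=seed + 3)
    return SyntheticCohort(reference=ref, truth=truth, counts=counts, flow=flow, gc_gene_set=gc_genes)
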