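"""End-to-end pipeline: simulate (optional) -> deconvolve -> GC score ->
cell statistics -> DGE attribution -> response prediction -> meta-analysis,
driven by one config dict with explicit seeds, writing TSV/JSON outputs and
a manifest of checksums (floats rounded to 10 significant digits before
hashing so checksums are platform-stable)."""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import cellstats, deconv, dge, io, meta, plots, predict, ssgsea, synthetic

__all__ = ["default_config", "run_pipeline"]


def default_config(out_dir: str = "bulkdecon_run", seed: int = 0) -> dict:
    """Config for a fully synthetic run with every stage enabled."""
    return {
        "out_dir": out_dir,
        "seed": seed,
        "stages": ["simulate", "deconvolve", "gc-score", "cell-stats", "dge", "predict", "meta"],
        "paths": {"counts": None, "metadata": None, "reference": None, "gmt": None},
        "simulate": {
            "n_genes": 2000,
            "n_cell_types": 29,
            "markers_per_type": 10,
            "n_intrinsic_genes": 0,
            "dispersion": 0.1,
        },
        "deconvolve": {"min_fold": 4.0, "max_per_type": 50, "min_expr": 1.0, "normalize": None},
        "gc_score": {"alpha": 0.25, "set_name": "GC_signature"},
        "cell_stats": {"fdr": 0.05, "stratified_fdr": 0.1},
        "dge": {"fdr": 0.05, "adjust_cells": None},
        "predict": {"outer_repeats": 20, "inner_folds": 5, "l1_ratios": [0.1, 0.5, 1.0],
                    "strengths": [0.01, 0.1, 1.0, 10.0]},
        "meta": {"n_studies": 3},
    }


def _checksum(obj) -> str:
    """Stable hash of a table/dict with floats at 10 significant digits."""

    def canon(x):
        if isinstance(x, float):
            return float(f"{x:.10g}") if np.isfinite(x) else str(x)
        if isinstance(x, dict):
            return {str(k): canon(v) for k, v in sorted(x.items(), key=lambda kv: str(kv[0]))}
        if isinstance(x, (list, tuple)):
            return [canon(v) for v in x]
        return x

    if isinstance(obj, pd.DataFrame):
        payload = canon(json.loads(obj.to_json(orient="split", double_precision=10)))
    else:
        payload = canon(obj)
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _load_inputs(cfg: dict, out: Path, seed: int, manifest: dict):
    """Either simulate a cohort or read counts/metadata/reference from disk."""
    stages = cfg["stages"]
    if "simulate" in stages:
        sim = synthetic.simulate_cohort(
            design=synthetic.CohortDesign(seed=seed), seed=seed, **cfg["simulate"]
        )
        io.write_counts(sim.counts, out / "counts.tsv")
        sim.truth.meta.to_csv(out / "metadata.csv")
        io.write_table(sim.truth.fractions, out / "truth_fractions.tsv", "true cell fractions")
        sim.flow.to_csv(out / "flow.csv")
        io.write_table(sim.reference, out / "reference.tsv", "signature matrix")
        io.write_gmt({"GC_signature": sim.gc_gene_set}, out / "gc_signature.gmt")
        manifest["stages"]["simulate"] = {"checksum": _checksum(sim.counts)}
        return sim.counts, sim.truth.meta, sim.reference, {"GC_signature": sim.gc_gene_set}, sim.flow
    paths = cfg["paths"]
    for key in ("counts", "metadata", "reference"):
        if not paths.get(key) or not Path(paths[key]).exists():
            raise FileNotFoundError(f"config path for {key!r} missing or absent: {paths.get(key)}")
    counts = io.read_counts(paths["counts"])
    meta_tbl = pd.read_csv(paths["metadata"], index_col=0)
    ref = io.read_table(paths["reference"])
    gene_sets = io.read_gmt(paths["gmt"]) if paths.get("gmt") else {}
    flow = pd.read_csv(paths["flow"], index_col=0) if paths.get("flow") else None
    return counts, meta_tbl, ref, gene_sets, flow


def run_pipeline(cfg: dict) -> dict:
    """Execute the configured stages; returns the run manifest."""
    stages = list(cfg["stages"])
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    if "gc-score" in stages and "simulate" not in stages and not cfg["paths"].get("gmt"):
        raise FileNotFoundError("gc-score stage enabled but no GMT path configured")

    manifest: dict = {"seed": seed, "config_checksum": _checksum(cfg), "stages": {}}
    counts, meta_tbl, ref, gene_sets, flow = _load_inputs(cfg, out, seed, manifest)

    scores = None
    if "deconvolve" in stages:
        dcfg = cfg["deconvolve"]
        markers = deconv.select_markers(
            ref, min_fold=dcfg["min_fold"], max_per_type=dcfg["max_per_type"], min_expr=dcfg["min_expr"]
        )
        scores = deconv.deconvolve(counts, ref, markers, normalize=dcfg.get("normalize"))
        io.write_table(scores, out / "cell_scores.tsv", "cell contribution scores")
        stage = {"checksum": _checksum(scores)}
        if flow is not None and not flow.empty:
            amap = {
                pop: tuple(c for c in members if c in scores.columns)
                for pop, members in synthetic.DEFAULT_FLOW_MAP.items()
                if pop in flow.columns
            }
            amap = {p: m for p, m in amap.items() if m}
            report = deconv.correlate_with_flow(scores, flow[list(amap)], amap)
            io.write_table(report["matched"], out / "flow_correlation.tsv", "flow validation", index=False)
            stage["flow_min_rho"] = float(report["matched"]["rho"].min())
            plots.flow_correlation_heatmap(report["matrix"], out / "flow_correlation.png")
        manifest["stages"]["deconvolve"] = stage

    if "gc-score" in stages:
        name = cfg["gc_score"]["set_name"]
        if name not in gene_sets:
            raise KeyError(f"gene set {name!r} not found in GMT")
        gc = ssgsea.ssgsea_score(
            counts, gene_sets[name], ssgsea.ScoreConfig(alpha=cfg["gc_score"]["alpha"]), name="gc_score"
        )
        meta_tbl = meta_tbl.assign(gc_score=gc)
        meta_tbl.to_csv(out / "metadata_with_gc.csv")
        manifest["stages"]["gc-score"] = {"checksum": _checksum(pd.DataFrame(gc))}
    elif "gc_score" not in meta_tbl.columns:
        meta_tbl = meta_tbl.assign(gc_score=0.0)

    if "cell-stats" in stages:
        if scores is None:
            raise RuntimeError("cell-stats requires the deconvolve stage")
        results = {}
        baseline = meta_tbl[meta_tbl["timepoint"] == "pre"]
        for group in ("early-RA", "established-RA"):
            grp_idx = baseline[baseline["group"].isin([group, "healthy"])].index
            results[f"disease_{group}"] = cellstats.wilcoxon_contrast(
                scores.loc[grp_idx], baseline.loc[grp_idx, "group"], paired=False
            )
            arm = meta_tbl[meta_tbl["group"] == group]
            results[f"treatment_{group}"] = cellstats.treatment_effect(scores.loc[arm.index], arm)
        corr = cellstats.baseline_correlations(scores, meta_tbl, variables=("gc_score", "age"))
        for name, tbl in results.items():
            io.write_table(tbl, out / f"cellstats_{name}.tsv", name, index=False)
        io.write_table(corr, out / "cellstats_baseline_correlations.tsv", "baseline", index=False)
        directions = cellstats.direction_table(results, fdr=cfg["cell_stats"]["fdr"])
        io.write_table(directions, out / "cellstats_directions.tsv", "direction heatmap")
        manifest["stages"]["cell-stats"] = {"checksum": _checksum(directions)}

    if "dge" in stages:
        if scores is None:
            raise RuntimeError("dge requires the deconvolve stage")
        dge_summaries = {}
        for group in ("early-RA", "established-RA"):
            arm = meta_tbl[meta_tbl["group"] == group]
            att = dge.run_attribution(
                counts, arm, scores, adjust_cells=cfg["dge"]["adjust_cells"], fdr=cfg["dge"]["fdr"]
            )
            io.write_table(att.table, out / f"dge_attribution_{group}.tsv", group)
            plots.attribution_scatter(att.table, out / f"dge_attribution_{group}.png", fdr=att.fdr)
            dge_summaries[group] = att.summary
        manifest["stages"]["dge"] = {"summaries": dge_summaries}

    if "predict" in stages:
        if scores is None:
            raise RuntimeError("predict requires the deconvolve stage")
        pcfg = cfg["predict"]
        reports = {}
        for group in ("early-RA", "established-RA"):
            base = meta_tbl[(meta_tbl["group"] == group) & (meta_tbl["timepoint"] == "pre")]
            labels = predict.encode_labels(base["response"])
            if labels.nunique() < 2:
                warnings.warn(f"{group}: single response class, prediction skipped")
                continue
            report = predict.nested_cv_elastic_net(
                scores.loc[base.index],
                labels,
                predict.PredictionConfig(
                    outer_repeats=pcfg["outer_repeats"],
                    inner_folds=pcfg["inner_folds"],
                    l1_ratios=tuple(pcfg["l1_ratios"]),
                    strengths=tuple(pcfg["strengths"]),
                    seed=seed,
                ),
            )
            io.write_table(report.per_repeat, out / f"prediction_{group}.tsv", group, index=False)
            reports[group] = report.summary
        (out / "prediction_summary.json").write_text(json.dumps(reports, indent=2))
        manifest["stages"]["predict"] = {"summaries": reports}

    if "meta" in stages:
        if scores is None:
            raise RuntimeError("meta requires the deconvolve stage")
        # split the cohort's baseline RA-vs-healthy contrast into pseudo-studies
        baseline = meta_tbl[meta_tbl["timepoint"] == "pre"]
        n_studies = int(cfg["meta"]["n_studies"])
        rng = np.random.default_rng(seed + 7)
        idx = baseline.index.to_numpy().copy()
        rng.shuffle(idx)
        effects = []
        for s, chunk in enumerate(np.array_split(idx, n_studies)):
            sub = baseline.loc[chunk]
            is_case = sub["group"] != "healthy"
            if is_case.sum() < 2 or (~is_case).sum() < 2:
                continue
            effects.extend(meta.study_effects_from_scores(scores.loc[chunk], is_case, f"study{s + 1}"))
        pooled = meta.random_effects_pool(effects)
        io.write_table(pooled, out / "meta_pooled.tsv", "random-effects meta-analysis")
        manifest["stages"]["meta"] = {"checksum": _checksum(pooled)}

    manifest["n_stages_completed"] = len(manifest["stages"])
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
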