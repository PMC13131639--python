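"""End-to-end pipeline orchestration with a YAML config and run manifest.

Stages run in dependency order (simulate -> normalize -> cluster -> de ->
markers -> score -> gsea -> spatial -> report); the manifest records
parameters, derived per-stage seeds, output paths and SHA-256 checksums,
and is sufficient to re-execute any stage in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import consensus, diffexpr, io_core, markers, scoring, simulate, spatial

log = logging.getLogger("synoclust")

STAGE_ORDER = ["simulate", "normalize", "cluster", "de", "markers",
               "score", "gsea", "spatial", "report"]

DEFAULT_STAGE_PARAMS: dict[str, dict] = {
    "simulate": {"n_samples": 60, "n_genes": 1200, "n_cells": 2000,
                 "n_spatial_cells": 5000, "log2_effect": 3.0,
                 "markers_per_cluster": 80},
    "normalize": {"pseudocount": 1.0},
    "cluster": {"n_genes": 500, "iterations": 200, "subsample": 0.8,
                "k_min": 2, "k_max": 6, "k": 4},
    "de": {"oarsi_threshold": 20, "expressed_min_frac": 0.1},
    "markers": {"lfc_min": 0.5, "frac_min": 0.4, "gap_min": 0.1,
                "top_n": 20},
    "score": {"k": 15},
    "gsea": {"n_perm": 200},
    "spatial": {},
    "report": {},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    stage_params: dict[str, dict] = field(default_factory=dict)
    master_seed: int = 0
    outdir: Path = Path("synoclust_out")
    log_level: str = "INFO"
    input_files: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")
        self.stages = [s for s in STAGE_ORDER if s in self.stages]
        self.outdir = Path(self.outdir)
        for name, path in self.input_files.items():
            if not Path(path).exists():
                raise FileNotFoundError(
                    f"config references missing input {name!r}: {path}")
        merged = {}
        for stage in STAGE_ORDER:
            merged[stage] = dict(DEFAULT_STAGE_PARAMS.get(stage, {}))
            merged[stage].update(self.stage_params.get(stage, {}))
        self.stage_params = merged

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            stages=raw.get("stages", list(STAGE_ORDER)),
            stage_params=raw.get("stage_params", {}),
            master_seed=int(raw.get("master_seed", 0)),
            outdir=Path(raw.get("outdir", "synoclust_out")),
            log_level=raw.get("log_level", "INFO"),
            input_files=raw.get("input_files", {}),
        )

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived deterministically from the master seed."""
        idx = STAGE_ORDER.index(stage)
        return int(np.random.SeedSequence(
            [self.master_seed, idx]).generate_state(1)[0])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute configured stages; return (and write) the run manifest."""
    logging.basicConfig(level=config.log_level)
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"master_seed": config.master_seed, "stages": {}}
    state: dict = {}
    for stage in config.stages:
        params = config.stage_params[stage]
        seed = config.stage_seed(stage)
        log.info("stage %s (seed %d)", stage, seed)
        try:
            outputs = _STAGE_FUNCS[stage](state, params, seed, out)
        except Exception:
            (out / "FAILED").write_text(stage)
            manifest["stages"][stage] = {"status": "failed"}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"stage {stage!r} failed") from None
        manifest["stages"][stage] = {
            "status": "ok", "seed": seed, "params": params,
            "outputs": {k: str(p) for k, p in outputs.items()},
            "checksums": {k: _sha256(Path(p)) for k, p in outputs.items()},
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _stage_simulate(state, params, seed, out: Path) -> dict:
    bulk_params = simulate.BulkSimParams(
        n_samples=params["n_samples"], n_genes=params["n_genes"],
        markers_per_cluster=params["markers_per_cluster"],
        log2_effect=params["log2_effect"], seed=seed)
    bulk, meta = simulate.simulate_bulk(bulk_params)
    sc = simulate.simulate_sc(simulate.ScSimParams(
        n_cells=params["n_cells"], seed=seed + 1))
    sp = simulate.simulate_spatial(simulate.SpatialSimParams(
        n_cells=params["n_spatial_cells"], seed=seed + 2))
    state.update(bulk=bulk, meta=meta, sc=sc, spatial=sp)
    paths = {
        "bulk_counts": out / "bulk_counts.csv",
        "metadata": out / "metadata.tsv",
        "spatial_cells": out / "spatial_cells.tsv",
        "truth_markers": out / "truth_markers.tsv",
    }
    io_core.write_expression(bulk, paths["bulk_counts"])
    io_core.write_metadata(meta, paths["metadata"])
    sp.write_tsv(paths["spatial_cells"])
    with open(paths["truth_markers"], "w") as fh:
        fh.write("scope\tlabel\tgene\n")
        for c, genes in getattr(meta, "true_markers", {}).items():
            for g in genes:
                fh.write(f"bulk_cluster\tC{c}\t{g}\n")
        for t, genes in getattr(sc, "true_markers", {}).items():
            for g in genes:
                fh.write(f"sc_type\t{t}\t{g}\n")
    return paths


def _stage_normalize(state, params, seed, out: Path) -> dict:
    state["logcpm"] = io_core.log_cpm(state["bulk"],
                                      pseudocount=params["pseudocount"])
    path = out / "bulk_logcpm.csv"
    io_core.write_expression(state["logcpm"], path)
    return {"bulk_logcpm": path}


def _stage_cluster(state, params, seed, out: Path) -> dict:
    mat = state["logcpm"]
    genes = consensus.select_variable_genes(
        mat, min(params["n_genes"], mat.n_genes))
    res = consensus.run_consensus(
        mat, genes, k_range=range(params["k_min"], params["k_max"] + 1),
        n_iterations=params["iterations"],
        subsample_fraction=params["subsample"], seed=seed)
    state["consensus"] = res
    k = params["k"]
    state["labels"] = np.array([f"C{c}" for c in res.assignments[k]])
    pca = consensus.pca_embed(mat, genes, n_components=10)
    state["pca"] = pca
    paths = {}
    for kk in res.k_range:
        p = out / f"consensus_K{kk}.csv"
        np.savetxt(p, np.nan_to_num(res.consensus[kk]), delimiter=",")
        paths[f"consensus_K{kk}"] = p
    import pandas as pd
    assign = pd.DataFrame({"sample_id": res.sample_ids, **{
        f"K{kk}": res.assignments[kk] for kk in res.k_range}})
    paths["assignments"] = out / "assignments.tsv"
    assign.to_csv(paths["assignments"], sep="\t", index=False)
    diag = pd.DataFrame({"K": res.k_range,
                         "auc": [res.auc[kk] for kk in res.k_range],
                         "delta_auc": [res.delta_auc[kk]
                                       for kk in res.k_range]})
    paths["cdf_auc"] = out / "cdf_auc.tsv"
    diag.to_csv(paths["cdf_auc"], sep="\t", index=False)
    return paths


def _stage_de(state, params, seed, out: Path) -> dict:
    mat, labels = state["logcpm"], state["labels"]
    paths = {}
    for target in sorted(set(labels)):
        res = diffexpr.de_cluster_vs_rest(
            mat, labels, target,
            expressed_min_frac=params["expressed_min_frac"])
        p = out / f"de_{target}_vs_rest.tsv"
        res.table.to_csv(p, sep="\t")
        paths[f"de_{target}"] = p
    de_oarsi = diffexpr.de_degeneration(
        mat, state["meta"], threshold=params["oarsi_threshold"],
        expressed_min_frac=params["expressed_min_frac"])
    state["de_oarsi"] = de_oarsi
    paths["de_oarsi"] = out / "de_oarsi.tsv"
    de_oarsi.table.to_csv(paths["de_oarsi"], sep="\t")
    return paths


def _stage_markers(state, params, seed, out: Path) -> dict:
    mset = markers.sc_markers(state["sc"], lfc_min=params["lfc_min"],
                              frac_min=params["frac_min"],
                              gap_min=params["gap_min"])
    state["markers"] = mset
    p = out / "markers.tsv"
    mset.to_frame().to_csv(p, sep="\t", index=False)
    enr = markers.loading_enrichment(state["pca"], mset, component=0)
    pe = out / "loading_enrichment.tsv"
    enr.to_csv(pe, sep="\t", index=False)
    return {"markers": p, "loading_enrichment": pe}


def _stage_score(state, params, seed, out: Path) -> dict:
    de = state["de_oarsi"]
    sc = state["sc"]
    pos = [g for g in de.up_genes() if g in sc.gene_ids]
    neg = [g for g in de.down_genes() if g in sc.gene_ids]
    paths = {}
    if pos and neg:
        sv = scoring.degeneration_score(sc, pos, neg)
        sv = scoring.knn_smooth(sv, sc.embedding,
                                k=min(params["k"], sc.n_cells - 1))
        summary = scoring.summarize_scores(sv, sc)
        paths["score_summary"] = out / "score_summary.tsv"
        summary.to_csv(paths["score_summary"], sep="\t", index=False)
    else:
        paths["score_summary"] = out / "score_summary.tsv"
        paths["score_summary"].write_text(
            "cell_type\tmedian\tp25\tp75\tn\n")
    return paths


def _stage_gsea(state, params, seed, out: Path) -> dict:
    de = state["de_oarsi"]
    ranked = de.table["log2_fold_change"]
    truth = getattr(state["meta"], "true_markers", {})
    sets = {f"cluster{c}_markers": genes for c, genes in truth.items()
            if len([g for g in genes if g in ranked.index]) >= 2}
    paths = {"gsea": out / "gsea.tsv"}
    if sets:
        coll = io_core.GeneSetCollection(sets, source="planted")
        df = scoring.gsea_collection(ranked, coll,
                                     n_perm=params["n_perm"], seed=seed)
        df.to_csv(paths["gsea"], sep="\t", index=False)
    else:
        paths["gsea"].write_text("set_name\tes\tnes\tp_value\tq_value\n")
    return paths


def _stage_spatial(state, params, seed, out: Path) -> dict:
    sp = state["spatial"]
    comp = spatial.composition(sp, "whole")
    zoom = spatial.composition(sp, "zoom")
    import pandas as pd
    paths = {"composition": out / "spatial_composition.tsv"}
    rows = [{"scope": s.scope, "cell_type": t, "count": c,
             "percent": s.percent(t, 1)}
            for s in (comp, zoom) for t, c in s.counts.items()]
    pd.DataFrame(rows).to_csv(paths["composition"], sep="\t", index=False)
    stats_df = spatial.detection_stats(sp, sp.genes)
    paths["detection"] = out / "spatial_detection.tsv"
    stats_df.to_csv(paths["detection"], sep="\t", index=False)
    enr = spatial.zoom_gene_enrichment(sp, "zoom", sp.genes)
    paths["gene_enrichment"] = out / "spatial_gene_enrichment.tsv"
    enr.to_csv(paths["gene_enrichment"], sep="\t", index=False)
    return paths


def _stage_report(state, params, seed, out: Path) -> dict:
    labels = state.get("labels")
    report = {}
    if labels is not None:
        report["cluster_percent"] = consensus.cluster_percentages(labels)
    if "consensus" in state:
        res = state["consensus"]
        report["delta_auc"] = {str(k): res.delta_auc[k] for k in res.k_range}
        report["suggested_k"] = consensus.suggest_k(res)
    if "spatial" in state:
        fold, rf, wf = spatial.region_fold_enrichment(
            state["spatial"], "zoom", "adipocyte", "whole_slide")
        report["adipocyte_zoom"] = {
            "fold": fold, "label": spatial.format_fold(fold),
            "zoom_percent": spatial.format_percent(rf, 2),
            "whole_percent": spatial.format_percent(wf, 2)}
    path = out / "report.json"
    path.write_text(json.dumps(report, indent=2))
    return {"report": path}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "normalize": _stage_normalize,
    "cluster": _stage_cluster,
    "de": _stage_de,
    "markers": _stage_markers,
    "score": _stage_score,
    "gsea": _stage_gsea,
    "spatial": _stage_spatial,
    "report": _stage_report,
}
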