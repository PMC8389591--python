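"""End-to-end orchestration: DE -> edge weighting -> module detection ->
survival screening -> hub selection, from a single config, with a run
manifest recording every artifact and count."""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import hubs as hub_mod
from . import io as sio
from . import modules as mod_detect
from . import preprocess, survival, weighting

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Paths, thresholds and strategy switches of one pipeline run."""

    expr: str | None = None
    surv: str | None = None
    edges: str | None = None
    classes: str | None = None
    gmt: str | None = None
    degs: str | None = None
    outdir: str = "survmod_out"

    lfc: float = 2.0
    alpha_de: float = 0.05
    alpha_surv: float = 0.05
    min_nodes: int = 6
    top_k: int = 10
    train_frac: float = 0.6
    enrich_alpha: float = 0.05
    enrich_top_n: int = 10

    stratify: str = "median_time"  # median_time | median_event_time
    module_filter: str = "nodes"  # nodes | edges
    correlation: str = "spearman"  # hub correlations: spearman | pearson
    run_de: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("lfc", "alpha_de", "alpha_surv", "min_nodes", "top_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (int(base_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class AnalysisResult:
    """In-memory result of one full analysis."""

    de: pd.DataFrame | None
    degs_up: list[str]
    degs_down: list[str]
    train_samples: list[str]
    test_samples: list[str]
    weighted_train: nx.Graph
    weighted_test: nx.Graph
    modules: list[mod_detect.Module]
    modules_filtered: list[mod_detect.Module]
    module_report: pd.DataFrame
    selected_module: mod_detect.Module | None
    rankings: dict[str, hub_mod.CentralityRanking]
    enrichment: list[hub_mod.EnrichmentResult]
    pathway_genes: set[str]
    hub_set: set[str]
    hub_corr: pd.DataFrame | None


def run_analysis(
    scaffold: nx.Graph,
    expr: pd.DataFrame,
    sample_class: pd.Series | None,
    surv: pd.DataFrame,
    gene_sets: dict[str, list[str]] | None = None,
    external_degs: list[str] | None = None,
    config: PipelineConfig | None = None,
) -> AnalysisResult:
    """Run the full analysis on in-memory inputs."""
    cfg = config or PipelineConfig()
    cfg.validate()
    expr = preprocess.collapse_duplicates(expr)

    # --- differential expression (restricts the scaffold to DEGs) ---
    de = None
    up: list[str] = []
    down: list[str] = []
    network = scaffold
    if cfg.run_de and sample_class is not None:
        de = preprocess.de_table(
            preprocess.moderated_t(expr, sample_class), cfg.lfc, cfg.alpha_de
        )
        up, down = preprocess.filter_degs(de, cfg.lfc, cfg.alpha_de)
        deg_set = set(up) | set(down)
        keep = [n for n in scaffold.nodes if n in deg_set]
        network = scaffold.subgraph(keep).copy()
        logger.info("DE: %d up, %d down; scaffold restricted to %d nodes", len(up), len(down), len(keep))

    # --- train/test split over tumor samples with survival records ---
    surv_idx = surv.set_index("sample_id") if "sample_id" in surv.columns else surv
    if sample_class is not None:
        tumor = [s for s in expr.columns if sample_class.get(s) == "tumor"]
    else:
        tumor = list(expr.columns)
    tumor = [s for s in tumor if s in surv_idx.index]
    train, test = weighting.split_train_test(
        tumor, cfg.train_frac, stage_seed(cfg.seed, "split")
    )

    # --- survival-stratified edge weighting, per partition ---
    network = network.subgraph([n for n in network.nodes if n in expr.index]).copy()
    strata_train = weighting.stratify_survival(surv_idx, train, cfg.stratify)
    strata_test = weighting.stratify_survival(surv_idx, test, cfg.stratify)
    w_train = weighting.weight_network(network, expr, strata_train)
    w_test = weighting.weight_network(network, expr, strata_test)

    # --- overlapping module detection on the training network ---
    modules = mod_detect.detect_modules(w_train) if w_train.number_of_edges() else []
    modules_f = mod_detect.filter_modules(modules, cfg.min_nodes, cfg.module_filter)

    # --- module survival screening in both partitions ---
    expr_train = expr.loc[:, train]
    expr_test = expr.loc[:, test]
    surv_train = surv_idx.loc[[s for s in train]]
    surv_test = surv_idx.loc[[s for s in test]]
    report = survival.evaluate_modules(
        modules_f, expr_train, surv_train, expr_test, surv_test, cfg.alpha_surv
    )

    selected = None
    if len(report) and report["significant_both"].any():
        sig = report[report["significant_both"]].copy()
        sig["worst_p"] = sig[["train_p", "test_p"]].max(axis=1)
        best_id = int(sig.sort_values(["worst_p", "module_id"]).iloc[0]["module_id"])
        selected = next(m for m in modules_f if m.id == best_id)

    # --- hub selection on the selected module ---
    rankings: dict[str, hub_mod.CentralityRanking] = {}
    enrichment: list[hub_mod.EnrichmentResult] = []
    pathway_genes: set[str] = set()
    hub_set: set[str] = set()
    hub_corr = None
    if selected is not None:
        sub = w_train.subgraph(selected.genes).copy()
        rankings["weighted_degree"] = hub_mod.rank_centrality(sub, "weighted_degree", cfg.top_k)
        rankings["eigenvector"] = hub_mod.rank_centrality(sub, "eigenvector", cfg.top_k)
        sets_to_intersect = [set(rankings["weighted_degree"].top_k), set(rankings["eigenvector"].top_k)]
        if gene_sets:
            enrichment = hub_mod.hypergeometric_enrichment(
                sorted(selected.genes), gene_sets, list(expr.index)
            )
            pathway_genes = hub_mod.significant_pathway_genes(
                enrichment, selected.genes, cfg.enrich_alpha, cfg.enrich_top_n
            )
            sets_to_intersect.append(pathway_genes)
        if external_degs is not None:
            sets_to_intersect.append(set(external_degs))
        hub_set = set.intersection(*sets_to_intersect)
        if hub_set:
            hub_corr = hub_mod.hub_correlations(
                expr.loc[:, [s for s in expr.columns if s in set(tumor)]],
                hub_set,
                cfg.correlation,
            )
    return AnalysisResult(
        de=de,
        degs_up=up,
        degs_down=down,
        train_samples=train,
        test_samples=test,
        weighted_train=w_train,
        weighted_test=w_test,
        modules=modules,
        modules_filtered=modules_f,
        module_report=report,
        selected_module=selected,
        rankings=rankings,
        enrichment=enrichment,
        pathway_genes=pathway_genes,
        hub_set=hub_set,
        hub_corr=hub_corr,
    )


def validate_inputs(config: PipelineConfig) -> list[dict]:
    """Consistency report across input files; returns issues, never raises."""
    issues: list[dict] = []

    def issue(kind: str, detail: str) -> None:
        issues.append({"issue": kind, "detail": detail})

    paths = {
        "expression matrix": config.expr,
        "survival table": config.surv,
        "edge list": config.edges,
    }
    loaded = {}
    for name, p in paths.items():
        if p is None or not Path(p).exists():
            issue("missing input", name)
            continue
        try:
            if name == "expression matrix":
                loaded[name] = sio.read_expression(p)
            elif name == "survival table":
                loaded[name] = sio.read_survival(p)
            else:
                loaded[name] = sio.read_edge_list(p)
        except Exception as exc:  # report, never raise
            issue("unreadable input", f"{name}: {exc}")

    expr = loaded.get("expression matrix")
    surv = loaded.get("survival table")
    edges = loaded.get("edge list")
    classes = None
    if config.classes and Path(config.classes).exists():
        classes = sio.read_sample_classes(config.classes)

    if expr is not None and surv is not None:
        known = set(expr.columns)
        for s in surv["sample_id"]:
            if s not in known:
                issue("unmatched sample", s)
    if expr is not None and edges is not None:
        known_g = set(expr.index)
        for g in edges.nodes:
            if g not in known_g:
                issue("unmatched gene", g)
    if classes is not None:
        counts = classes.value_counts()
        if counts.get("tumor", 0) < 2 or counts.get("normal", 0) < 2:
            issue("class imbalance", f"tumor={counts.get('tumor', 0)}, normal={counts.get('normal', 0)}")
    try:
        config.validate()
    except ValueError as exc:
        issue("bad threshold", str(exc))
    return issues


def _write_module_tables(result: AnalysisResult, outdir: Path) -> None:
    rows = [
        {"module_id": m.id, "gene": g}
        for m in result.modules_filtered
        for g in sorted(m.genes)
    ]
    pd.DataFrame(rows, columns=["module_id", "gene"]).to_csv(
        outdir / "modules.tsv", sep="\t", index=False
    )
    erows = [
        {"module_id": m.id, "u": u, "v": v, "D": w}
        for m in result.modules_filtered
        for (u, v, w) in m.edges
    ]
    pd.DataFrame(erows, columns=["module_id", "u", "v", "D"]).to_csv(
        outdir / "module_edges.tsv", sep="\t", index=False, float_format="%.10g"
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based end-to-end run; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    try:
        expr = sio.read_expression(config.expr)
    except Exception as exc:
        fail("load expression matrix", exc)
    try:
        surv = sio.read_survival(config.surv)
    except Exception as exc:
        fail("load survival table", exc)
    try:
        scaffold = sio.read_edge_list(config.edges)
    except Exception as exc:
        fail("load scaffold edge list", exc)
    classes = sio.read_sample_classes(config.classes) if config.classes else None
    gene_sets = sio.read_gmt(config.gmt) if config.gmt else None
    external = sio.read_gene_list(config.degs) if config.degs else None

    result = run_analysis(scaffold, expr, classes, surv, gene_sets, external, config)

    if result.de is not None:
        result.de.to_csv(outdir / "de_table.tsv", sep="\t", float_format="%.10g")
        stages["de"] = {
            "outputs": ["de_table.tsv"],
            "n_up": len(result.degs_up),
            "n_down": len(result.degs_down),
        }
    for name, net in (("train", result.weighted_train), ("test", result.weighted_test)):
        weighting.weighted_edge_table(net).to_csv(
            outdir / f"weighted_edges_{name}.tsv", sep="\t", index=False, float_format="%.10g"
        )
    stages["weighting"] = {
        "outputs": ["weighted_edges_train.tsv", "weighted_edges_test.tsv"],
        "n_nodes": result.weighted_train.number_of_nodes(),
        "n_edges": result.weighted_train.number_of_edges(),
        "n_train": len(result.train_samples),
        "n_test": len(result.test_samples),
    }
    _write_module_tables(result, outdir)
    stages["module_detection"] = {
        "outputs": ["modules.tsv", "module_edges.tsv"],
        "n_modules": len(result.modules),
        "n_modules_filtered": len(result.modules_filtered),
    }
    result.module_report.to_csv(outdir / "module_survival.tsv", sep="\t", index=False, float_format="%.10g")
    stages["module_survival"] = {
        "outputs": ["module_survival.tsv"],
        "n_significant_both": int(result.module_report["significant_both"].sum())
        if len(result.module_report)
        else 0,
        "selected_module": result.selected_module.id if result.selected_module else None,
    }
    rank_rows = [
        {"kind": kind, "rank": i + 1, "gene": g, "score": r.scores[g]}
        for kind, r in sorted(result.rankings.items())
        for i, g in enumerate(r.top_k)
    ]
    pd.DataFrame(rank_rows, columns=["kind", "rank", "gene", "score"]).to_csv(
        outdir / "centrality_rankings.tsv", sep="\t", index=False, float_format="%.10g"
    )
    enr_rows = [
        {
            "set_name": r.set_name,
            "overlap": r.overlap,
            "set_size": r.set_size,
            "query_size": r.query_size,
            "universe_size": r.universe_size,
            "p": r.p,
            "p_adj": r.p_adj,
            "overlap_genes": ",".join(r.overlap_genes),
        }
        for r in result.enrichment
    ]
    pd.DataFrame(
        enr_rows,
        columns=[
            "set_name", "overlap", "set_size", "query_size",
            "universe_size", "p", "p_adj", "overlap_genes",
        ],
    ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.10g")
    with open(outdir / "hub_set.json", "w") as fh:
        json.dump(sorted(result.hub_set), fh, indent=1)
    if result.hub_corr is not None:
        result.hub_corr.to_csv(outdir / "hub_correlations.tsv", sep="\t", float_format="%.10g")
    stages["hub_selection"] = {
        "outputs": ["centrality_rankings.tsv", "enrichment.tsv", "hub_set.json"],
        "n_hubs": len(result.hub_set),
        "hubs": sorted(result.hub_set),
    }

    manifest = {
        "config": dataclasses.asdict(config),
        "versions": {
            "survmod": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "networkx": nx.__version__,
        },
        "stages": stages,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
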