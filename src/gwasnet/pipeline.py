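"""End-to-end orchestration: score → build → extend → IVI → rank → enrich."""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, centrality, enrichment, interactome, io
from . import prioritization, scoring
from .config import PipelineConfig
from .exceptions import PipelineStageError, ValidationError


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Schema checks, duplicate detection and cross-file id consistency."""
    report = ValidationReport()
    for name in ("gene_table", "edge_list", "gene_map"):
        path = getattr(config, name)
        if not path or not Path(path).exists():
            report.errors.append(f"{name}: missing file {path!r}")
    if report.errors:
        return report
    try:
        records = io.read_gene_table(config.gene_table)
        scoring.validate_table(records, config.genome_wide_p)
    except ValidationError as exc:
        report.errors.append(f"gene_table: {exc}")
        return report
    network, _ = interactome.load_network(config.edge_list)
    gene_map = io.read_gene_map(config.gene_map)
    gene_ids = {r.gene_id for r in records}
    for g in gene_map:
        if g not in gene_ids:
            report.warnings.append(f"gene_map: gene {g!r} not in gene table")
    for g, prots in gene_map.items():
        for p in prots:
            if p not in network:
                report.warnings.append(
                    f"gene_map: protein {p!r} of gene {g!r} not in network")
    unmapped = gene_ids - set(gene_map)
    if unmapped:
        report.warnings.append(
            f"{len(unmapped)} gene(s) in the table have no protein mapping")
    if config.gene_sets and not Path(config.gene_sets).exists():
        report.errors.append(f"gene_sets: missing file {config.gene_sets!r}")
    return report


def _stage(name):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapper
    return decorate


def map_scores_to_proteins(score_table: pd.DataFrame,
                           gene_map: dict) -> pd.Series:
    """Carry each gene's score to every mapped protein.

    A protein mapped by several genes keeps the highest score.
    """
    values: dict = {}
    for gene, prots in gene_map.items():
        if gene not in score_table.index:
            continue
        s = float(score_table.at[gene, "score"])
        for p in prots:
            values[p] = max(values.get(p, float("-inf")), s)
    return pd.Series(values, name="score")


def run_all(config: PipelineConfig) -> dict:
    """Execute the whole pipeline and write every output table.

    Returns a dict with the in-memory results plus the manifest.  Any stage
    failure raises :class:`PipelineStageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_warnings: list[str] = []

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        records = _stage("load")(io.read_gene_table)(config.gene_table)
        _stage("load")(scoring.validate_table)(records, config.genome_wide_p)
        network, load_report = _stage("load")(
            interactome.load_network)(config.edge_list)
        gene_map = _stage("load")(io.read_gene_map)(config.gene_map)

        score_table = _stage("score")(scoring.compute_integrated_scores)(
            records, weights=config.weights,
            final_rescale=config.final_rescale_score,
            criterion1_k=config.criterion1_k)
        c1_genes = set(score_table.index[score_table["prioritized_c1"]])
        protein_scores = map_scores_to_proteins(score_table, gene_map)
        c1_proteins = {p for g in c1_genes
                       for p in gene_map.get(g, [])}

        gwas_proteins = {p for prots in gene_map.values() for p in prots}
        classification = _stage("build")(interactome.classify_bn_gn)(
            network, gwas_proteins)
        rbsp = _stage("extend")(interactome.rbsp_extend)(
            network, classification, path_policy=config.path_policy)

        ivi_rbsp = _stage("ivi")(centrality.compute_ivi)(
            rbsp.graph, radius=config.ci_radius,
            final_rescale=config.final_rescale_ivi)
        c2 = _stage("ivi")(centrality.prioritize_by_ivi)(
            ivi_rbsp, k=config.criterion2_k)

        prioritized_in_net = (c1_proteins & set(rbsp.graph.nodes))
        c3_res = _stage("criterion3")(prioritization.criterion3_subnetwork)(
            rbsp, prioritized_in_net)
        if c3_res.subgraph.number_of_nodes() >= 2:
            c3_table = _stage("criterion3")(prioritization.criterion3_rank)(
                c3_res.subgraph, radius=config.ci_radius,
                k=config.criterion2_k)
            ivi_c3 = c3_table["ivi"]
        else:
            c3_table = pd.DataFrame()
            ivi_c3 = pd.Series(dtype=float)
        c3 = c3_res.nodes

        ranking = _stage("combine")(prioritization.combine_and_rank)(
            c1_proteins, c2, c3, scores=protein_scores,
            ivi_rbsp=ivi_rbsp["ivi"], ivi_c3=ivi_c3,
            node_types=rbsp.classification.labels)

        enrich_table = pd.DataFrame()
        if config.gene_sets:
            collection = _stage("enrich")(
                enrichment.GeneSetCollection.from_gmt)(config.gene_sets)
            enrich_table = _stage("enrich")(enrichment.enrich)(
                set(rbsp.graph.nodes), collection,
                mode=config.enrichment_mode)
            enrich_table = enrichment.yn_pathway_flag(
                enrich_table, rbsp.classification.labels)

        run_warnings = [str(w.message) for w in caught]

    # ---- outputs -----------------------------------------------------
    io.write_tsv(score_table, out / "scores.tsv")
    node_rows = pd.DataFrame({
        "label": pd.Series(rbsp.classification.labels),
        "component": pd.Series(rbsp.classification.component_id),
        "distance_to_BN": pd.Series(rbsp.gn_distance),
    })
    node_rows.index.name = "node"
    io.write_tsv(node_rows.sort_index(), out / "node_classes.tsv")
    io.write_tsv(ivi_rbsp, out / "ivi_rbsp.tsv")
    if len(c3_table):
        io.write_tsv(c3_table, out / "criterion3_ivi.tsv")
    io.write_tsv(ranking, out / "ranking.tsv")
    if len(enrich_table):
        io.write_tsv(
            enrich_table.assign(
                overlap=enrich_table["overlap"].map(
                    lambda s: ";".join(sorted(s)))),
            out / "enrichment.tsv")

    summary = {
        "scores": scoring.score_summary(records, score_table),
        "network": interactome.network_summary(
            rbsp.graph, network, hub_threshold=config.hub_threshold),
        "load_report": vars(load_report),
        "n_bn": len(rbsp.classification.nodes_with("BN")),
        "n_gn": len(rbsp.classification.nodes_with("GN")),
        "n_yn": len(rbsp.yn_set),
        "n_unreachable_gn": len(rbsp.unreachable_gns),
        "fraction_gn_within_two": rbsp.fraction_gn_within_two,
        "n_c1": len(c1_proteins), "n_c2": len(c2), "n_c3": len(c3),
        "n_prioritized_union": len(ranking),
        "per_group_counts": ranking["group"].value_counts().to_dict()
        if len(ranking) else {},
    }
    io.write_json(summary, out / "summary.json")

    manifest = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "warnings": sorted(set(run_warnings)),
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    io.write_json(manifest, out / "manifest.json")

    return {
        "records": records, "score_table": score_table,
        "network": network, "classification": rbsp.classification,
        "rbsp": rbsp, "ivi_rbsp": ivi_rbsp,
        "c1_genes": c1_genes, "c1_proteins": c1_proteins,
        "c2": c2, "c3": c3, "c3_table": c3_table,
        "ranking": ranking, "enrichment": enrich_table,
        "summary": summary, "manifest": manifest,
    }
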