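"""End-to-end orchestration of the network-pharmacology workflow.

Stage order mirrors the study design: consensus targets -> C-T network
-> topological hubs -> MCODE cluster -> consensus hub targets ->
confidence-filtered PPI subnetwork -> pathway/process enrichment, with
non-compartmental PK analysis as an independent stage when
concentration data are supplied.  Every stage writes a TSV artifact,
and a JSON manifest records input hashes, parameters and the headline
counts so downstream checks never have to re-parse tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io, mcode, nca, network, ppi, topology
from .enrich import (ALPHA_BIOLOGICAL_PROCESS, ALPHA_PATHWAY,
                     enrich as run_enrichment, terms_from_gmt,
                     write_enrichment_tsv)

log = logging.getLogger("netpharm")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    compound_targets: str
    disease_targets: str
    ppi_edges: str
    out_dir: str
    gmt_bp: str | None = None
    gmt_pathway: str | None = None
    concentrations: str | None = None
    mcode_params: mcode.MCODEParams = field(default_factory=mcode.MCODEParams)
    min_ppi_score: float = ppi.HIGHEST_CONFIDENCE
    alpha_bp: float = ALPHA_BIOLOGICAL_PROCESS
    alpha_pathway: float = ALPHA_PATHWAY
    enrichment_sided: str = "two"
    auc_method: str = "linear"
    rng_seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        mc = raw.pop("mcode_params", None)
        cfg = cls(**raw)
        if mc:
            cfg.mcode_params = mcode.MCODEParams(**mc)
        return cfg

    def validate(self) -> None:
        for key in ("compound_targets", "disease_targets", "ppi_edges",
                    "gmt_bp", "gmt_pathway", "concentrations"):
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"config key {key!r}: no such file: {val}")
        if not 0.0 <= self.min_ppi_score <= 1.0:
            raise ValueError("min_ppi_score must be in [0,1]")


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return (and write) the run manifest.

    Identical config + inputs yield an identical manifest.  On stage
    failure a ``FAILED`` marker naming the stage is left in the output
    directory, partial outputs are retained, and :class:`PipelineError`
    is raised.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "inputs": {
            key: {"path": str(getattr(config, key)), "sha256": _sha256(getattr(config, key))}
            for key in ("compound_targets", "disease_targets", "ppi_edges",
                        "gmt_bp", "gmt_pathway", "concentrations")
            if getattr(config, key) is not None
        },
        "params": {
            "mcode": vars(config.mcode_params).copy(),
            "min_ppi_score": config.min_ppi_score,
            "alpha_bp": config.alpha_bp,
            "alpha_pathway": config.alpha_pathway,
            "enrichment_sided": config.enrichment_sided,
            "auc_method": config.auc_method,
            "rng_seed": config.rng_seed,
        },
        "counts": {},
    }
    counts = manifest["counts"]
    stage = "targets"
    try:
        ct_map = io.read_compound_target_table(config.compound_targets)
        disease = network.TargetSet("disease", io.read_gene_list(config.disease_targets))
        compound_union = network.union_compound_targets(ct_map)
        consensus = network.intersect_targets(compound_union, disease)
        io.write_gene_list(consensus.symbols, out / "consensus_targets.txt")
        counts["compound_target_union"] = len(compound_union)
        counts["disease_targets"] = len(disease)
        counts["consensus_targets"] = len(consensus)
        log.info("targets: %d union, %d disease, %d consensus",
                 len(compound_union), len(disease), len(consensus))

        stage = "network"
        net = network.build_ct_network(ct_map, consensus)
        network.write_sif(net, out / "ct_network.sif")
        network.write_graphml(net, out / "ct_network.graphml")
        counts["ct_nodes"] = net.graph.number_of_nodes()
        counts["ct_compounds"] = len(net.compound_nodes)
        counts["ct_targets"] = len(net.target_nodes)
        counts["ct_edges"] = net.graph.number_of_edges()

        stage = "topology"
        topo = topology.node_topology(net.graph)
        topology.write_topology_tsv(topology.rank_nodes(topo), out / "ct_topology.tsv")
        hub_graph, threshold = topology.extract_major_hub_network(net.graph)
        hub_targets = sorted(set(hub_graph.nodes()) & net.target_nodes)
        hub_compounds = sorted(set(hub_graph.nodes()) & net.compound_nodes)
        io.write_gene_list(hub_targets, out / "major_hub_targets.txt")
        counts["hub_threshold_mean_neighbors"] = threshold.mean_neighbors
        counts["major_hub_targets"] = len(hub_targets)
        counts["major_hub_compounds"] = len(hub_compounds)

        stage = "mcode"
        clusters = mcode.find_clusters(net.graph, config.mcode_params)
        mcode.write_clusters_tsv(clusters, out / "clusters.tsv")
        counts["clusters"] = len(clusters)
        counts["cluster_sizes"] = [c.size for c in clusters]
        top_cluster = clusters[0].members if clusters else frozenset()

        stage = "hubs"
        consensus_hubs = ppi.intersect_hubs(hub_targets, top_cluster)
        io.write_gene_list(consensus_hubs, out / "hub_targets.txt")
        counts["consensus_hub_targets"] = len(consensus_hubs)

        stage = "ppi"
        edges = io.read_scored_edges(config.ppi_edges)
        filtered = ppi.filter_ppi_edges(edges, config.min_ppi_score)
        io.write_scored_edges(filtered, out / "ppi_filtered.tsv")
        ppi_graph = ppi.build_ppi_network(filtered, consensus_hubs)
        ppi.write_ppi_sif(ppi_graph, out / "ppi_network.sif")
        ppi_topo = topology.node_topology(ppi_graph)
        topology.write_topology_tsv(topology.rank_nodes(ppi_topo), out / "ppi_topology.tsv")
        report = ppi.make_hub_report(hub_targets, top_cluster, ppi_graph.nodes())
        counts["ppi_nodes"] = ppi_graph.number_of_nodes()
        counts["ppi_edges"] = ppi_graph.number_of_edges()
        counts["predicted_functional_genes"] = len(report.predicted_functional)

        stage = "enrich"
        query = network.TargetSet("consensus", consensus.symbols)
        for key, gmt_path, alpha, label in (
            ("significant_bp_terms", config.gmt_bp, config.alpha_bp, "bp"),
            ("significant_pathway_terms", config.gmt_pathway, config.alpha_pathway, "pathway"),
        ):
            if gmt_path is None:
                continue
            terms = terms_from_gmt(io.read_gmt(gmt_path))
            res = run_enrichment(query, terms, alpha=alpha,
                                 sided=config.enrichment_sided)
            write_enrichment_tsv(res, out / f"enrichment_{label}.tsv")
            counts[key] = int(res["significant"].sum())

        stage = "nca"
        if config.concentrations is not None:
            summary = nca.run_nca(config.concentrations, out / "nca_summary.tsv",
                                  auc_method=config.auc_method,
                                  per_subject_tsv=out / "nca_per_subject.tsv")
            counts["nca_compounds"] = len(summary)
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n", encoding="utf-8")
        raise PipelineError(stage, exc) from exc

    manifest_json = json.dumps(manifest, indent=2, sort_keys=True)
    (out / "manifest.json").write_text(manifest_json + "\n", encoding="utf-8")
    manifest["manifest_sha256"] = hashlib.sha256(manifest_json.encode()).hexdigest()
    return manifest
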