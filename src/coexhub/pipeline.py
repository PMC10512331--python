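"""End-to-end pipeline driver: normalize -> DE -> filter -> network ->
cluster -> select, with every intermediate written to disk and a run
manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Mapping

import pandas as pd

import coexhub
from coexhub.data_model import (
    CountMatrix,
    GeneAnnotation,
    PipelineConfig,
)
from coexhub.enrichment import NOISE, TargetSelection, cluster_genes, select_targets
from coexhub.network import CoexpressionNetwork, build_consensus
from coexhub.normalize_de import (
    NormalizationResult,
    cpm_matrix,
    estimate_common_dispersion,
    run_de,
    timepoint_contrasts,
    tmm_factors,
    write_de_table,
)
from coexhub.secretome_kog import filter_secreted, heatmap_matrix, kog_radar_counts

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    norm: NormalizationResult
    dispersion: float
    de: pd.DataFrame
    secreted_degs: pd.DataFrame
    network: CoexpressionNetwork
    clusters: dict[str, int]
    targets: TargetSelection
    manifest: dict = field(default_factory=dict)


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_all(counts: CountMatrix, annotation: Mapping[str, GeneAnnotation],
            config: PipelineConfig | None = None,
            out_dir: str | Path | None = None,
            raw_network: bool = False,
            cluster_all_genes: bool = False,
            subgraph_centrality: bool = False,
            input_digests: dict | None = None) -> PipelineResult:
    """Run every stage of the target-enrichment pipeline.

    Stages: TMM normalization, common-dispersion estimation, per-timepoint
    exact-test DE with BH correction and calling, secretion filtering, KOG
    summaries, consensus network construction (on log-CPM by default, on
    raw counts with ``raw_network=True``), PCA + DBSCAN clustering of the
    secreted-DEG expression profiles (all genes with
    ``cluster_all_genes=True``), and per-cluster betweenness target
    selection.  With ``out_dir`` set, writes every intermediate plus a
    ``manifest.json`` capturing the configuration, package version and
    input digests.  Any stage failure raises :class:`PipelineStageError`
    naming the stage.
    """
    config = config or PipelineConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            logger.info("stage %s", name)
            return fn()
        except PipelineStageError:
            raise
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
            raise PipelineStageError(name, exc) from exc

    norm = stage("tmm_factors", lambda: tmm_factors(counts))
    groups = [f"{s.strain}|{s.condition}|{s.timepoint_h}" for s in counts.samples]
    phi = stage("estimate_common_dispersion",
                lambda: estimate_common_dispersion(counts, groups, norm))
    contrasts = stage("timepoint_contrasts", lambda: timepoint_contrasts(counts))
    de = stage("differential_expression",
               lambda: run_de(counts, norm, contrasts, phi, config))
    called = de[de["call"] != "ns"]
    secreted = stage("filter_secreted",
                     lambda: filter_secreted(called, annotation,
                                             config.signalp_threshold))
    kog = stage("kog_radar_counts",
                lambda: kog_radar_counts(secreted, annotation,
                                         config.kog_focus_categories))

    logcpm = stage("cpm_matrix",
                   lambda: cpm_matrix(counts, norm, log=True,
                                      prior_count=config.prior_count))
    net_expr = counts.to_frame().astype(float) if raw_network else logcpm
    net = stage("build_consensus",
                lambda: build_consensus(net_expr, config.network_methods,
                                        config.edge_threshold_per_method,
                                        config.consensus_min_support))

    if cluster_all_genes:
        cluster_gene_ids = list(logcpm.index)
    else:
        cluster_gene_ids = sorted(set(secreted["gene_id"].astype(str)))
    if len(cluster_gene_ids) < config.n_components + 1:
        raise PipelineStageError(
            "cluster_genes",
            ValueError(f"only {len(cluster_gene_ids)} genes available for "
                       "clustering; need more than n_components"))
    clusters, pca_res = stage(
        "cluster_genes",
        lambda: cluster_genes(logcpm.loc[cluster_gene_ids], config))
    targets = stage("select_targets",
                    lambda: select_targets(clusters, net,
                                           subgraph=subgraph_centrality))

    manifest = {
        "package": "coexhub",
        "version": coexhub.__version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "seed": config.random_seed,
        "input_digests": input_digests or {},
        "dispersion": phi,
        "n_genes": counts.n_genes,
        "n_samples": counts.n_samples,
        "n_clusters": len({l for l in clusters.values() if l != NOISE}),
        "outputs": {},
    }

    if out is not None:
        paths = {
            "normalization": out / "normalization.tsv",
            "de": out / "de.tsv",
            "secreted_degs": out / "secreted_degs.tsv",
            "kog_summary": out / "kog_summary.tsv",
            "heatmap": out / "heatmap.tsv",
            "network_edges": out / "network_edges.tsv",
            "network_graphml": out / "network.graphml",
            "pca_scores": out / "pca_scores.tsv",
            "clusters": out / "clusters.tsv",
            "targets": out / "targets.tsv",
        }
        pd.DataFrame({
            "sample_id": norm.sample_ids,
            "library_size": norm.library_sizes,
            "tmm_factor": norm.tmm_factors,
            "effective_library_size": norm.effective_library_sizes,
        }).to_csv(paths["normalization"], sep="\t", index=False)
        write_de_table(de, paths["de"])
        write_de_table(secreted, paths["secreted_degs"])
        kog.write(paths["kog_summary"])
        heat_genes = sorted(set(secreted["gene_id"].astype(str)))
        if heat_genes:
            heatmap_matrix(de, heat_genes, config).write(paths["heatmap"])
        net.write_edges(paths["network_edges"])
        net.write_graphml(paths["network_graphml"])
        scores = pca_res.scores.copy()
        scores.index.name = "gene_id"
        scores.to_csv(paths["pca_scores"], sep="\t")
        pd.DataFrame({
            "gene_id": list(clusters.keys()),
            "cluster": list(clusters.values()),
        }).to_csv(paths["clusters"], sep="\t", index=False)
        targets.write(paths["targets"])
        manifest["outputs"] = {k: str(v) for k, v in paths.items()}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(norm=norm, dispersion=phi, de=de,
                          secreted_degs=secreted, network=net,
                          clusters=clusters, targets=targets,
                          manifest=manifest)
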