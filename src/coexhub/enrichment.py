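"""Target enrichment: PCA, density clustering and centrality-based selection.

Gene expression profiles are projected onto their top principal
components (three by default), the per-component scores are standardized
so the DBSCAN radius is scale-free, and genes are grouped by density
clustering.  Betweenness centrality is then computed once on the full
consensus co-expression network, and within every non-noise cluster the
most central member is selected as a putative target.  The rationale: a
cluster groups genes with similar temporal expression, and the member
most often lying on shortest paths between other genes is the best
single-gene proxy for the cluster's role in the wider transcriptional
program ("hub" genes, hypothesized to have outsized phenotypic impact
when perturbed).

DBSCAN here is implemented directly rather than delegated, because target
selection requires a fully deterministic border-point rule: points are
processed in lexicographic gene-ID order, clusters are created in that
order, and a border point belongs to the first-created cluster that
density-reaches it.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.decomposition import PCA as _SkPCA

from coexhub.data_model import DataModelError, PipelineConfig
from coexhub.network import CoexpressionNetwork, max_degree_gene

logger = logging.getLogger(__name__)

#: Reserved DBSCAN label for unclustered (noise) genes.
NOISE = -1


@dataclass
class PcaResult:
    """Scores (genes x components), loadings (samples x components) and
    the fraction of variance each component explains."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_fraction: np.ndarray


@dataclass(frozen=True)
class ClusterTarget:
    cluster_id: int
    target_gene: str
    centrality: float
    cluster_size: int


@dataclass
class TargetSelection:
    """One most-central gene per non-noise cluster, plus the global
    max-degree hub."""

    cluster_targets: list[ClusterTarget]
    unique_targets: list[str]
    hub_gene: str
    hub_degree: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"cluster_id": t.cluster_id, "target_gene": t.target_gene,
                 "centrality": t.centrality, "cluster_size": t.cluster_size}
                for t in self.cluster_targets
            ],
            columns=["cluster_id", "target_gene", "centrality", "cluster_size"],
        )

    def write(self, path: str | Path) -> None:
        df = self.to_frame()
        with open(path, "w", encoding="utf-8") as fh:
            df.to_csv(fh, sep="\t", index=False)
            fh.write(f"# hub_gene\t{self.hub_gene}\t{self.hub_degree}\n")


def pca(expr: pd.DataFrame, n_components: int = 3) -> PcaResult:
    """Column-centered SVD-based PCA of genes over samples.

    Genes are the observations, samples the features.  The sign of each
    component is fixed so that its largest-magnitude loading is positive,
    which makes scores reproducible across SVD backends.
    """
    x = expr.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataModelError("expression matrix contains non-finite values")
    k = int(n_components)
    if not (1 <= k <= min(x.shape)):
        raise DataModelError(
            f"n_components={k} exceeds min(genes, samples)={min(x.shape)}"
        )
    model = _SkPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(x)
    load = model.components_.T  # samples x components
    for c in range(k):
        pivot = np.argmax(np.abs(load[:, c]))
        if load[pivot, c] < 0:
            load[:, c] = -load[:, c]
            scores[:, c] = -scores[:, c]
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=expr.index.astype(str), columns=comp_names),
        loadings=pd.DataFrame(load, index=expr.columns, columns=comp_names),
        explained_variance_fraction=model.explained_variance_ratio_.copy(),
    )


def standardize_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Scale each component to unit standard deviation (zero-variance
    components pass through), so a single eps applies to every axis."""
    sd = scores.std(axis=0, ddof=0).replace(0.0, 1.0)
    return scores / sd


def dbscan(points: pd.DataFrame, eps: float, min_samples: int
           ) -> dict[str, int]:
    """Density-based clustering with a deterministic border rule.

    ``points`` is indexed by gene ID (coordinates in PC space, Euclidean
    metric).  A core point has at least ``min_samples`` neighbors within
    ``eps`` (itself included).  Clusters are maximal density-connected
    sets, created while scanning genes in lexicographic ID order; border
    points join the first-created cluster that reaches them.  Unreachable
    points get the :data:`NOISE` label.  Labels are contiguous from 0.
    """
    if eps <= 0:
        raise DataModelError("eps must be > 0")
    if min_samples < 1:
        raise DataModelError("min_samples must be >= 1")
    ids = sorted(str(g) for g in points.index)
    if not ids:
        raise DataModelError("no points to cluster")
    x = points.loc[ids].to_numpy(dtype=float)
    n = len(ids)
    dist = squareform(pdist(x)) if n > 1 else np.zeros((1, 1))
    neigh = [np.nonzero(dist[i] <= eps)[0] for i in range(n)]
    core = np.array([len(nb) >= min_samples for nb in neigh])

    labels = np.full(n, NOISE, dtype=int)
    next_label = 0
    for i in range(n):
        if not core[i] or labels[i] != NOISE:
            continue
        labels[i] = next_label
        queue = deque([i])
        while queue:
            j = queue.popleft()
            for k in neigh[j]:
                if labels[k] == NOISE:
                    labels[k] = next_label
                    if core[k]:
                        queue.append(k)
        next_label += 1
    return {ids[i]: int(labels[i]) for i in range(n)}


def zscore_profiles(expr: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene's profile to mean 0, sd 1 (constant rows pass
    through centered), so clustering groups by expression shape rather
    than magnitude."""
    mu = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=0).replace(0.0, 1.0)
    return expr.sub(mu, axis=0).div(sd, axis=0)


def cluster_genes(expr: pd.DataFrame, config: PipelineConfig | None = None,
                  standardize_genes: bool = True
                  ) -> tuple[dict[str, int], PcaResult]:
    """Per-gene z-scoring (optional) -> PCA -> per-component
    standardization -> DBSCAN, per configuration."""
    config = config or PipelineConfig()
    if standardize_genes:
        expr = zscore_profiles(expr)
    res = pca(expr, n_components=config.n_components)
    coords = standardize_scores(res.scores)
    labels = dbscan(coords, eps=config.dbscan_eps,
                    min_samples=config.dbscan_min_samples)
    return labels, res


def betweenness(net: CoexpressionNetwork) -> dict[str, float]:
    """Normalized shortest-path betweenness centrality of every gene.

    Unweighted shortest paths; for undirected graphs the node sums are
    divided by (n-1)(n-2)/2, so a path midpoint and a star center both
    score 1.0.  Disconnected pairs contribute nothing.
    """
    if net.graph.number_of_nodes() == 0:
        raise DataModelError("betweenness of an empty network is undefined")
    return {str(k): float(v) for k, v in
            nx.betweenness_centrality(net.graph, normalized=True).items()}


def select_targets(clusters: dict[str, int], net: CoexpressionNetwork,
                   subgraph: bool = False) -> TargetSelection:
    """Pick the most central member of every non-noise cluster.

    Centrality is computed once on the full network by default (a member's
    hub-ness is judged against the whole transcriptome); ``subgraph=True``
    instead scores each cluster on its induced subgraph.  Genes absent
    from the network score 0.  Ties, and clusters whose members all score
    0, resolve to the lexicographically smallest gene ID (with a warning
    for the all-zero case).  ``unique_targets`` deduplicates targets in
    cluster-ID order; the global max-degree gene is reported alongside.
    """
    if not subgraph:
        central = betweenness(net)
    labels = sorted({l for l in clusters.values() if l != NOISE})
    targets: list[ClusterTarget] = []
    for lab in labels:
        members = sorted(g for g, l in clusters.items() if l == lab)
        if subgraph:
            sub = CoexpressionNetwork(
                graph=net.graph.subgraph([m for m in members
                                          if m in net.graph]).copy(),
                n_methods=net.n_methods,
            )
            central = betweenness(sub) if sub.graph.number_of_nodes() else {}
        scores = {m: central.get(m, 0.0) for m in members}
        best = min(scores, key=lambda m: (-scores[m], m))
        if scores[best] == 0.0:
            logger.warning(
                "cluster %d: all member centralities are 0; "
                "selecting lexicographic minimum %s", lab, best
            )
        targets.append(ClusterTarget(cluster_id=lab, target_gene=best,
                                     centrality=scores[best],
                                     cluster_size=len(members)))
    unique: list[str] = []
    for t in targets:
        if t.target_gene not in unique:
            unique.append(t.target_gene)
    hub, deg = max_degree_gene(net)
    return TargetSelection(cluster_targets=targets, unique_targets=unique,
                           hub_gene=hub, hub_degree=deg)
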