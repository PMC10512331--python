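"""Consensus co-expression network construction.

Candidate edges are proposed independently by several association measures
(absolute Pearson correlation, absolute Spearman correlation, normalized
mutual information on equal-frequency-binned profiles) and an edge enters
the consensus network only when proposed by at least ``min_support``
measures.  Requiring agreement between rank-based, linear and
nonparametric measures suppresses edges driven by a single outlier sample
or by one measure's artefacts, which is the rationale of consensus network
builders.  The graph is undirected with no self-loops; every pair is
stored in canonical lexicographic order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from coexhub.data_model import DataModelError

METHODS = ("pearson", "spearman", "mutual_information")


@dataclass
class CoexpressionNetwork:
    """Undirected gene graph; each edge carries a weight and a support count."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    n_methods: int = 1

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted((a, b))) for a, b in self.graph.edges}

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "weight": d["weight"], "support": d["support"]}
            for (a, b), d in ((tuple(sorted(e)), self.graph.edges[e])
                              for e in self.graph.edges)
        ]
        df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight", "support"])
        return df.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)

    def write_edges(self, path: str | Path) -> None:
        self.to_edge_frame().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _pairwise_abs_corr(x: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    return np.abs(r)


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each value of each row to one of ``n_bins`` rank-based bins.

    Stable argsort makes the assignment deterministic under ties.
    """
    n = x.shape[1]
    order = np.argsort(x, axis=1, kind="stable")
    ranks = np.empty_like(order)
    cols = np.arange(n)
    for i in range(x.shape[0]):
        ranks[i, order[i]] = cols
    return (ranks * n_bins) // n


def _pairwise_normalized_mi(x: np.ndarray, n_bins: int,
                            block: int = 256) -> np.ndarray:
    """Normalized mutual information MI / min(H_i, H_j) for all row pairs.

    Joint bin counts for all pairs come from matmuls on the one-hot
    bin-indicator matrix, blocked over genes to bound memory.
    """
    g, n = x.shape
    bins = _equal_frequency_bins(x, n_bins)
    onehot = np.zeros((g, n_bins, n))
    onehot[np.repeat(np.arange(g), n), bins.ravel(), np.tile(np.arange(n), g)] = 1.0
    flat = onehot.reshape(g * n_bins, n)

    marg = onehot.sum(axis=2) / n  # g x n_bins
    with np.errstate(divide="ignore"):
        h = -np.sum(np.where(marg > 0, marg * np.log(marg), 0.0), axis=1)

    mi = np.zeros((g, g))
    for lo in range(0, g, block):
        hi = min(lo + block, g)
        joint = (flat[lo * n_bins:hi * n_bins] @ flat.T)
        joint = joint.reshape(hi - lo, n_bins, g, n_bins) / n  # P(bi, bj)
        outer = marg[lo:hi, :, None, None] * marg[None, None, :, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(joint > 0, joint * np.log(joint / outer), 0.0)
        mi[lo:hi] = term.sum(axis=(1, 3))

    hmin = np.minimum(h[:, None], h[None, :])
    with np.errstate(invalid="ignore"):
        nmi = np.where(hmin > 0, mi / hmin, 0.0)
    return np.clip(nmi, 0.0, None)


def score_edges(expr: pd.DataFrame, method: str, threshold: float,
                n_bins: int = 4) -> dict[tuple[str, str], float]:
    """Propose candidate edges under one association measure.

    ``expr`` is a genes x samples DataFrame.  Correlation methods keep a
    pair iff ``|r| >= threshold`` with weight ``|r|``; mutual information
    keeps a pair iff the normalized MI (MI divided by the smaller marginal
    entropy) reaches the threshold.  Genes with zero variance propose no
    edges.
    """
    if method not in METHODS:
        raise DataModelError(f"unknown network method {method!r}")
    if expr.shape[1] < 4:
        raise DataModelError("edge scoring requires at least 4 samples")
    genes = [str(g) for g in expr.index]
    x = expr.to_numpy(dtype=float)
    variable = x.std(axis=1) > 0

    if method == "pearson":
        w = _pairwise_abs_corr(x)
    elif method == "spearman":
        w = _pairwise_abs_corr(stats.rankdata(x, axis=1))
    else:
        w = _pairwise_normalized_mi(x, n_bins)
        # a constant profile has zero entropy; exclude exactly as for r
    out: dict[tuple[str, str], float] = {}
    iu, ju = np.triu_indices(len(genes), k=1)
    vals = w[iu, ju]
    # tiny slack so an exact-dependence pair (|r| = 1 up to rounding)
    # passes a threshold of exactly 1
    ok = (np.isfinite(vals) & (vals >= threshold - 1e-12)
          & variable[iu] & variable[ju])
    for i, j, v in zip(iu[ok], ju[ok], vals[ok]):
        out[_canonical(genes[i], genes[j])] = float(v)
    return out


def build_consensus(expr: pd.DataFrame,
                    methods: Sequence[str] = METHODS,
                    thresholds: Mapping[str, float] | float = 0.75,
                    min_support: int = 2,
                    n_bins: int = 4) -> CoexpressionNetwork:
    """Build the consensus network over the configured measures.

    An edge is kept iff proposed by at least ``min_support`` measures; its
    weight is the mean weight over the proposing measures and its
    ``support`` attribute records how many proposed it.  All genes of
    ``expr`` are nodes, so genes without any consensus edge appear as
    isolated nodes (degree 0).
    """
    if len(methods) == 0:
        raise DataModelError("at least one network method required")
    if min_support > len(methods):
        raise DataModelError("min_support exceeds the number of methods")
    if isinstance(thresholds, (int, float)):
        thresholds = {m: float(thresholds) for m in methods}
    missing = [m for m in methods if m not in thresholds]
    if missing:
        raise DataModelError(f"no edge threshold configured for: {missing}")

    proposals = [score_edges(expr, m, thresholds[m], n_bins=n_bins) for m in methods]
    support: dict[tuple[str, str], int] = {}
    weight_sum: dict[tuple[str, str], float] = {}
    for prop in proposals:
        for pair, w in prop.items():
            support[pair] = support.get(pair, 0) + 1
            weight_sum[pair] = weight_sum.get(pair, 0.0) + w

    g = nx.Graph()
    g.add_nodes_from(str(i) for i in expr.index)
    for pair, s in support.items():
        if s >= min_support:
            a, b = pair
            g.add_edge(a, b, weight=weight_sum[pair] / s, support=s)
    return CoexpressionNetwork(graph=g, n_methods=len(methods))


def max_degree_gene(net: CoexpressionNetwork) -> tuple[str, int]:
    """The network hub by connection count; ties go to the smaller gene ID."""
    if net.graph.number_of_nodes() == 0:
        raise DataModelError("empty network has no maximum-degree gene")
    best = min(net.graph.nodes, key=lambda n: (-net.graph.degree[n], str(n)))
    return str(best), int(net.graph.degree[best])
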