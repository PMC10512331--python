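import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import DBSCAN as SkDBSCAN

from coexhub.data_model import DataModelError
from coexhub.enrichment import (
    NOISE,
    betweenness,
    dbscan,
    pca,
    select_targets,
    standardize_scores,
)
from coexhub.network import CoexpressionNetwork

from _oracles import brute_betweenness, covariance_pca_scores, dbscan_closure


def points_frame(x, ids=None):
    x = np.asarray(x, dtype=float)
    ids = ids or [f"g{i:03d}" for i in range(x.shape[0])]
    return pd.DataFrame(x, index=ids)


def net_from_edges(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b in edges:
        g.add_edge(a, b, weight=1.0, support=2)
    return CoexpressionNetwork(graph=g)


class TestPCA:
    def test_rank_one_data_explained_by_first_component(self, rng):
        direction = rng.normal(size=6)
        coeff = rng.normal(size=20)
        x = np.outer(coeff, direction)
        res = pca(points_frame(x), n_components=3)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_scores_match_covariance_eigendecomposition(self, rng):
        x = rng.normal(size=(20, 6))
        res = pca(points_frame(x), n_components=3)
        expect = covariance_pca_scores(x, 3)
        for c in range(3):
            ours = res.scores.iloc[:, c].to_numpy()
            ref = expect[:, c]
            agree = min(np.abs(ours - ref).max(), np.abs(ours + ref).max())
            assert agree < 1e-8  # equal up to component sign

    def test_explained_fractions_non_increasing(self, rng):
        res = pca(points_frame(rng.normal(size=(30, 8))), n_components=5)
        frac = res.explained_variance_fraction
        assert np.all(np.diff(frac) <= 1e-12)
        assert frac.sum() <= 1.0 + 1e-12

    def test_duplicated_gene_leaves_components_stable(self, rng):
        x = rng.normal(size=(15, 6))
        x2 = np.vstack([x, x[3]])
        r1 = pca(points_frame(x), 2)
        r2 = pca(points_frame(x2), 2)
        # same span: loadings agree up to sign
        for c in range(2):
            a = r1.loadings.iloc[:, c].to_numpy()
            b = r2.loadings.iloc[:, c].to_numpy()
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 0.05

    def test_sign_convention_is_deterministic(self, rng):
        x = rng.normal(size=(12, 5))
        res = pca(points_frame(x), 3)
        for c in range(3):
            load = res.loadings.iloc[:, c].to_numpy()
            assert load[np.argmax(np.abs(load))] > 0

    def test_non_finite_rejected(self):
        x = np.ones((4, 4))
        x[2, 2] = np.nan
        with pytest.raises(DataModelError):
            pca(points_frame(x), 2)


class TestDBSCAN:
    def test_two_separated_blobs(self, rng):
        a = rng.normal(0, 0.1, size=(10, 3))
        b = rng.normal(0, 0.1, size=(10, 3)) + 50.0
        labels = dbscan(points_frame(np.vstack([a, b])), eps=1.0,
                        min_samples=3)
        vals = set(labels.values())
        assert vals == {0, 1}
        # blob membership is coherent
        first = [labels[f"g{i:03d}"] for i in range(10)]
        second = [labels[f"g{i:03d}"] for i in range(10, 20)]
        assert len(set(first)) == 1 and len(set(second)) == 1

    def test_isolated_point_is_noise(self, rng):
        cloud = rng.normal(0, 0.2, size=(8, 2))
        lone = np.array([[30.0, 30.0]])
        labels = dbscan(points_frame(np.vstack([cloud, lone])), eps=1.0,
                        min_samples=3)
        assert labels["g008"] == NOISE
        assert labels["g000"] != NOISE

    @pytest.mark.parametrize("eps,min_samples", [(0.3, 3), (0.5, 4), (0.8, 5)])
    def test_matches_reachability_closure_oracle(self, rng, eps, min_samples):
        for _ in range(25):
            n = int(rng.integers(5, 61))
            x = rng.uniform(0, 2, size=(n, 2))
            ids = [f"p{i:02d}" for i in range(n)]
            ours = dbscan(points_frame(x, ids), eps, min_samples)
            oracle = dbscan_closure(ids, x, eps, min_samples)
            assert ours == oracle

    def test_core_labels_agree_with_sklearn(self, rng):
        # on core points the partition is implementation-independent
        x = rng.uniform(0, 2, size=(50, 2))
        ids = [f"p{i:02d}" for i in range(50)]
        ours = dbscan(points_frame(x, ids), 0.4, 4)
        sk = SkDBSCAN(eps=0.4, min_samples=4).fit(x)
        core = set(sk.core_sample_indices_)
        # mapping between label schemes must be a bijection on core points
        pairs = {(ours[ids[i]], sk.labels_[i]) for i in core}
        assert len({a for a, _ in pairs}) == len(pairs)
        assert len({b for _, b in pairs}) == len(pairs)

    def test_no_points_rejected(self):
        with pytest.raises(DataModelError):
            dbscan(points_frame(np.empty((0, 3))), 0.5, 3)


class TestBetweenness:
    def test_path_graph_closed_form(self):
        net = net_from_edges([("a", "b"), ("b", "c")])
        cen = betweenness(net)
        assert cen == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_star_center_closed_form(self):
        net = net_from_edges([("h", l) for l in "abc"])
        assert betweenness(net)["h"] == pytest.approx(1.0)

    def test_random_graphs_match_path_enumeration_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 13))
            nodes = [f"n{i:02d}" for i in range(n)]
            edges = {(a, b) for i, a in enumerate(nodes)
                     for b in nodes[i + 1:] if rng.random() < 0.3}
            net = net_from_edges(edges, nodes=nodes)
            ours = betweenness(net)
            oracle = brute_betweenness(nodes, edges)
            for v in nodes:
                assert ours[v] == pytest.approx(oracle[v], abs=1e-12)


class TestSelectTargets:
    def test_singleton_cluster_selects_its_gene(self):
        net = net_from_edges([("a", "b"), ("b", "c")])
        sel = select_targets({"a": 0, "b": 1, "c": NOISE}, net)
        assert [(t.cluster_id, t.target_gene) for t in sel.cluster_targets] \
            == [(0, "a"), (1, "b")]
        assert sel.unique_targets == ["a", "b"]

    def test_most_central_member_wins(self):
        # b bridges two cliques; cluster contains the whole component
        edges = [("a1", "a2"), ("a1", "b"), ("a2", "b"),
                 ("c1", "c2"), ("c1", "b"), ("c2", "b")]
        net = net_from_edges(edges)
        clusters = {g: 0 for g in ["a1", "a2", "b", "c1", "c2"]}
        sel = select_targets(clusters, net)
        assert sel.cluster_targets[0].target_gene == "b"

    def test_tie_breaks_lexicographically(self):
        net = net_from_edges([], nodes=["200", "1000"])
        sel = select_targets({"200": 0, "1000": 0}, net)
        assert sel.cluster_targets[0].target_gene == "1000"  # "1000" < "200"

    def test_all_zero_centrality_warns(self, caplog):
        net = net_from_edges([], nodes=["x", "y"])
        with caplog.at_level("WARNING"):
            sel = select_targets({"x": 0, "y": 0}, net)
        assert sel.cluster_targets[0].target_gene == "x"
        assert "centralities are 0" in caplog.text

    def test_genes_absent_from_network_score_zero(self):
        net = net_from_edges([("a", "b"), ("b", "c")])
        sel = select_targets({"b": 0, "zzz": 0}, net)
        assert sel.cluster_targets[0].target_gene == "b"

    def test_noise_gets_no_target_and_sizes_reported(self):
        net = net_from_edges([("a", "b")], nodes=["a", "b", "c"])
        sel = select_targets({"a": 0, "b": 0, "c": NOISE}, net)
        assert len(sel.cluster_targets) == 1
        assert sel.cluster_targets[0].cluster_size == 2

    def test_subgraph_mode_restricts_centrality(self):
        # full-network centrality of m is inflated by the pendant chain;
        # induced-subgraph centrality ignores it
        edges = [("a", "m"), ("m", "b"), ("b", "x1"), ("x1", "x2")]
        net = net_from_edges(edges)
        clusters = {"a": 0, "m": 0, "b": 0}
        full = select_targets(clusters, net, subgraph=False)
        sub = select_targets(clusters, net, subgraph=True)
        assert full.cluster_targets[0].target_gene == "b"
        assert sub.cluster_targets[0].target_gene == "m"

    def test_standardize_scores_unit_sd(self, rng):
        s = pd.DataFrame(rng.normal(0, [5, 0.2, 1], size=(40, 3)))
        z = standardize_scores(s)
        np.testing.assert_allclose(z.std(axis=0, ddof=0), 1.0, rtol=1e-9)
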