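"""Independent brute-force oracles used by the test suite.

Every function here re-derives a quantity from first principles (plain
loops, exhaustive enumeration, textbook formulas) without touching the
package's implementation paths, so agreement is evidence rather than
tautology.
"""

from __future__ import annotations

import math

import numpy as np


# -- TMM ----------------------------------------------------------------------

def tmm_log2_factor(obs: np.ndarray, ref: np.ndarray,
                    trim_m: float = 0.30, trim_a: float = 0.05) -> float:
    """Direct evaluation of the doubly trimmed weighted mean of log ratios.

    Plain-Python translation of the definition: per-gene M (log2 ratio of
    library-size-scaled counts), A (average log2 abundance), precision
    weights from the delta method; drop genes with a zero in either
    library; trim by sort position in M and in A; weighted mean of the
    survivors.  Assumes no ties in M or A (callers pick tie-free data).
    """
    n_obs, n_ref = float(obs.sum()), float(ref.sum())
    entries = []
    for o, r in zip(obs, ref):
        if o == 0 or r == 0:
            continue
        m = math.log2((o / n_obs) / (r / n_ref))
        a = 0.5 * math.log2((o / n_obs) * (r / n_ref))
        w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
        entries.append((m, a, w))
    n = len(entries)
    if n == 0:
        return 0.0
    by_m = sorted(range(n), key=lambda i: entries[i][0])
    by_a = sorted(range(n), key=lambda i: entries[i][1])
    rank_m = {idx: pos + 1 for pos, idx in enumerate(by_m)}
    rank_a = {idx: pos + 1 for pos, idx in enumerate(by_a)}
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    num = den = 0.0
    for i, (m, a, w) in enumerate(entries):
        if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
            num += w * m
            den += w
    return num / den if den else 0.0


# -- correlation --------------------------------------------------------------

def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson correlation via explicit sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


# -- betweenness --------------------------------------------------------------

def brute_betweenness(nodes: list[str], edges: set[tuple[str, str]]
                      ) -> dict[str, float]:
    """Betweenness by explicit all-pairs shortest-path enumeration.

    BFS from every node gives distances and path counts; a node v lies on
    a shortest s-t path iff d(s,v) + d(v,t) = d(s,t), contributing
    sigma(s,v) * sigma(v,t) / sigma(s,t).  Normalized by (n-1)(n-2)/2.
    """
    adj = {u: set() for u in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def bfs(src):
        dist = {src: 0}
        sigma = {src: 1}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        sigma[v] = 0
                        nxt.append(v)
                    if dist[v] == dist[u] + 1:
                        sigma[v] += sigma[u]
            frontier = nxt
        return dist, sigma

    info = {u: bfs(u) for u in nodes}
    n = len(nodes)
    score = {u: 0.0 for u in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            dist_s, sig_s = info[s]
            if t not in dist_s:
                continue
            d = dist_s[t]
            total = sig_s[t]
            for v in nodes:
                if v in (s, t) or v not in dist_s:
                    continue
                dist_v, sig_v = info[v]
                if t in dist_v and dist_s[v] + dist_v[t] == d:
                    score[v] += sig_s[v] * sig_v[t] / total
    if n > 2:
        norm = (n - 1) * (n - 2) / 2
        score = {u: v / norm for u, v in score.items()}
    return score


# -- DBSCAN -------------------------------------------------------------------

def dbscan_closure(ids: list[str], points: np.ndarray, eps: float,
                   min_samples: int) -> dict[str, int]:
    """Density-reachability closure oracle for DBSCAN.

    Core points are found from the full distance matrix; clusters are the
    connected components of the core-core eps-adjacency graph, numbered
    by their lexicographically smallest core member; a non-core point
    within eps of core points joins the lowest-numbered such cluster, and
    everything else is noise (-1).
    """
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    ids = [ids[i] for i in order]
    points = points[order]
    n = len(ids)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    within = d <= eps
    core = within.sum(axis=1) >= min_samples

    # components of the core graph via union-find
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        if not core[i]:
            continue
        for j in range(i + 1, n):
            if core[j] and within[i, j]:
                parent[find(i)] = find(j)

    comp_min: dict[int, int] = {}
    for i in range(n):
        if core[i]:
            root = find(i)
            comp_min.setdefault(root, i)  # first i in sorted order is minimal
    # cluster ids ordered by smallest member index
    ordered_roots = sorted(comp_min, key=lambda r: comp_min[r])
    cluster_of_root = {r: c for c, r in enumerate(ordered_roots)}

    labels = {}
    for i in range(n):
        if core[i]:
            labels[ids[i]] = cluster_of_root[find(i)]
        else:
            reachable = [cluster_of_root[find(j)] for j in range(n)
                         if core[j] and within[i, j]]
            labels[ids[i]] = min(reachable) if reachable else -1
    return labels


# -- PCA ----------------------------------------------------------------------

def covariance_pca_scores(x: np.ndarray, k: int) -> np.ndarray:
    """PCA scores via eigendecomposition of the feature covariance."""
    xc = x - x.mean(axis=0, keepdims=True)
    cov = xc.T @ xc / (x.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:k]
    return xc @ vecs[:, order]
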