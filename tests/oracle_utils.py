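"""Brute-force oracles shared by the unit and acceptance tests.

Everything here is deliberately naive — exhaustive path enumeration,
explicit triangle loops, literal definitions — so it stays independent of
the implementations it checks.
"""

import itertools

import numpy as np

from gswnet.graphmetrics import weight_to_length


# ---------------------------------------------------------------------------
# shortest paths / clustering
# ---------------------------------------------------------------------------

def oracle_shortest_paths(w):
    """All-pairs shortest path lengths by enumerating every simple path."""
    n = w.shape[0]
    lengths = weight_to_length(w)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            best = np.inf
            inner = [v for v in range(n) if v not in (s, t)]
            for r in range(len(inner) + 1):
                for mid in itertools.permutations(inner, r):
                    path = (s, *mid, t)
                    tot = sum(lengths[path[i], path[i + 1]]
                              for i in range(len(path) - 1))
                    best = min(best, tot)
            d[s, t] = best
    return d


def oracle_path_length(w):
    d = oracle_shortest_paths(w)
    n = w.shape[0]
    off = d[~np.eye(n, dtype=bool)].reshape(n, n - 1)
    return np.mean(np.mean(off, axis=1))


def oracle_clustering(w):
    """Direct triangle enumeration of the geometric-mean clustering."""
    n = w.shape[0]
    wh = w / w.max() if w.max() > 0 else w
    total = 0.0
    for i in range(n):
        k = np.count_nonzero(w[i])
        if k < 2:
            continue
        t = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    t += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1 / 3)
        t /= 2.0
        total += 2 * t / (k * (k - 1))
    return total / n


def random_connected_graph(rng, n):
    from scipy.sparse.csgraph import connected_components
    while True:
        w = np.triu(rng.uniform(0.2, 2.0, size=(n, n)), 1)
        w *= rng.random((n, n)) < 0.6
        w = w + w.T
        if connected_components(w > 0, directed=False)[0] == 1:
            return w


# ---------------------------------------------------------------------------
# centralities
# ---------------------------------------------------------------------------

def _neighbors(adj, i):
    return [j for j in range(adj.shape[0]) if adj[i, j]]


def oracle_degree(adj):
    return adj.sum(axis=1).astype(float)


def oracle_neighborhood_connectivity(adj):
    k = oracle_degree(adj)
    out = np.zeros(adj.shape[0])
    for i in range(adj.shape[0]):
        nb = _neighbors(adj, i)
        out[i] = np.mean([k[j] for j in nb]) if nb else 0.0
    return out


def oracle_clusterrank(adj):
    k = oracle_degree(adj)
    out = np.zeros(adj.shape[0])
    for i in range(adj.shape[0]):
        nb = _neighbors(adj, i)
        if not nb:
            continue
        links = sum(adj[a, b] for a, b in itertools.combinations(nb, 2))
        possible = len(nb) * (len(nb) - 1) / 2
        c = links / possible if possible else 0.0
        out[i] = 10.0 ** (-c) * sum(k[j] + 1 for j in nb)
    return out


def oracle_h_index(adj):
    k = oracle_degree(adj)
    h = np.zeros(adj.shape[0], dtype=int)
    for i in range(adj.shape[0]):
        degs = sorted((int(k[j]) for j in _neighbors(adj, i)), reverse=True)
        h[i] = max([0] + [m for m in range(1, len(degs) + 1)
                          if sum(1 for d in degs if d >= m) >= m])
    return h


def oracle_local_h(adj):
    h = oracle_h_index(adj)
    return np.array([h[i] + sum(h[j] for j in _neighbors(adj, i))
                     for i in range(adj.shape[0])], dtype=float)


def oracle_betweenness(w):
    """Shortest-path dependencies by enumerating all simple paths."""
    n = w.shape[0]
    lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1), np.inf)
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths, best = [], np.inf
        inner = [v for v in range(n) if v not in (s, t)]
        for r in range(len(inner) + 1):
            for mid in itertools.permutations(inner, r):
                path = (s, *mid, t)
                tot = sum(lengths[path[i], path[i + 1]]
                          for i in range(len(path) - 1))
                if not np.isfinite(tot):
                    continue
                if tot < best - 1e-12:
                    best, paths = tot, [path]
                elif abs(tot - best) <= 1e-12:
                    paths.append(path)
        if not np.isfinite(best):
            continue
        for v in range(n):
            if v in (s, t):
                continue
            frac = sum(1 for p in paths if v in p) / len(paths)
            bc[v] += frac
    return bc


def oracle_collective_influence(adj, radius=2):
    k = oracle_degree(adj)
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        if k[i] == 0:
            continue
        dist = {i: 0}
        frontier = [i]
        for d in range(1, radius + 1):
            nxt = []
            for u in frontier:
                for v in _neighbors(adj, u):
                    if v not in dist:
                        dist[v] = d
                        nxt.append(v)
            frontier = nxt
        out[i] = (k[i] - 1) * sum(k[j] - 1 for j, d in dist.items()
                                  if d == radius)
    return out


CENTRALITY_ORACLES = {
    "DC": lambda w, adj: oracle_degree(adj),
    "NC": lambda w, adj: oracle_neighborhood_connectivity(adj),
    "CR": lambda w, adj: oracle_clusterrank(adj),
    "LH": lambda w, adj: oracle_local_h(adj),
    "BC": lambda w, adj: oracle_betweenness(w),
    "CI": lambda w, adj: oracle_collective_influence(adj),
}


def all_four_node_graphs():
    """All 64 labeled graphs on 4 nodes (unit weights)."""
    graphs = []
    pairs = list(itertools.combinations(range(4), 2))
    for mask in range(2 ** 6):
        w = np.zeros((4, 4))
        for b, (i, j) in enumerate(pairs):
            if mask >> b & 1:
                w[i, j] = w[j, i] = 1.0
        graphs.append(w)
    return graphs


def random_weighted_graphs(n, count, seed):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(count):
        w = np.triu(rng.uniform(0.5, 2.0, (n, n)), 1)
        w *= rng.random((n, n)) < 0.6
        w = w + w.T
        out.append(w)
    return out


def gfp_oracle(data):
    """Literal per-sample evaluation of the GFP formula."""
    n_ch, n_samp = data.shape
    out = np.zeros(n_samp)
    for t in range(n_samp):
        u = data[:, t]
        ubar = sum(u) / n_ch
        out[t] = np.sqrt(sum((ui - ubar) ** 2 for ui in u) / n_ch)
    return out
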