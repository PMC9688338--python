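"""Integrated value of influence (IVI): fusing six centralities into one
hub score.

Six node-level measures are computed on the network's binarized support
(betweenness additionally respects edge weights through lengths ``1/w``):

* **DC** — degree centrality;
* **NC** — neighborhood connectivity, the mean degree of a node's neighbours;
* **CR** — ClusterRank, ``10^(−c_i) · Σ_{j∈Γ(i)} (k_j + 1)`` with ``c_i`` the
  local clustering coefficient;
* **LH** — local H-index, the node's own h-index (largest ``h`` such that it
  has ≥ h neighbours of degree ≥ h) plus the h-indices of its neighbours;
* **BC** — betweenness centrality (unnormalized pair counts);
* **CI** — collective influence, ``(k_i − 1) · Σ_{j : d(i,j)=ℓ} (k_j − 1)``
  over the frontier at graph distance ℓ (default 2).

Each measure is range-normalized to [1, 100] (a constant vector maps to 1)
and fused as

    spreading_i = (NC'_i + CR'_i) · (BC'_i + CI'_i)
    hubness_i   = DC'_i + LH'_i
    IVI_i       = hubness_i · spreading_i   →   range-normalized to [1, 100].

Nodes whose IVI strictly exceeds mean + 1 SD are flagged as influential.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .nbs import WeightedNetwork

__all__ = [
    "CentralityTable",
    "IVIResult",
    "centrality_suite",
    "integrated_value_of_influence",
    "select_influential",
    "influential_nodes",
]

_MEASURES = ("DC", "NC", "CR", "LH", "BC", "CI")


@dataclass
class CentralityTable:
    """Raw and range-normalized (primed, in [1, 100]) centralities."""

    raw: dict[str, np.ndarray]
    primed: dict[str, np.ndarray]
    node_labels: list[str]

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)


@dataclass
class IVIResult:
    spreading: np.ndarray
    hubness: np.ndarray
    ivi: np.ndarray
    threshold: float
    influential: list[str]
    node_labels: list[str]


def _range_normalize(x: np.ndarray) -> np.ndarray:
    """Map to [1, 100]; constant vectors map to all-ones."""
    x = np.asarray(x, dtype=float)
    span = x.max() - x.min()
    if span == 0:
        return np.ones_like(x)
    return 1.0 + 99.0 * (x - x.min()) / span


def _h_index(values: np.ndarray) -> int:
    """Largest h such that at least h of ``values`` are >= h."""
    vals = np.sort(np.asarray(values))[::-1]
    h = 0
    for rank, v in enumerate(vals, start=1):
        if v >= rank:
            h = rank
        else:
            break
    return h


def _bfs_frontier(adj: np.ndarray, start: int, radius: int) -> np.ndarray:
    """Indices at exactly ``radius`` hops from ``start``."""
    n = adj.shape[0]
    dist = np.full(n, -1)
    dist[start] = 0
    frontier = [start]
    for d in range(1, radius + 1):
        nxt = []
        for u in frontier:
            for v in np.flatnonzero(adj[u]):
                if dist[v] < 0:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
        if not frontier:
            break
    return np.flatnonzero(dist == radius)


def centrality_suite(
    W: WeightedNetwork | np.ndarray,
    ci_radius: int = 2,
) -> CentralityTable:
    """All six centralities plus their [1, 100] range-normalized forms.

    Isolated nodes get DC = NC = CR = CI = LH = 0 before normalization.
    """
    if isinstance(W, WeightedNetwork):
        w = W.weights
        labels = list(W.node_labels)
    else:
        w = np.asarray(W, dtype=float)
        labels = [f"n{i}" for i in range(w.shape[0])]
    n = w.shape[0]
    if n < 2:
        raise ValueError("centralities need >= 2 nodes")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    adj = (w > 0).astype(int)
    np.fill_diagonal(adj, 0)
    k = adj.sum(axis=1)

    # neighborhood connectivity: mean neighbour degree
    nc = np.where(k > 0, adj @ k / np.maximum(k, 1), 0.0)

    # local clustering (binary) for ClusterRank
    tri = np.diag(adj @ adj @ adj) / 2.0
    possible = k * (k - 1) / 2.0
    c_local = np.where(possible > 0, tri / np.where(possible > 0, possible, 1), 0.0)
    cr = np.where(k > 0, 10.0**(-c_local) * (adj @ (k + 1)), 0.0)

    h = np.array([_h_index(k[np.flatnonzero(adj[i])]) for i in range(n)])
    lh = h + adj @ h

    G = nx.from_numpy_array(np.where(w > 0, w, 0.0))
    for u, v, d in G.edges(data=True):
        d["length"] = 1.0 / d["weight"]
    bc_dict = nx.betweenness_centrality(G, weight="length", normalized=False)
    bc = np.array([bc_dict[i] for i in range(n)])

    ci = np.zeros(n)
    for i in range(n):
        if k[i] == 0:
            continue
        frontier = _bfs_frontier(adj, i, ci_radius)
        ci[i] = (k[i] - 1) * np.sum(k[frontier] - 1)

    raw = {"DC": k.astype(float), "NC": nc, "CR": cr, "LH": lh.astype(float),
           "BC": bc, "CI": ci}
    primed = {name: _range_normalize(raw[name]) for name in _MEASURES}
    return CentralityTable(raw, primed, labels)


def select_influential(scores: np.ndarray,
                       labels: list[str]) -> tuple[float, list[str]]:
    """Mean + 1 SD rule: (threshold, labels strictly above it)."""
    scores = np.asarray(scores, dtype=float)
    threshold = float(np.mean(scores) + np.std(scores, ddof=1))
    return threshold, [labels[i] for i in np.flatnonzero(scores > threshold)]


def integrated_value_of_influence(tab: CentralityTable) -> IVIResult:
    """Fuse the primed centralities into spreading, hubness and IVI scores."""
    p = tab.primed
    spreading = (p["NC"] + p["CR"]) * (p["BC"] + p["CI"])
    hubness = p["DC"] + p["LH"]
    ivi = _range_normalize(hubness * spreading)
    threshold, influential = select_influential(ivi, tab.node_labels)
    return IVIResult(spreading, hubness, ivi, threshold, influential,
                     list(tab.node_labels))


def influential_nodes(res: IVIResult) -> list[str]:
    """Nodes whose IVI strictly exceeds mean + 1 SD (empty when SD = 0)."""
    return list(res.influential)
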