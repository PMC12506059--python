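"""Bridge edges and bridge centrality for member-partitioned networks.

Edges connecting symptom nodes of *different* family members are bridge
edges.  Bridge strength of a node is the summed absolute weight of its
cross-member edges; bridge betweenness is the (fractional) number of
shortest paths between nodes of distinct members that pass through the
node, with edge distances 1/|weight| (the usual convention for
association-weighted psychometric networks).
"""

from __future__ import annotations

from heapq import heappop, heappush

import numpy as np
import pandas as pd

from famnet.ggm import NetworkGraph

__all__ = ["bridge_edges", "bridge_strength", "bridge_betweenness",
           "bridge_centrality_table"]


def _labels(net: NetworkGraph) -> list:
    miss = [n for n in net.node_names if n not in net.communities]
    if miss:
        raise ValueError(f"unlabeled node(s): {miss}")
    return [net.communities[n] for n in net.node_names]


def bridge_edges(net: NetworkGraph) -> tuple[pd.DataFrame, NetworkGraph]:
    """Nonzero edges whose endpoints belong to different members.

    Returns the bridge-edge table and the display network with all
    non-bridge edges set to zero.
    """
    lab = _labels(net)
    p = len(net.node_names)
    W = np.zeros_like(net.weights)
    rows = []
    for i in range(p):
        for j in range(i + 1, p):
            w = net.weights[i, j]
            if w != 0 and lab[i] != lab[j]:
                W[i, j] = W[j, i] = w
                rows.append((net.node_names[i], net.node_names[j], w,
                             lab[i], lab[j]))
    table = pd.DataFrame(rows, columns=["node_a", "node_b", "weight",
                                        "community_a", "community_b"])
    display = NetworkGraph(node_names=list(net.node_names), weights=W,
                           communities=dict(net.communities))
    return table, display


def bridge_strength(net: NetworkGraph) -> pd.Series:
    """Per node: sum of |weight| over edges to other members' nodes."""
    lab = np.array(_labels(net))
    cross = lab[:, None] != lab[None, :]
    vals = (np.abs(net.weights) * cross).sum(axis=1)
    return pd.Series(vals, index=net.node_names, name="bridge_strength")


def _dijkstra_counts(dist_matrix: np.ndarray, source: int):
    """Single-source shortest-path distances, path counts and
    predecessor lists on a dense distance matrix (inf = no edge)."""
    p = dist_matrix.shape[0]
    dist = np.full(p, np.inf)
    sigma = np.zeros(p)
    preds: list[list[int]] = [[] for _ in range(p)]
    dist[source] = 0.0
    sigma[source] = 1.0
    done = np.zeros(p, dtype=bool)
    heap = [(0.0, source)]
    order = []
    while heap:
        d, u = heappop(heap)
        if done[u]:
            continue
        done[u] = True
        order.append(u)
        for v in range(p):
            duv = dist_matrix[u, v]
            if not np.isfinite(duv):
                continue
            alt = d + duv
            if alt < dist[v] - 1e-12:
                dist[v] = alt
                sigma[v] = sigma[u]
                preds[v] = [u]
                heappush(heap, (alt, v))
            elif abs(alt - dist[v]) <= 1e-12 and not done[v]:
                sigma[v] += sigma[u]
                preds[v].append(u)
    return dist, sigma, preds, order


def bridge_betweenness(net: NetworkGraph) -> pd.Series:
    """Brandes-style betweenness restricted to cross-member pairs.

    For every unordered pair (s, t) with different member labels, each
    interior node v accumulates the fraction of shortest s-t paths
    through v (fractional counting on ties; endpoints never accumulate;
    disconnected pairs contribute nothing).  Distances are 1/|weight|.
    """
    lab = np.array(_labels(net))
    p = len(net.node_names)
    with np.errstate(divide="ignore"):
        D = np.where(net.weights != 0, 1.0 / np.abs(net.weights), np.inf)
    np.fill_diagonal(D, np.inf)
    acc = np.zeros(p)
    for s in range(p):
        dist, sigma, preds, order = _dijkstra_counts(D, s)
        # dependency accumulation, crediting only cross-member targets t > s
        delta = np.zeros(p)
        for w in reversed(order):
            credit = delta[w]
            if w != s and w > s and lab[w] != lab[s] and np.isfinite(dist[w]):
                credit += 1.0
            for u in preds[w]:
                delta[u] += (sigma[u] / sigma[w]) * credit
        delta[s] = 0.0
        mask = np.ones(p, dtype=bool)
        mask[s] = False
        # endpoints of each pair never accumulate: delta[t] already only
        # carries flow-through credit for t as interior node of other pairs
        acc[mask] += delta[mask]
    # subtract nothing: targets receive credit only as interiors by design
    return pd.Series(acc, index=net.node_names, name="bridge_betweenness")


def bridge_centrality_table(net: NetworkGraph) -> pd.DataFrame:
    """CSV-ready table: node, community, bridge strength, bridge betweenness."""
    bs = bridge_strength(net)
    bb = bridge_betweenness(net)
    return pd.DataFrame({
        "node": net.node_names,
        "community": [net.communities[n] for n in net.node_names],
        "bridge_strength": bs.values,
        "bridge_betweenness": bb.values,
    })
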