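"""Six-parameter node centrality and consensus hub ranking.

Computes the classic CentiScaPe sextet — degree, eccentricity, closeness,
betweenness, stress and centroid — on the undirected union of the network's
edge layers with unit edge weights, per connected component.  Reciprocal
forms are used for eccentricity (1 / max distance) and closeness
(1 / summed distance) so that *higher = more central* holds for all six
parameters, which makes the above-component-mean hub flags coherent.

Definitions, for a node v inside its component:

* betweenness(v) = Σ_{s<t, s,t≠v} σ_st(v) / σ_st   (endpoints excluded)
* stress(v)      = Σ_{s<t, s,t≠v} σ_st(v)          (shortest paths through v)
* centroid(v)    = min_{w≠v} γ_v(w) − γ_w(v), where γ_v(w) counts nodes
  strictly closer to v than to w (v itself always qualifies).

Nodes in singleton components have no finite distances; all their
centralities are reported as 0.
"""

from __future__ import annotations

from collections import deque

import networkx as nx
import numpy as np
import pandas as pd

from .network_build import IntegratedNetwork

__all__ = ["compute_centralities", "rank_hubs", "CENTRALITY_PARAMS"]

CENTRALITY_PARAMS = ["degree", "eccentricity", "closeness", "betweenness", "stress", "centroid"]


def _bfs_dist_sigma(adj: list[list[int]], source: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Distances and shortest-path counts from one source (unit weights)."""
    dist = np.full(n, -1, dtype=np.int64)
    sigma = np.zeros(n, dtype=np.float64)
    dist[source] = 0
    sigma[source] = 1.0
    q = deque([source])
    while q:
        u = q.popleft()
        du = dist[u]
        for v in adj[u]:
            if dist[v] < 0:
                dist[v] = du + 1
                q.append(v)
            if dist[v] == du + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def _component_table(sub: nx.Graph) -> pd.DataFrame:
    nodes = sorted(sub.nodes)
    n = len(nodes)
    if n == 1:
        return pd.DataFrame(
            {p: [0.0] for p in CENTRALITY_PARAMS}, index=pd.Index(nodes, name="node")
        )
    index = {node: i for i, node in enumerate(nodes)}
    adj = [[index[v] for v in sub[u]] for u in nodes]
    dist = np.empty((n, n), dtype=np.int64)
    sigma = np.empty((n, n), dtype=np.float64)
    for i in range(n):
        dist[i], sigma[i] = _bfs_dist_sigma(adj, i, n)

    degree = np.array([sub.degree(u) for u in nodes], dtype=float)
    ecc = 1.0 / dist.max(axis=1)
    closeness = 1.0 / dist.sum(axis=1)

    bc = nx.betweenness_centrality(sub, normalized=False)
    betweenness = np.array([bc[u] for u in nodes])

    stress = np.zeros(n)
    centroid = np.zeros(n)
    for v in range(n):
        on_path = dist[:, v][:, None] + dist[v, :][None, :] == dist
        paths = sigma[:, v][:, None] * sigma[v, :][None, :]
        contrib = np.where(on_path, paths, 0.0)
        contrib[v, :] = 0.0
        contrib[:, v] = 0.0
        np.fill_diagonal(contrib, 0.0)
        stress[v] = contrib.sum() / 2.0  # each unordered pair counted once

        # gamma_v(w) = #{u : d(u,v) < d(u,w)}; node v itself always counts
        closer_v = (dist[:, v][:, None] < dist).sum(axis=0)  # gamma_v(w) for all w
        closer_w = (dist < dist[:, v][:, None]).sum(axis=0)  # gamma_w(v) for all w
        f = closer_v - closer_w
        centroid[v] = np.delete(f, v).min()

    return pd.DataFrame(
        {
            "degree": degree,
            "eccentricity": ecc,
            "closeness": closeness,
            "betweenness": betweenness,
            "stress": stress,
            "centroid": centroid,
        },
        index=pd.Index(nodes, name="node"),
    )


def compute_centralities(net: IntegratedNetwork | nx.Graph) -> pd.DataFrame:
    """Centrality table for every node, computed within its component.

    Returns a DataFrame indexed by node with the six centrality columns, a
    ``component`` id, per-parameter boolean ``above_mean_*`` hub flags
    (strictly above the component mean) and their count ``n_above_mean``.
    """
    g = net.union_graph() if isinstance(net, IntegratedNetwork) else net
    parts = []
    for comp_id, comp in enumerate(sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])):
        table = _component_table(g.subgraph(comp))
        table["component"] = comp_id
        for p in CENTRALITY_PARAMS:
            table[f"above_mean_{p}"] = table[p] > table[p].mean()
        parts.append(table)
    if not parts:
        cols = CENTRALITY_PARAMS + ["component"] + [f"above_mean_{p}" for p in CENTRALITY_PARAMS]
        return pd.DataFrame(columns=cols, index=pd.Index([], name="node"))
    out = pd.concat(parts).sort_index()
    out["n_above_mean"] = out[[f"above_mean_{p}" for p in CENTRALITY_PARAMS]].sum(axis=1)
    return out


def rank_hubs(table: pd.DataFrame, top_n: int = 25) -> pd.DataFrame:
    """Consensus hub ranking: most above-mean parameters first.

    Sort key: count of centrality parameters above the component mean
    (descending), then degree (descending), then symbol (ascending);
    truncated to ``top_n`` rows with a 1-based ``consensus_rank`` column.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    if table.empty:
        raise ValueError("empty centrality table")
    ranked = (
        table.assign(_sym=table.index)
        .sort_values(["n_above_mean", "degree", "_sym"], ascending=[False, False, True], kind="stable")
        .drop(columns="_sym")
        .head(top_n)
        .copy()
    )
    ranked["consensus_rank"] = np.arange(1, len(ranked) + 1)
    return ranked
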