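"""Density-based complex detection in the PPI layer (MCODE-style).

Each vertex is weighted by the highest k-core of its closed neighborhood:
``weight(v) = k_max · density(k_max-core of N[v])``.  Complexes are grown
greedily outward from unvisited highest-weight seeds, admitting a neighbor
whenever its weight is within ``vwp`` (vertex weight percentage) of the
seed's weight; each vertex belongs to at most one complex.  A module's score
is its density times its size, and modules are reported above a score
threshold — by default *strictly* above 2, with an inclusive variant exposed
because borderline two-node complexes sit exactly at score 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .network_build import IntegratedNetwork

__all__ = ["DenseModule", "vertex_weights", "find_modules"]


@dataclass(frozen=True)
class DenseModule:
    """A detected complex: connected member set with density-based score."""

    members: frozenset[str]
    seed_node: str
    density: float
    score: float  # density * len(members)


def _ppi_graph(net: IntegratedNetwork | nx.Graph) -> nx.Graph:
    return net.ppi_graph() if isinstance(net, IntegratedNetwork) else net


def vertex_weights(net: IntegratedNetwork | nx.Graph) -> dict[str, float]:
    """MCODE vertex weighting over the PPI layer.

    For each vertex v, take the induced subgraph on the closed neighborhood
    N[v], find its highest k-core, and set
    ``weight(v) = k_max × density(core)``.  Isolated vertices weigh 0; a
    vertex inside a (k+1)-clique weighs k.
    """
    g = _ppi_graph(net)
    weights: dict[str, float] = {}
    for v in g.nodes:
        nbrs = set(g[v])
        if not nbrs:
            weights[v] = 0.0
            continue
        sub = g.subgraph(nbrs | {v})
        core = nx.core_number(sub)
        k_max = max(core.values())
        if k_max == 0:
            weights[v] = 0.0
            continue
        core_nodes = [u for u, k in core.items() if k >= k_max]
        weights[v] = k_max * nx.density(sub.subgraph(core_nodes))
    return weights


def _module_stats(g: nx.Graph, members: set[str]) -> tuple[float, float]:
    n = len(members)
    if n < 2:
        return 0.0, 0.0
    e = g.subgraph(members).number_of_edges()
    density = 2.0 * e / (n * (n - 1))
    return density, density * n


def find_modules(
    net: IntegratedNetwork | nx.Graph,
    vwp: float = 0.2,
    min_score: float = 2.0,
    haircut: bool = True,
    inclusive: bool = False,
) -> list[DenseModule]:
    """Detect dense modules by seeded growth from high-weight vertices.

    A neighbor joins a growing module when its weight is at least
    ``(1 − vwp) ×`` the seed's weight; growth is breadth-first and each
    vertex is assigned to at most one module.  ``haircut`` iteratively
    removes members with fewer than two within-module neighbors (skipped for
    two-node modules, which are otherwise unreportable).  Modules scoring
    above ``min_score`` (or ``>=`` with ``inclusive``) are returned sorted by
    score, then size, then seed symbol.
    """
    if not 0.0 <= vwp < 1.0:
        raise ValueError("vwp must lie in [0, 1)")
    g = _ppi_graph(net)
    weights = vertex_weights(g)
    order = sorted(g.nodes, key=lambda v: (-weights[v], v))
    assigned: set[str] = set()
    modules: list[DenseModule] = []
    for seed in order:
        if seed in assigned or weights[seed] <= 0.0:
            continue
        threshold = (1.0 - vwp) * weights[seed]
        members = {seed}
        frontier = [seed]
        examined = {seed}
        while frontier:
            u = frontier.pop()
            for v in g[u]:
                if v in examined or v in assigned:
                    continue
                examined.add(v)
                if weights[v] >= threshold:
                    members.add(v)
                    frontier.append(v)
        if haircut and len(members) > 2:
            while True:
                sub = g.subgraph(members)
                trim = [v for v in members if sub.degree(v) < 2]
                if not trim:
                    break
                members -= set(trim)
                if len(members) <= 2:
                    break
        if not members:
            continue
        density, score = _module_stats(g, members)
        keep = score >= min_score if inclusive else score > min_score
        assigned |= members
        if keep:
            modules.append(
                DenseModule(members=frozenset(members), seed_node=seed, density=density, score=score)
            )
    modules.sort(key=lambda m: (-m.score, -len(m.members), m.seed_node))
    return modules
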