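"""Assembly of the integrated colored regulatory/PPI network.

The central object is :class:`IntegratedNetwork`: nodes are differentially
expressed genes and differentially expressed transcription factors (DE-TFs),
colored ``up``/``down`` by expression direction, connected by two edge
layers — directed regulatory edges (TF → target, from a ChIP-derived
catalog) and undirected protein–protein interaction edges.  PPI edges are
admitted only when both interactors are themselves nodes of the network,
i.e. differentially expressed: this is the computable reading of filtering
interactions by the expression profiles of the interacting counterparts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import networkx as nx
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .diffexpr import DEResult
    from .io_formats import GeneSetCollection

__all__ = [
    "NodeData",
    "IntegratedNetwork",
    "build_regulatory_network",
    "build_tf_ppi_network",
]


@dataclass
class NodeData:
    """Per-node annotation: expression color, role and DE statistics."""

    color: str | None = None  # "up" | "down" | None (unmeasured PPI partner)
    role: str = "gene"  # "tf" | "gene" | "both"
    log2_fc: float | None = None
    p_value: float | None = None
    self_regulating: bool = False


@dataclass
class IntegratedNetwork:
    """Mixed network: directed ``reg_edges`` plus undirected ``ppi_edges``.

    Undirected edges are stored once with lexicographically ordered endpoints.
    Regulatory self-loops (a TF targeting itself) are retained and flagged on
    the node; PPI self-loops are rejected.
    """

    nodes: dict[str, NodeData] = field(default_factory=dict)
    reg_edges: set[tuple[str, str]] = field(default_factory=set)
    ppi_edges: set[tuple[str, str]] = field(default_factory=set)

    # -- construction -------------------------------------------------------

    def add_node(self, name: str, data: NodeData | None = None) -> None:
        if name not in self.nodes:
            self.nodes[name] = data or NodeData()
        elif data is not None:
            self.nodes[name] = data

    def add_reg_edge(self, tf: str, target: str) -> None:
        self.add_node(tf)
        self.add_node(target)
        self.reg_edges.add((tf, target))
        if tf == target:
            self.nodes[tf].self_regulating = True

    def add_ppi_edge(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"PPI self-loop {a!r} not allowed")
        self.add_node(a)
        self.add_node(b)
        self.ppi_edges.add((min(a, b), max(a, b)))

    # -- views --------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.reg_edges) + len(self.ppi_edges)

    def tf_nodes(self) -> set[str]:
        return {n for n, d in self.nodes.items() if d.role in ("tf", "both")}

    def union_adjacency(self) -> dict[str, set[str]]:
        """Neighbour sets under the union of both layers (self-loops dropped)."""
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for a, b in self.reg_edges:
            if a != b:
                adj[a].add(b)
                adj[b].add(a)
        for a, b in self.ppi_edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def union_graph(self) -> nx.Graph:
        """Undirected simple graph over the union of layers, with node attrs."""
        g = nx.Graph()
        for n, d in self.nodes.items():
            g.add_node(n, color=d.color, role=d.role, log2_fc=d.log2_fc, p_value=d.p_value)
        for a, b in self.reg_edges:
            if a != b:
                g.add_edge(a, b)
        g.add_edges_from(self.ppi_edges)
        return g

    def ppi_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.ppi_edges)
        return g

    def copy(self) -> "IntegratedNetwork":
        return IntegratedNetwork(
            nodes={n: NodeData(**vars(d)) for n, d in self.nodes.items()},
            reg_edges=set(self.reg_edges),
            ppi_edges=set(self.ppi_edges),
        )


def _node_from_de(de: "DEResult", gene: str, role: str) -> NodeData:
    row = de.table.loc[gene]
    lfc = float(row["log2_fc"])
    return NodeData(
        color="up" if lfc >= 0 else "down",
        role=role,
        log2_fc=lfc,
        p_value=float(row["p_value"]),
    )


def _de_tf_list(de_tfs: "pd.DataFrame | Sequence[str]") -> list[str]:
    if isinstance(de_tfs, pd.DataFrame):
        if "is_de_tf" in de_tfs.columns:
            return list(de_tfs.loc[de_tfs["is_de_tf"], "tf"])
        return list(de_tfs["tf"])
    return list(de_tfs)


def build_regulatory_network(
    de: "DEResult",
    de_tfs: "pd.DataFrame | Sequence[str]",
    catalog: "GeneSetCollection",
    ppi: Iterable[tuple[str, str]] = (),
) -> IntegratedNetwork:
    """Build the main integrated network from DE calls and DE-TFs.

    Regulatory edges are ``(f, g)`` for every DE-TF *f* and target
    ``g ∈ targets(f) ∩ DE``; nodes are the DE-TFs plus their regulated DE
    genes; PPI edges are kept iff both endpoints are nodes (hence DE).

    Raises ``ValueError("empty regulator set")`` when no DE-TFs are given.
    """
    tf_list = _de_tf_list(de_tfs)
    if not tf_list:
        raise ValueError("empty regulator set")
    de_set = de.de_genes
    net = IntegratedNetwork()
    measured = set(de.table.index)
    for tf in tf_list:
        role = "both" if tf in de_set else "tf"
        if tf in measured:
            data = _node_from_de(de, tf, role)
        else:  # DE-TF status requires measurement; guard for hand-built inputs
            data = NodeData(role=role)
        net.add_node(tf, data)
    tf_set = set(tf_list)
    for tf in tf_list:
        targets = catalog.sets.get(tf, frozenset()) if tf in catalog else frozenset()
        for g in sorted(targets & de_set):
            if g not in net.nodes:
                role = "both" if g in tf_set else "gene"
                net.add_node(g, _node_from_de(de, g, role))
            elif net.nodes[g].role == "tf":
                net.nodes[g].role = "both"
            net.add_reg_edge(tf, g)
    node_set = set(net.nodes)
    for a, b in ppi:
        if a in node_set and b in node_set and a != b:
            net.add_ppi_edge(a, b)
    return net


def build_tf_ppi_network(
    de_tfs: "pd.DataFrame | Sequence[str]",
    ppi: Iterable[tuple[str, str]],
    de: "DEResult | None" = None,
) -> IntegratedNetwork:
    """Build the TF protein–protein interaction network.

    Nodes are the DE-TF proteins plus their direct PPI partners; edges are
    all PPI pairs between those nodes (so partner–partner interactions are
    retained); the regulatory layer is empty.  Expression annotation is
    attached where a DE result is supplied and the protein was measured.
    """
    tf_list = _de_tf_list(de_tfs)
    tf_set = set(tf_list)
    ppi = [(a, b) for a, b in ppi if a != b]
    partners: set[str] = set()
    for a, b in ppi:
        if a in tf_set:
            partners.add(b)
        if b in tf_set:
            partners.add(a)
    node_set = tf_set | partners
    net = IntegratedNetwork()
    measured = set(de.table.index) if de is not None else set()
    for n in sorted(node_set):
        role = "tf" if n in tf_set else "gene"
        if de is not None and n in measured:
            net.add_node(n, _node_from_de(de, n, role))
        else:
            net.add_node(n, NodeData(role=role))
    for a, b in ppi:
        if a in node_set and b in node_set:
            net.add_ppi_edge(a, b)
    return net
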