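"""Readers, writers and run configuration.

External representations handled here:

* **GMT** — gene-set collections (TF→target catalogs in the style of curated
  ChIP-enrichment databases, and pathway/process gene sets).
* **TSV** — expression matrices (genes × samples), sample→condition tables
  and protein–protein interaction (PPI) edge lists.
* **SIF / GraphML** — network exports compatible with Cytoscape-era tooling.
* **flat YAML mapping** — run configuration (:class:`RunConfig`).

Gene symbols arriving from heterogeneous sources mix cases (ChIP catalogs are
typically upper-case, mouse PPI exports title-case).  Every symbol is
normalised to a single canonical capitalised form at parse time so that joins
across sources are well defined.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import pandas as pd
import yaml

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .network_build import IntegratedNetwork

__all__ = [
    "ParseError",
    "ConfigError",
    "canonical_symbol",
    "GeneSetCollection",
    "ExpressionMatrix",
    "RunConfig",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "read_group_labels",
    "read_ppi",
    "write_ppi",
    "write_network",
    "read_network",
]


class ParseError(ValueError):
    """Malformed external input (GMT/TSV/SIF/GraphML)."""


class ConfigError(ValueError):
    """Invalid run configuration (bad value or unknown key)."""


def canonical_symbol(raw: str) -> str:
    """Return the canonical capitalised form of a gene symbol.

    ``"SOX2"``, ``"sox2"`` and ``"Sox2"`` all map to ``"Sox2"``.  Leading and
    trailing whitespace is stripped; an empty symbol is a :class:`ParseError`.
    """
    sym = raw.strip()
    if not sym:
        raise ParseError("empty gene symbol")
    return sym[0].upper() + sym[1:].lower()


# ---------------------------------------------------------------------------
# Gene set collections (GMT)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets: a TF→target catalog or pathway collection.

    ``sets`` maps a unique set name to a frozenset of member symbols; no set
    is empty and every member is a non-empty symbol.
    """

    sets: Mapping[str, frozenset[str]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)

    @classmethod
    def from_dict(
        cls, sets: Mapping[str, Iterable[str]], descriptions: Mapping[str, str] | None = None
    ) -> "GeneSetCollection":
        return cls(
            sets={name: frozenset(members) for name, members in sets.items()},
            descriptions=dict(descriptions or {}),
        )


def read_gmt(path: str | Path, *, symbol_names: bool = True) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Each line: ``name<TAB>description<TAB>member1<TAB>member2...``.  Members
    are whitespace-trimmed, case-normalised and de-duplicated within a line.
    With ``symbol_names`` (the default, appropriate for TF→target catalogs
    whose set names are themselves gene symbols) set names are case-normalised
    too; pathway collections should pass ``symbol_names=False``.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path.name}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields (name, description, members...), got {len(parts)}"
                )
            name = parts[0].strip()
            if symbol_names:
                name = canonical_symbol(name)
            if not name:
                raise ParseError(f"{path.name}:{lineno}: empty set name")
            if name in sets:
                raise ParseError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            try:
                members = frozenset(canonical_symbol(m) for m in parts[2:] if m.strip())
            except ParseError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
            if not members:
                raise ParseError(f"{path.name}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
            descriptions[name] = parts[1]
    if not sets:
        raise ParseError(f"{path.name}: no gene sets")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT (members sorted for determinism)."""
    path = Path(path)
    with path.open("w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Numeric expression values (genes × samples) in two labeled conditions.

    ``values`` rows are keyed by canonical gene symbol (duplicates permitted
    until :func:`tfnetminer.diffexpr.collapse_duplicates`); ``groups`` maps
    every sample column to one of exactly two condition labels.
    """

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ParseError(f"samples missing from group labels: {missing}")
        present = {s: g for s, g in self.groups.items() if s in set(self.values.columns)}
        conds = sorted(set(present.values()))
        if len(conds) != 2:
            raise ParseError(
                f"expected exactly two conditions with samples, got {conds!r}"
            )
        for cond in conds:
            if not any(g == cond for g in present.values()):
                raise ParseError(f"condition {cond!r} has zero samples")
        self.groups = present

    @property
    def conditions(self) -> tuple[str, str]:
        """The two condition labels, sorted; (A, B) order for fold changes."""
        a, b = sorted(set(self.groups.values()))
        return a, b

    def samples(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == condition]

    @property
    def n_genes(self) -> int:
        return len(self.values)


def read_expression(path: str | Path, group_labels: Mapping[str, str]) -> ExpressionMatrix:
    """Read a TSV expression matrix (header = sample IDs, first column = gene).

    Every sample in the header must appear in ``group_labels``; non-numeric
    cells raise a :class:`ParseError` naming the offending gene/sample.
    Duplicate gene symbols are retained (collapsed later by ``diffexpr``).
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.shape[1] == 0:
        raise ParseError(f"{path.name}: no sample columns")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    # values literally absent in the file are also an error: the matrix must be dense
    bad |= raw.isna()
    if bad.to_numpy().any():
        gi, si = next(zip(*bad.to_numpy().nonzero()))
        gene, sample = raw.index[gi], raw.columns[si]
        val = raw.iat[gi, si]
        raise ParseError(
            f"{path.name}: non-numeric value {val!r} at gene {gene!r}, sample {sample!r}"
        )
    numeric.index = [canonical_symbol(str(g)) for g in numeric.index]
    numeric.index.name = "gene"
    return ExpressionMatrix(values=numeric.astype(float), groups=dict(group_labels))


def read_group_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample, condition) into a mapping."""
    path = Path(path)
    out: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path.name}:{lineno}: expected sample<TAB>condition")
            out[parts[0].strip()] = parts[1].strip()
    if not out:
        raise ParseError(f"{path.name}: no sample labels")
    return out


# ---------------------------------------------------------------------------
# PPI edge lists
# ---------------------------------------------------------------------------


def read_ppi(path: str | Path) -> list[tuple[str, str]]:
    """Read a TSV PPI edge list (two symbol columns, extra columns ignored).

    Undirected edges are stored once with lexicographically ordered endpoints;
    duplicates and self-interactions are dropped.
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path.name}:{lineno}: expected two symbol columns")
            try:
                a, b = canonical_symbol(parts[0]), canonical_symbol(parts[1])
            except ParseError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
            if a == b:
                continue
            edges.add((min(a, b), max(a, b)))
    return sorted(edges)


def write_ppi(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    path = Path(path)
    normalised = sorted({(min(a, b), max(a, b)) for a, b in edges})
    with path.open("w") as fh:
        for a, b in normalised:
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Network export / import
# ---------------------------------------------------------------------------

_GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


def write_network(net: "IntegratedNetwork", path: str | Path, dialect: str = "sif") -> None:
    """Write an integrated network as SIF or GraphML.

    SIF uses relation tokens ``reg`` (directed, one line per TF→target) and
    ``pp`` (undirected, written once with the lexicographically smaller symbol
    first).  Output ordering is fixed, so identical networks produce
    byte-identical files.  GraphML carries node attributes (color, role,
    log2_fc, p_value) and per-edge direction.
    """
    if not net.nodes:
        raise ValueError("refusing to write an empty network")
    path = Path(path)
    if dialect == "sif":
        _write_sif(net, path)
    elif dialect == "graphml":
        _write_graphml(net, path)
    else:
        raise ValueError(f"unknown network dialect {dialect!r}")


def _write_sif(net: "IntegratedNetwork", path: Path) -> None:
    linked: set[str] = set()
    lines: list[str] = []
    for a, b in sorted(net.reg_edges):
        lines.append(f"{a}\treg\t{b}")
        linked |= {a, b}
    for a, b in sorted(net.ppi_edges):
        lines.append(f"{a}\tpp\t{b}")
        linked |= {a, b}
    for node in sorted(set(net.nodes) - linked):
        lines.append(node)
    path.write_text("\n".join(lines) + "\n")


def _write_graphml(net: "IntegratedNetwork", path: Path) -> None:
    ET.register_namespace("", _GRAPHML_NS)
    root = ET.Element(f"{{{_GRAPHML_NS}}}graphml")
    keys = [
        ("color", "node", "string"),
        ("role", "node", "string"),
        ("log2_fc", "node", "double"),
        ("p_value", "node", "double"),
        ("interaction", "edge", "string"),
    ]
    for kid, domain, ktype in keys:
        ET.SubElement(
            root,
            f"{{{_GRAPHML_NS}}}key",
            {"id": kid, "for": domain, "attr.name": kid, "attr.type": ktype},
        )
    graph = ET.SubElement(root, f"{{{_GRAPHML_NS}}}graph", {"edgedefault": "directed"})
    for name in sorted(net.nodes):
        data = net.nodes[name]
        el = ET.SubElement(graph, f"{{{_GRAPHML_NS}}}node", {"id": name})
        for kid, value in (
            ("color", data.color),
            ("role", data.role),
            ("log2_fc", data.log2_fc),
            ("p_value", data.p_value),
        ):
            if value is not None:
                sub = ET.SubElement(el, f"{{{_GRAPHML_NS}}}data", {"key": kid})
                sub.text = str(value)
    for a, b in sorted(net.reg_edges):
        el = ET.SubElement(graph, f"{{{_GRAPHML_NS}}}edge", {"source": a, "target": b})
        sub = ET.SubElement(el, f"{{{_GRAPHML_NS}}}data", {"key": "interaction"})
        sub.text = "reg"
    for a, b in sorted(net.ppi_edges):
        el = ET.SubElement(
            graph,
            f"{{{_GRAPHML_NS}}}edge",
            {"source": a, "target": b, "directed": "false"},
        )
        sub = ET.SubElement(el, f"{{{_GRAPHML_NS}}}data", {"key": "interaction"})
        sub.text = "pp"
    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def read_network(path: str | Path, dialect: str | None = None) -> "IntegratedNetwork":
    """Read a network written by :func:`write_network` (dialect from suffix)."""
    from .network_build import IntegratedNetwork, NodeData

    path = Path(path)
    if dialect is None:
        dialect = "graphml" if path.suffix.lower() in {".graphml", ".xml"} else "sif"
    net = IntegratedNetwork()
    if dialect == "sif":
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 1:
                    net.add_node(parts[0].strip())
                    continue
                if len(parts) != 3:
                    raise ParseError(f"{path.name}:{lineno}: malformed SIF line")
                a, rel, b = (p.strip() for p in parts)
                if rel == "reg":
                    net.add_reg_edge(a, b)
                elif rel == "pp":
                    net.add_ppi_edge(a, b)
                else:
                    raise ParseError(f"{path.name}:{lineno}: unknown relation {rel!r}")
        return net
    tree = ET.parse(path)
    ns = {"g": _GRAPHML_NS}
    graph = tree.getroot().find("g:graph", ns)
    if graph is None:
        raise ParseError(f"{path.name}: no <graph> element")
    for el in graph.findall("g:node", ns):
        attrs: dict[str, str] = {}
        for sub in el.findall("g:data", ns):
            attrs[sub.attrib["key"]] = sub.text or ""
        net.nodes[el.attrib["id"]] = NodeData(
            color=attrs.get("color"),
            role=attrs.get("role", "gene"),
            log2_fc=float(attrs["log2_fc"]) if "log2_fc" in attrs else None,
            p_value=float(attrs["p_value"]) if "p_value" in attrs else None,
        )
    for el in graph.findall("g:edge", ns):
        a, b = el.attrib["source"], el.attrib["target"]
        kind = None
        for sub in el.findall("g:data", ns):
            if sub.attrib["key"] == "interaction":
                kind = sub.text
        if kind == "pp" or el.attrib.get("directed") == "false":
            net.add_ppi_edge(a, b)
        else:
            net.add_reg_edge(a, b)
    return net


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Pipeline thresholds and sizes.

    Defaults follow the analysis protocol this package implements: restrictive
    3-fold change for DE genes, 2-fold + p <= 0.05 for DE-TFs, 1,000 random
    networks for the motif null with a z >= 2 flag, dense-complex score
    threshold 2, and a >= 2-of-3 within-study consensus rule.
    """

    de_fold_change_threshold: float = 3.0
    tf_fold_change_threshold: float = 2.0
    tf_enrichment_alpha: float = 0.05
    n_random_networks: int = 1000
    motif_z_threshold: float = 2.0
    mcode_score_threshold: float = 2.0
    mcode_score_inclusive: bool = False
    mcode_vwp: float = 0.2
    consensus_min_networks: int = 2
    hub_top_n: int = 25
    active_n_modules: int = 5
    active_max_size: int = 50
    expression_scale: str = "log2"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "de_fold_change_threshold",
            "tf_fold_change_threshold",
            "mcode_score_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if not 0.0 < self.tf_enrichment_alpha < 1.0:
            raise ConfigError("tf_enrichment_alpha must be in (0, 1)")
        if self.n_random_networks < 1:
            raise ConfigError("n_random_networks must be a positive integer")
        if self.consensus_min_networks < 1:
            raise ConfigError("consensus_min_networks must be a positive integer")
        if not 0.0 <= self.mcode_vwp < 1.0:
            raise ConfigError("mcode_vwp must lie in [0, 1)")
        if self.hub_top_n < 1 or self.active_n_modules < 1 or self.active_max_size < 1:
            raise ConfigError("hub_top_n/active_n_modules/active_max_size must be positive")
        if self.expression_scale not in {"log2", "linear"}:
            raise ConfigError("expression_scale must be 'log2' or 'linear'")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a flat YAML mapping; unknown keys are errors."""
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path.name}: config must be a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"{path.name}: unknown config keys {unknown}")
        return cls(**raw)

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)
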