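"""Synthetic study generator with planted ground truth.

Emulates the statistical structure of a two-condition microarray comparison
(fibroblast vs induced neural stem cell) joined to a TF→target catalog and a
PPI layer, with every signal the downstream pipeline is supposed to find
*planted* and recorded in a :class:`PlantedTruth`:

* two-group log2 expression (baseline N(7, 1), per-sample noise N(0, 0.25))
  with a planted DE fraction, shifts ±|N(lfc_mean, lfc_sd)| split half
  up / half down;
* a TF catalog whose planted *enriched* TFs draw their targets
  preferentially from the DE pool (``enrichment_boost``) and are themselves
  planted as upregulated genes, so they can pass the DE-TF fold-change rule;
* a PPI layer containing fully connected planted cliques among TF proteins
  (the first clique holds the enriched TFs, a PRC2-like structure) over a
  sparse random background;
* a connected low-p active module: DE genes wired as targets of the enriched
  TFs, connected through them in the integrated network.

Smaller self-contained generators (:func:`planted_motif_network`,
:func:`er_mixed_network`, :func:`planted_clique_ppi`,
:func:`planted_p_network`) build benchmark graphs with planted structure for
the motif, complex and active-module stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneSetCollection, write_gmt, write_ppi
from .network_build import IntegratedNetwork, NodeData

__all__ = [
    "PlantedTruth",
    "SimulatedStudy",
    "simulate_study",
    "write_study",
    "planted_motif_network",
    "er_mixed_network",
    "planted_clique_ppi",
    "planted_p_network",
]

CONDITION_A = "fibroblast"
CONDITION_B = "insc"


@dataclass
class PlantedTruth:
    """Ground truth planted by :func:`simulate_study`."""

    de_genes_up: set[str]
    de_genes_down: set[str]
    enriched_tfs: set[str]
    ppi_cliques: list[set[str]]
    active_module_nodes: set[str]
    seed: int

    def __post_init__(self) -> None:
        if self.de_genes_up & self.de_genes_down:
            raise ValueError("planted up and down sets must be disjoint")

    @property
    def de_genes(self) -> set[str]:
        return self.de_genes_up | self.de_genes_down

    def to_json(self, path) -> None:
        payload = {
            "de_genes_up": sorted(self.de_genes_up),
            "de_genes_down": sorted(self.de_genes_down),
            "enriched_tfs": sorted(self.enriched_tfs),
            "ppi_cliques": [sorted(c) for c in self.ppi_cliques],
            "active_module_nodes": sorted(self.active_module_nodes),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            de_genes_up=set(payload["de_genes_up"]),
            de_genes_down=set(payload["de_genes_down"]),
            enriched_tfs=set(payload["enriched_tfs"]),
            ppi_cliques=[set(c) for c in payload["ppi_cliques"]],
            active_module_nodes=set(payload["active_module_nodes"]),
            seed=int(payload["seed"]),
        )


@dataclass
class SimulatedStudy:
    """Bundle of simulated inputs plus planted truth."""

    expression: ExpressionMatrix
    tf_catalog: GeneSetCollection
    ppi_edges: list[tuple[str, str]]
    pathways: GeneSetCollection
    truth: PlantedTruth


def _symbols(n_tfs: int, n_genes: int) -> tuple[list[str], list[str]]:
    tf_syms = [f"Tf{i:03d}" for i in range(1, n_tfs + 1)]
    gene_syms = tf_syms + [f"G{i:05d}" for i in range(1, n_genes - n_tfs + 1)]
    return tf_syms, gene_syms


def simulate_study(
    n_genes: int = 2000,
    n_samples_per_group: int = 3,
    de_fraction: float = 0.1,
    lfc_mean: float = 3.0,
    lfc_sd: float = 0.5,
    n_tfs: int = 200,
    targets_per_tf: int = 50,
    enrichment_boost: float = 8.0,
    n_enriched_tfs: int = 5,
    clique_sizes: tuple[int, ...] = (5, 4, 3),
    module_size: int = 15,
    n_pathways: int = 10,
    pathway_size: int = 40,
    seed: int = 0,
    noise_sd: float = 0.25,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.0,
) -> SimulatedStudy:
    """Generate a full planted study; fully reproducible from ``seed``.

    The first ``n_tfs`` gene symbols are TF-coding genes; planted enriched
    TFs are forced into the *up* DE set so the DE-TF expression rule can
    fire.  Per-TF regulon sizes are jittered Uniform(0.5, 1.5)× around
    ``targets_per_tf`` (real ChIP catalogs have widely dispersed regulon
    sizes).  ``enrichment_boost = 1`` reduces enriched TFs to background
    behaviour (null calibration).
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must be a probability")
    if n_tfs > n_genes:
        raise ValueError("n_tfs cannot exceed n_genes")
    if enrichment_boost < 1.0:
        raise ValueError("enrichment_boost must be >= 1")
    n_de = int(round(de_fraction * n_genes))
    if de_fraction > 0 and n_de < module_size:
        raise ValueError("infeasible sizes: de_fraction * n_genes < module_size")
    if n_enriched_tfs > n_tfs:
        raise ValueError("infeasible sizes: n_enriched_tfs > n_tfs")
    if any(c < 3 for c in clique_sizes):
        raise ValueError("clique sizes must be >= 3")
    if sum(clique_sizes) > n_tfs:
        raise ValueError("infeasible sizes: cliques need more TFs than available")
    rng = np.random.default_rng(seed)
    tf_syms, genes = _symbols(n_tfs, n_genes)
    gene_arr = np.array(genes)

    # ----- planted DE assignment ------------------------------------------
    enriched = list(tf_syms[:n_enriched_tfs]) if de_fraction > 0 else []
    if de_fraction > 0:
        remaining = [g for g in genes if g not in set(enriched)]
        extra = rng.choice(len(remaining), size=max(0, n_de - len(enriched)), replace=False)
        de_pool = enriched + [remaining[i] for i in sorted(extra)]
        n_up = (n_de + 1) // 2
        # enriched TFs first so they always land in the up half
        others = [g for g in de_pool if g not in set(enriched)]
        order = enriched + [others[i] for i in rng.permutation(len(others))]
        up = set(order[:n_up])
        down = set(order[n_up:])
    else:
        up, down = set(), set()
    de_set = up | down

    # ----- expression matrix ----------------------------------------------
    n_s = n_samples_per_group
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    shift = np.zeros(n_genes)
    for i, g in enumerate(genes):
        if g in up:
            shift[i] = abs(rng.normal(lfc_mean, lfc_sd))
        elif g in down:
            shift[i] = -abs(rng.normal(lfc_mean, lfc_sd))
    data = np.empty((n_genes, 2 * n_s))
    data[:, :n_s] = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_s))
    data[:, n_s:] = (baseline + shift)[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_s))
    samples = [f"fib_{i+1}" for i in range(n_s)] + [f"insc_{i+1}" for i in range(n_s)]
    groups = {s: (CONDITION_A if s.startswith("fib") else CONDITION_B) for s in samples}
    expression = ExpressionMatrix(
        values=pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=samples),
        groups=groups,
    )

    # ----- TF -> target catalog -------------------------------------------
    de_arr = np.array(sorted(de_set)) if de_set else np.array([], dtype=object)
    w = min(0.9, de_fraction * enrichment_boost) if de_set else 0.0
    catalog_sets: dict[str, set[str]] = {}
    enriched_set = set(enriched)
    for tf in tf_syms:
        size = max(5, int(round(rng.uniform(0.5, 1.5) * targets_per_tf)))
        size = min(size, n_genes)
        if tf in enriched_set and len(de_set) > 0:
            n_from_de = int(rng.binomial(size, w))
            n_from_de = min(n_from_de, len(de_arr))
            targets = {str(t) for t in rng.choice(de_arr, size=n_from_de, replace=False)}
            while len(targets) < size:
                targets.add(str(gene_arr[rng.integers(0, n_genes)]))
        else:
            targets = {str(t) for t in rng.choice(gene_arr, size=size, replace=False)}
        catalog_sets[tf] = targets
    # ----- active module: DE genes wired to the enriched TFs --------------
    if de_fraction > 0 and enriched:
        module_pool = sorted(de_set - enriched_set)
        idx = rng.choice(len(module_pool), size=min(module_size, len(module_pool)), replace=False)
        module_genes = [module_pool[i] for i in sorted(idx)]
        for j, g in enumerate(module_genes):
            catalog_sets[enriched[j % len(enriched)]].add(g)
        active_nodes = set(module_genes) | enriched_set
    else:
        active_nodes = set()
    catalog = GeneSetCollection.from_dict(
        catalog_sets, descriptions={tf: "simulated regulon" for tf in tf_syms}
    )

    # ----- PPI layer -------------------------------------------------------
    cliques: list[set[str]] = []
    used: set[str] = set()
    pool = list(tf_syms)
    ppi: set[tuple[str, str]] = set()
    for ci, size in enumerate(clique_sizes):
        if ci == 0 and enriched:
            members = list(enriched)
            for tf in pool:
                if len(members) >= size:
                    break
                if tf not in set(members):
                    members.append(tf)
            members = members[:size]
        else:
            avail = [t for t in pool if t not in used]
            pick = rng.choice(len(avail), size=size, replace=False)
            members = [avail[i] for i in sorted(pick)]
        used |= set(members)
        cliques.append(set(members))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                ppi.add((min(a, b), max(a, b)))
    background_p = 0.02
    n_pairs = rng.binomial(n_tfs * (n_tfs - 1) // 2, background_p)
    for _ in range(n_pairs):
        i, j = rng.integers(0, n_tfs, size=2)
        if i != j:
            a, b = tf_syms[i], tf_syms[j]
            ppi.add((min(a, b), max(a, b)))

    # ----- pathway gene sets ----------------------------------------------
    pw_sets = {}
    for p in range(1, n_pathways + 1):
        pick = rng.choice(n_genes, size=min(pathway_size, n_genes), replace=False)
        pw_sets[f"pathway_{p:02d}"] = {genes[i] for i in pick}
    pathways = GeneSetCollection.from_dict(
        pw_sets, descriptions={k: "simulated pathway" for k in pw_sets}
    )

    truth = PlantedTruth(
        de_genes_up=up,
        de_genes_down=down,
        enriched_tfs=enriched_set,
        ppi_cliques=cliques,
        active_module_nodes=active_nodes,
        seed=seed,
    )
    return SimulatedStudy(
        expression=expression,
        tf_catalog=catalog,
        ppi_edges=sorted(ppi),
        pathways=pathways,
        truth=truth,
    )


def write_study(study: SimulatedStudy, out_dir) -> None:
    """Write expression.tsv, groups.tsv, tf_targets.gmt, ppi.tsv,
    pathways.gmt and truth.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.expression.values.to_csv(out / "expression.tsv", sep="\t")
    with (out / "groups.tsv").open("w") as fh:
        for sample, cond in study.expression.groups.items():
            fh.write(f"{sample}\t{cond}\n")
    write_gmt(study.tf_catalog, out / "tf_targets.gmt")
    write_ppi(study.ppi_edges, out / "ppi.tsv")
    write_gmt(study.pathways, out / "pathways.gmt")
    study.truth.to_json(out / "truth.json")


# ---------------------------------------------------------------------------
# Benchmark graphs with planted structure
# ---------------------------------------------------------------------------


def planted_motif_network(
    n_copies: int = 40,
    n_noise_reg: int = 30,
    n_noise_ppi: int = 30,
    seed: int = 0,
) -> tuple[IntegratedNetwork, int]:
    """Disjoint copies of the co-regulated interacting-pair pattern plus noise.

    Each copy is one upregulated TF regulating two genes (one up, one down)
    whose proteins interact: reg T→A, reg T→B, ppi A–B.  Random regulatory
    and PPI noise edges are added across copies.  Returns the network and the
    canonical code of the planted class.
    """
    from .motif_census import canonical_code

    rng = np.random.default_rng(seed)
    net = IntegratedNetwork()
    names: list[str] = []
    for c in range(n_copies):
        t, a, b = f"T{c:03d}", f"A{c:03d}", f"B{c:03d}"
        net.add_node(t, NodeData(color="up", role="tf"))
        net.add_node(a, NodeData(color="up", role="gene"))
        net.add_node(b, NodeData(color="down", role="gene"))
        net.add_reg_edge(t, a)
        net.add_reg_edge(t, b)
        net.add_ppi_edge(a, b)
        names += [t, a, b]
    n = len(names)
    added = 0
    while added < n_noise_reg:
        i, j = rng.integers(0, n, size=2)
        if i == j or (names[i], names[j]) in net.reg_edges:
            continue
        net.add_reg_edge(names[i], names[j])
        added += 1
    added = 0
    while added < n_noise_ppi:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        a, b = sorted((names[i], names[j]))
        if (a, b) in net.ppi_edges:
            continue
        net.add_ppi_edge(a, b)
        added += 1
    planted = canonical_code((1, 1, 0), reg=[(0, 1), (0, 2)], ppi=[(1, 2)])
    return net, planted


def er_mixed_network(
    n: int = 30,
    p_reg: float = 0.06,
    p_ppi: float = 0.06,
    seed: int = 0,
) -> IntegratedNetwork:
    """Erdős–Rényi mixed colored graph with no planted structure."""
    rng = np.random.default_rng(seed)
    net = IntegratedNetwork()
    names = [f"N{i:03d}" for i in range(n)]
    colors = rng.integers(0, 2, size=n)
    for name, c in zip(names, colors):
        net.add_node(name, NodeData(color="up" if c else "down"))
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p_reg:
                net.add_reg_edge(names[i], names[j])
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_ppi:
                net.add_ppi_edge(names[i], names[j])
    return net


def planted_clique_ppi(
    clique_sizes: tuple[int, ...] = (5, 5),
    n_background: int = 20,
    p_background: float = 0.05,
    n_bridges: int = 2,
    seed: int = 0,
) -> tuple[IntegratedNetwork, list[set[str]]]:
    """Node-disjoint planted cliques plus a sparse ER background component.

    Background edges run among background nodes only; ``n_bridges`` single
    edges tie background nodes to clique members (they never change the
    clique's core structure).  Returns the network and the planted cliques.
    """
    rng = np.random.default_rng(seed)
    net = IntegratedNetwork()
    cliques: list[set[str]] = []
    for ci, size in enumerate(clique_sizes):
        members = [f"C{ci}{chr(ord('a') + k)}" for k in range(size)]
        for m in members:
            net.add_node(m, NodeData(color="up"))
        for i in range(size):
            for j in range(i + 1, size):
                net.add_ppi_edge(members[i], members[j])
        cliques.append(set(members))
    bg = [f"X{i:02d}" for i in range(n_background)]
    for b in bg:
        net.add_node(b, NodeData(color="down"))
    for i in range(n_background):
        for j in range(i + 1, n_background):
            if rng.random() < p_background:
                net.add_ppi_edge(bg[i], bg[j])
    clique_nodes = sorted(set().union(*cliques)) if cliques else []
    for _ in range(min(n_bridges, len(bg))):
        b = bg[rng.integers(0, len(bg))]
        c = clique_nodes[rng.integers(0, len(clique_nodes))]
        net.add_ppi_edge(b, c)
    return net, cliques


def planted_p_network(
    n_nodes: int = 300,
    module_size: int = 15,
    p_low: float = 0.01,
    extra_edge_factor: float = 0.3,
    seed: int = 0,
) -> tuple[IntegratedNetwork, dict[str, float], set[str]]:
    """Connected background graph with one planted low-p connected module.

    Background topology is a random spanning tree plus random extra edges
    (~``extra_edge_factor``·n, average degree ≈ 2.6 — the sparse regime of
    biological interaction networks); the planted module is a random tree
    over ``module_size`` nodes with a few shortcuts.  Module p-values are
    drawn Uniform(0, ``p_low``), all others Uniform(0, 1).  Returns the
    network, the node→p map and the planted member set.
    """
    rng = np.random.default_rng(seed)
    names = [f"N{i:03d}" for i in range(n_nodes)]
    net = IntegratedNetwork()
    for nm in names:
        net.add_node(nm, NodeData(color="up"))
    order = rng.permutation(n_nodes)
    for k in range(1, n_nodes):
        a = names[order[k]]
        b = names[order[rng.integers(0, k)]]
        net.add_ppi_edge(a, b)
    for _ in range(int(extra_edge_factor * n_nodes)):
        i, j = rng.integers(0, n_nodes, size=2)
        if i != j:
            net.add_ppi_edge(names[i], names[j])
    module_idx = rng.choice(n_nodes, size=module_size, replace=False)
    module = [names[i] for i in module_idx]
    for k in range(1, module_size):
        net.add_ppi_edge(module[k], module[rng.integers(0, k)])
    for _ in range(module_size // 3):
        i, j = rng.integers(0, module_size, size=2)
        if i != j:
            net.add_ppi_edge(module[i], module[j])
    module_set = set(module)
    p_values = {
        nm: (rng.uniform(0.0, p_low) if nm in module_set else rng.uniform(0.0, 1.0))
        for nm in names
    }
    p_values = {nm: max(p, 1e-15) for nm, p in p_values.items()}
    return net, p_values, module_set
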