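"""End-to-end orchestration of a single-study analysis.

``run_study`` chains the stages in the order the analysis protocol
prescribes: collapse duplicate probes → fold-change DE calling → TF-target
enrichment (DE-TF nomination) → integrated network assembly → motif census →
centrality hub ranking → dense-complex detection in the TF PPI network →
active-module search → TF-per-pathway scoring → within-study consensus.
``compare_studies`` applies the cross-study consensus rule to several
completed studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .active_modules import ActiveModule, search_modules
from .centrality import compute_centralities, rank_hubs
from .diffexpr import DEResult, call_de, collapse_duplicates
from .enrichment import de_tf_symbols, tf_enrich
from .io_formats import ExpressionMatrix, GeneSetCollection, RunConfig
from .mcode import DenseModule, find_modules
from .motif_census import MotifCensus, motif_zscores
from .network_build import IntegratedNetwork, build_regulatory_network, build_tf_ppi_network
from .tf_ranking import (
    ConsensusReport,
    TFPathwayMatrix,
    build_consensus_report,
    cross_study_overlap,
    pathway_fraction_matrix,
)

__all__ = ["StudyResult", "run_study", "compare_studies"]


@dataclass
class StudyResult:
    """Everything one study's pipeline run produces."""

    de: DEResult
    tf_table: pd.DataFrame
    network: IntegratedNetwork
    tf_ppi: IntegratedNetwork
    motifs: MotifCensus | None
    centrality: pd.DataFrame
    hubs: pd.DataFrame
    complexes: list[DenseModule]
    active: list[ActiveModule]
    tf_pathways: TFPathwayMatrix | None
    consensus: ConsensusReport
    config: RunConfig

    @property
    def de_tfs(self) -> list[str]:
        return de_tf_symbols(self.tf_table)


def run_study(
    expression: ExpressionMatrix,
    tf_catalog: GeneSetCollection,
    ppi_edges: Iterable[tuple[str, str]],
    pathways: GeneSetCollection | None = None,
    config: RunConfig | None = None,
    compute_motifs: bool = True,
) -> StudyResult:
    """Run the full single-study pipeline; see the module docstring.

    Raises ``ValueError`` when no gene passes the DE threshold or no TF
    qualifies as a DE-TF (downstream stages would be vacuous).
    """
    cfg = config or RunConfig()
    ppi_edges = list(ppi_edges)

    matrix = collapse_duplicates(expression, scale=cfg.expression_scale)
    de = call_de(matrix, cfg.de_fold_change_threshold, scale=cfg.expression_scale)
    if not de.de_genes:
        raise ValueError("no genes pass the DE fold-change threshold")
    universe = set(matrix.values.index)
    tf_table = tf_enrich(
        de.de_genes,
        tf_catalog,
        universe,
        de=de,
        alpha=cfg.tf_enrichment_alpha,
        tf_fc_threshold=cfg.tf_fold_change_threshold,
    )
    detfs = de_tf_symbols(tf_table)
    network = build_regulatory_network(de, tf_table, tf_catalog, ppi_edges)
    tf_ppi = build_tf_ppi_network(detfs, ppi_edges, de=de)

    motifs = None
    if compute_motifs and network.n_nodes >= 3:
        motifs = motif_zscores(
            network,
            n_random=cfg.n_random_networks,
            seed=cfg.rng_seed,
            z_threshold=cfg.motif_z_threshold,
        )

    centrality = compute_centralities(network)
    hubs = rank_hubs(centrality, cfg.hub_top_n)
    complexes = find_modules(
        tf_ppi,
        vwp=cfg.mcode_vwp,
        min_score=cfg.mcode_score_threshold,
        inclusive=cfg.mcode_score_inclusive,
    )
    p_values = {n: network.nodes[n].p_value for n in network.nodes}
    active = search_modules(
        network,
        p_values,
        n_modules=cfg.active_n_modules,
        max_size=cfg.active_max_size,
        seed=cfg.rng_seed,
    )
    tf_pw = None
    if pathways is not None:
        tf_pw = pathway_fraction_matrix(de.de_genes, tf_catalog, pathways)

    detf_set = set(detfs)
    hub_tfs = [n for n in hubs.index if n in detf_set]
    complex_tfs = sorted({m for mod in complexes for m in mod.members if m in detf_set})
    active_tfs = sorted({m for mod in active for m in mod.member_tfs})
    directions = {
        tf: ("up" if tf_table.set_index("tf").at[tf, "tf_log2_fc"] >= 0 else "down")
        for tf in detfs
    }
    consensus = build_consensus_report(
        {"hubs": hub_tfs, "complexes": complex_tfs, "active_modules": active_tfs},
        m=cfg.consensus_min_networks,
        directions=directions,
    )
    return StudyResult(
        de=de,
        tf_table=tf_table,
        network=network,
        tf_ppi=tf_ppi,
        motifs=motifs,
        centrality=centrality,
        hubs=hubs,
        complexes=complexes,
        active=active,
        tf_pathways=tf_pw,
        consensus=consensus,
        config=cfg,
    )


def compare_studies(results: Mapping[str, StudyResult]) -> ConsensusReport:
    """Cross-study consensus over per-study master regulators.

    Each study contributes its within-study master regulators with their
    expression direction and the number of supporting analyses; concordant
    TFs common to all studies become the cross-study master regulators.
    """
    per_study = {
        name: [
            (tf, res.consensus.directions.get(tf, "up"), res.consensus.support.get(tf, 1))
            for tf in res.consensus.master_regulators
        ]
        for name, res in results.items()
    }
    return cross_study_overlap(per_study)
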