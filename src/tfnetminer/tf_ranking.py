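"""TF-per-pathway regulation scoring and consensus master-regulator ranking.

The pathway matrix gives, for each TF f and gene set P, the fraction of the
differentially expressed genes of P that f regulates:
``cell(f, P) = |targets(f) ∩ DE ∩ P| / |DE ∩ P|``.  Consensus operates at two
levels: *within* a study, TFs appearing in at least m of the named analysis
lists (hubs / complexes / active modules); *across* studies, TFs present in
every study, flagged concordant when their expression direction agrees
everywhere, and ranked by the number of supporting analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import GeneSetCollection

__all__ = [
    "TFPathwayMatrix",
    "ConsensusReport",
    "pathway_fraction_matrix",
    "rank_regulators_of_set",
    "within_study_consensus",
    "build_consensus_report",
    "cross_study_overlap",
]


@dataclass
class TFPathwayMatrix:
    """Per-TF, per-gene-set regulation fractions.

    ``fractions`` is TFs × set names with cells in [0, 1], rows sorted by row
    mean descending; ``support`` holds |DE ∩ P| per reported column.  Columns
    with zero support are absent, never 0/0.
    """

    fractions: pd.DataFrame
    support: pd.Series


def pathway_fraction_matrix(
    de_genes: Iterable[str],
    catalog: GeneSetCollection,
    pathways: GeneSetCollection,
) -> TFPathwayMatrix:
    de = set(de_genes)
    cols: dict[str, pd.Series] = {}
    support: dict[str, int] = {}
    for pname in pathways.names():
        de_in_p = pathways[pname] & de
        if not de_in_p:
            continue
        support[pname] = len(de_in_p)
        cols[pname] = pd.Series(
            {tf: len(catalog[tf] & de_in_p) / len(de_in_p) for tf in catalog.names()}
        )
    if not cols:
        frame = pd.DataFrame(index=pd.Index(catalog.names(), name="tf"))
        return TFPathwayMatrix(fractions=frame, support=pd.Series(dtype=int))
    frame = pd.DataFrame(cols)
    frame.index.name = "tf"
    frame = frame.loc[frame.mean(axis=1).sort_values(ascending=False, kind="stable").index]
    return TFPathwayMatrix(fractions=frame, support=pd.Series(support))


def rank_regulators_of_set(
    gene_set: Iterable[str],
    de_genes: Iterable[str],
    catalog: GeneSetCollection,
    top_n: int = 10,
) -> list[tuple[str, int]]:
    """TFs ranked by how many DE members of ``gene_set`` they target.

    Sorted by target count descending, ties alphabetical; truncated to
    ``top_n`` entries.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    pool = set(gene_set) & set(de_genes)
    scored = [(tf, len(catalog[tf] & pool)) for tf in catalog.names()]
    scored.sort(key=lambda item: (-item[1], item[0]))
    return scored[:top_n]


def within_study_consensus(lists: Mapping[str, Iterable[str]], m: int = 2) -> set[str]:
    """TFs appearing in at least ``m`` of the named analysis lists."""
    if m < 1:
        raise ValueError("m must be a positive integer")
    if m > len(lists):
        raise ValueError(f"m={m} exceeds the number of lists ({len(lists)})")
    counts: dict[str, int] = {}
    for members in lists.values():
        for tf in set(members):
            counts[tf] = counts.get(tf, 0) + 1
    return {tf for tf, c in counts.items() if c >= m}


@dataclass
class ConsensusReport:
    """Multi-level consensus over analyses and (optionally) studies."""

    analysis_lists: dict[str, list[str]]
    consensus: list[str]  # within-study consensus, sorted
    support: dict[str, int]  # TF -> number of supporting analyses
    master_regulators: list[str]
    cross_study: pd.DataFrame | None = None
    directions: dict[str, str] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "analysis_lists": self.analysis_lists,
            "consensus": self.consensus,
            "support": self.support,
            "master_regulators": self.master_regulators,
            "directions": self.directions,
        }
        if self.cross_study is not None:
            payload["cross_study"] = json.loads(self.cross_study.to_json(orient="index"))
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def build_consensus_report(
    lists: Mapping[str, Iterable[str]],
    m: int = 2,
    directions: Mapping[str, str] | None = None,
) -> ConsensusReport:
    """Single-study consensus: master regulators are the TFs supported by at
    least ``m`` analyses, ordered by (supporting analyses desc, symbol)."""
    consensus = within_study_consensus(lists, m)
    support: dict[str, int] = {}
    for members in lists.values():
        for tf in set(members):
            support[tf] = support.get(tf, 0) + 1
    master = sorted(consensus, key=lambda tf: (-support[tf], tf))
    return ConsensusReport(
        analysis_lists={name: sorted(set(v)) for name, v in lists.items()},
        consensus=sorted(consensus),
        support=support,
        master_regulators=master,
        directions=dict(directions or {}),
    )


def cross_study_overlap(
    per_study: Mapping[str, Sequence[tuple]],
) -> ConsensusReport:
    """Cross-study consensus over per-study (tf, direction[, n_analyses]) lists.

    TFs present in *all* studies are tabulated with their per-study direction
    and a concordance flag (identical direction everywhere); the master
    regulators are the concordant common TFs ordered by total supporting
    analyses (descending), then symbol.
    """
    if len(per_study) < 2:
        raise ValueError("cross-study overlap needs at least two studies")
    studies = list(per_study)
    info: dict[str, dict[str, tuple[str, int]]] = {}
    for study, entries in per_study.items():
        seen: dict[str, tuple[str, int]] = {}
        for entry in entries:
            tf, direction = entry[0], entry[1]
            n_analyses = int(entry[2]) if len(entry) > 2 else 1
            seen[tf] = (direction, n_analyses)
        info[study] = seen
    common = set.intersection(*(set(v) for v in info.values()))
    rows = []
    for tf in sorted(common):
        dirs = [info[s][tf][0] for s in studies]
        support = sum(info[s][tf][1] for s in studies)
        rows.append(
            {"tf": tf, **{s: info[s][tf][0] for s in studies},
             "concordant": len(set(dirs)) == 1, "n_supporting": support}
        )
    table = pd.DataFrame(rows).set_index("tf") if rows else pd.DataFrame(
        columns=[*studies, "concordant", "n_supporting"]
    )
    concordant = [tf for tf in sorted(common) if len({info[s][tf][0] for s in studies}) == 1]
    support_map = {tf: sum(info[s][tf][1] for s in studies) for tf in common}
    master = sorted(concordant, key=lambda tf: (-support_map[tf], tf))
    return ConsensusReport(
        analysis_lists={s: sorted(set(v)) for s, v in info.items()},
        consensus=sorted(common),
        support={tf: support_map[tf] for tf in sorted(common)},
        master_regulators=master,
        cross_study=table,
        directions={tf: info[studies[0]][tf][0] for tf in sorted(common)},
    )
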