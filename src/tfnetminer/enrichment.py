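"""TF-target and pathway over-representation statistics.

Two hypergeometric conventions are used, matching the tools they emulate:

* TF enrichment (ChEA-style): one-sided upper tail, ``P(X >= k)`` with
  population = measured universe, successes = catalog targets in the
  universe, draws = DE genes.  A TF is a *DE-TF* when its enrichment p-value
  is at most alpha **and** its own expression changes at least
  ``tf_fc_threshold``-fold (so TFs absent from the expression matrix can
  never be DE-TFs).
* Pathway enrichment (ClueGO-style "Enrichment versus Depletion"):
  two-sided doubled tail ``min(1, 2·min(P(X <= k), P(X >= k)))`` with Holm
  (Bonferroni step-down) correction across the tested sets.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

if TYPE_CHECKING:  # pragma: no cover
    from .diffexpr import DEResult

__all__ = [
    "hypergeom_upper_tail",
    "hypergeom_two_sided",
    "holm",
    "tf_enrich",
    "pathway_enrich",
    "de_tf_symbols",
]


def hypergeom_upper_tail(n_universe: int, n_marked: int, n_drawn: int, overlap: int) -> float:
    """``P(X >= overlap)`` for X ~ Hypergeom(n_universe, n_marked, n_drawn)."""
    return float(stats.hypergeom.sf(overlap - 1, n_universe, n_marked, n_drawn))


def hypergeom_two_sided(
    n_universe: int, n_marked: int, n_drawn: int, overlap: int
) -> tuple[float, str]:
    """Doubled-tail two-sided p and direction (enrichment vs depletion).

    Direction compares the observed overlap with the hypergeometric mean
    ``n_drawn * n_marked / n_universe``; an overlap at or above the mean is
    reported as enrichment.
    """
    lower = float(stats.hypergeom.cdf(overlap, n_universe, n_marked, n_drawn))
    upper = float(stats.hypergeom.sf(overlap - 1, n_universe, n_marked, n_drawn))
    p = min(1.0, 2.0 * min(lower, upper))
    mean = n_drawn * n_marked / n_universe if n_universe else 0.0
    return p, ("enrichment" if overlap >= mean else "depletion")


def holm(p_values: Sequence[float]) -> np.ndarray:
    """Holm (Bonferroni step-down) adjusted p-values, input order preserved."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="holm")[1]


def _validate_universe(de_genes: set[str], universe: set[str]) -> None:
    if not universe:
        raise ValueError("empty universe")
    if not de_genes:
        raise ValueError("empty DE gene list")
    stray = de_genes - universe
    if stray:
        raise ValueError(f"DE genes outside the universe: {sorted(stray)[:5]}...")


def tf_enrich(
    de_genes: Iterable[str],
    catalog: GeneSetCollection,
    universe: Iterable[str],
    de: "DEResult | None" = None,
    alpha: float = 0.05,
    tf_fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Score every catalog TF for target over-representation among DE genes.

    Returns one row per TF sorted by ascending p-value (ties by symbol) with
    columns ``tf, n_universe, n_targets, n_de, overlap, p_value,
    tf_fold_change, tf_log2_fc, is_de_tf``.  Fold-change columns are NaN for
    TFs not measured in the expression data (such TFs are never DE-TFs).
    """
    de_set = set(de_genes)
    uni = set(universe)
    _validate_universe(de_set, uni)
    n_universe, n_de = len(uni), len(de_set)
    rows = []
    for tf in catalog.names():
        targets = catalog[tf] & uni
        overlap = len(targets & de_set)
        p = hypergeom_upper_tail(n_universe, len(targets), n_de, overlap)
        fc = np.nan
        lfc = np.nan
        if de is not None and tf in de.table.index:
            fc = float(de.table.at[tf, "fold_change"])
            lfc = float(de.table.at[tf, "log2_fc"])
        is_de_tf = bool(p <= alpha and np.isfinite(fc) and fc >= tf_fc_threshold)
        rows.append((tf, n_universe, len(targets), n_de, overlap, p, fc, lfc, is_de_tf))
    out = pd.DataFrame(
        rows,
        columns=[
            "tf",
            "n_universe",
            "n_targets",
            "n_de",
            "overlap",
            "p_value",
            "tf_fold_change",
            "tf_log2_fc",
            "is_de_tf",
        ],
    )
    return out.sort_values(["p_value", "tf"], kind="stable").reset_index(drop=True)


def pathway_enrich(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Two-sided hypergeometric enrichment/depletion over a gene-set collection.

    Set members are intersected with the universe before testing; the Holm
    step-down correction runs over all tested sets.  Rows sorted by raw p.
    """
    q = set(query)
    uni = set(universe)
    _validate_universe(q, uni)
    names, overlaps, directions, raw = [], [], [], []
    for name in sets.names():
        members = sets[name] & uni
        k = len(members & q)
        p, direction = hypergeom_two_sided(len(uni), len(members), len(q), k)
        names.append(name)
        overlaps.append(k)
        directions.append(direction)
        raw.append(p)
    out = pd.DataFrame(
        {
            "set_name": names,
            "overlap": overlaps,
            "direction": directions,
            "p_two_sided": raw,
            "p_adjusted": holm(raw),
        }
    )
    return out.sort_values(["p_two_sided", "set_name"], kind="stable").reset_index(drop=True)


def de_tf_symbols(tf_table: pd.DataFrame) -> list[str]:
    """The DE-TF symbols of a :func:`tf_enrich` table, in table order."""
    return list(tf_table.loc[tf_table["is_de_tf"], "tf"])
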