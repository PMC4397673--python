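"""Fold-change differential expression calling with Welch p-values.

DE genes are called purely on fold change — the ratio of linear-scale group
means, a restrictive threshold of 3 by default — mirroring the fold-change
algorithm of classic microarray packages.  A Welch two-sample t statistic
supplies per-gene p-values; these are *not* used for the DE call itself but
feed the downstream active-module search, which aggregates them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix

__all__ = ["DEResult", "collapse_duplicates", "call_de"]


@dataclass
class DEResult:
    """Per-gene DE statistics.

    ``table`` is indexed by gene with columns ``log2_fc`` (mean(B) − mean(A)
    on log2 scale), ``fold_change`` (= 2^|log2_fc|, always >= 1),
    ``direction`` (up/down/unchanged at ``fc_threshold``) and ``p_value``
    (Welch two-sided; 1.0 where the variance is undefined).
    """

    table: pd.DataFrame
    fc_threshold: float
    condition_a: str
    condition_b: str

    @property
    def de_genes(self) -> set[str]:
        return set(self.table.index[self.table["direction"] != "unchanged"])

    @property
    def up_genes(self) -> set[str]:
        return set(self.table.index[self.table["direction"] == "up"])

    @property
    def down_genes(self) -> set[str]:
        return set(self.table.index[self.table["direction"] == "down"])

    def p_values(self) -> dict[str, float]:
        return self.table["p_value"].to_dict()


def _log2_values(matrix: ExpressionMatrix, scale: str) -> pd.DataFrame:
    if scale == "log2":
        return matrix.values
    if scale == "linear":
        vals = matrix.values
        if (vals.to_numpy() <= 0).any():
            raise ValueError("linear-scale expression must be strictly positive")
        return np.log2(vals)
    raise ValueError(f"unknown expression scale {scale!r}")


def _group_log2_fc(matrix: ExpressionMatrix, scale: str, conditions: tuple[str, str]) -> pd.Series:
    vals = _log2_values(matrix, scale)
    cond_a, cond_b = conditions
    mean_a = vals[matrix.samples(cond_a)].mean(axis=1)
    mean_b = vals[matrix.samples(cond_b)].mean(axis=1)
    return mean_b - mean_a


def collapse_duplicates(matrix: ExpressionMatrix, scale: str = "log2") -> ExpressionMatrix:
    """Collapse repeated gene symbols (multiple probes) to one row per symbol.

    The retained row is the duplicate with maximal |log2 fold change| between
    the two conditions; ties keep the first row in file order.
    """
    if matrix.values.index.is_unique:
        return matrix
    lfc = _group_log2_fc(matrix, scale, matrix.conditions).to_numpy()
    order = np.arange(len(lfc))
    pick = (
        pd.DataFrame({"gene": matrix.values.index, "abs_lfc": np.abs(lfc), "pos": order})
        .sort_values(["abs_lfc", "pos"], ascending=[False, True], kind="stable")
        .drop_duplicates("gene")
        .sort_values("pos")["pos"]
        .to_numpy()
    )
    collapsed = matrix.values.iloc[pick]
    return ExpressionMatrix(values=collapsed, groups=dict(matrix.groups))


def call_de(
    matrix: ExpressionMatrix,
    fc_threshold: float = 3.0,
    scale: str = "log2",
    conditions: tuple[str, str] | None = None,
) -> DEResult:
    """Call DE genes at a fold-change threshold; attach Welch p-values.

    ``conditions`` fixes the (A, B) orientation of the comparison (default:
    lexicographic); log2_fc is mean(B) − mean(A).  The fold change is the
    ratio of linear-scale group means, i.e. 2^|log2_fc| for log2 input.
    Genes with < 2 samples per group or undefined variance get p = 1.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must exceed 1")
    conds = conditions if conditions is not None else matrix.conditions
    if set(conds) != set(matrix.conditions):
        raise ValueError(f"conditions {conds!r} do not match matrix {matrix.conditions!r}")
    vals = _log2_values(matrix, scale)
    a = vals[matrix.samples(conds[0])].to_numpy(float)
    b = vals[matrix.samples(conds[1])].to_numpy(float)
    lfc = b.mean(axis=1) - a.mean(axis=1)
    if a.shape[1] >= 2 and b.shape[1] >= 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = stats.ttest_ind(b, a, axis=1, equal_var=False).pvalue
        p = np.where(np.isfinite(p), p, 1.0)
    else:
        p = np.ones(len(lfc))
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    cut = math.log2(fc_threshold)
    direction = np.where(lfc >= cut, "up", np.where(lfc <= -cut, "down", "unchanged"))
    table = pd.DataFrame(
        {
            "log2_fc": lfc,
            "fold_change": np.exp2(np.abs(lfc)),
            "direction": direction,
            "p_value": p,
        },
        index=matrix.values.index,
    )
    table.index.name = "gene"
    return DEResult(
        table=table, fc_threshold=fc_threshold, condition_a=conds[0], condition_b=conds[1]
    )
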