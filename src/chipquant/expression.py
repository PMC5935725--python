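"""RPKM computation and twofold gene-classification procedures.

All regulation calls use pseudocounted RPKM fold changes: a gene is called up
from sample ``a`` to sample ``b`` when ``(RPKM_b + c) / (RPKM_a + c) >= T``
(T = 2 by default, boundary inclusive for reproducibility on continuous
values), down when the ratio is ``<= 1/T``, otherwise unchanged.  A gene up-
regulated in the control time course is "sensitive" to a mutant when it fails
to be induced there — its mutant-course fold change stays below T — and
"resistant" otherwise.  Depot-selectivity ranks genes by log2 fold change
between two conditions and takes the top N in each direction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ExpressionTable, GenePartition, SelectivityRanking

log = logging.getLogger("chipquant")

__all__ = [
    "compute_rpkm",
    "call_regulated",
    "partition_sensitivity",
    "overlap",
    "OverlapResult",
    "rank_selectivity",
    "heatmap_matrix",
    "summarize_fractions",
]


def compute_rpkm(expr: ExpressionTable) -> ExpressionTable:
    """RPKM = counts / (exonic length / 1e3) / (library size / 1e6), per sample."""
    kb = expr.lengths / 1_000.0
    rpkm = pd.DataFrame(index=expr.df.index)
    for s in expr.samples:
        millions = expr.library_sizes[s] / 1e6
        rpkm[s] = expr.df[s] / kb / millions
    expr.set_rpkm(rpkm)
    return expr


def _rpkm(expr: ExpressionTable, sample: str) -> pd.Series:
    try:
        rpkm = expr.rpkm
    except AttributeError:
        rpkm = compute_rpkm(expr).rpkm
    if sample not in rpkm.columns:
        raise KeyError(f"sample {sample!r} not in expression table "
                       f"(have {list(rpkm.columns)})")
    return rpkm[sample]


def call_regulated(expr: ExpressionTable, sample_from: str, sample_to: str,
                   threshold: float = 2.0, pseudocount: float = 0.5) -> GenePartition:
    """Partition genes into up / down / unchanged by pseudocounted fold change."""
    if threshold <= 1:
        raise ValueError("threshold must be > 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    a = _rpkm(expr, sample_from) + pseudocount
    b = _rpkm(expr, sample_to) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = b / a
    up = set(ratio.index[ratio >= threshold])
    down = set(ratio.index[ratio <= 1.0 / threshold])
    unchanged = set(ratio.index) - up - down
    return GenePartition(
        scheme=f"regulation:{sample_from}->{sample_to}",
        sets={"up": up, "down": down, "unchanged": unchanged},
        params={"threshold": threshold, "pseudocount": pseudocount,
                "from": sample_from, "to": sample_to},
    )


def partition_sensitivity(
    up_in_control: set[str],
    expr: ExpressionTable,
    mutant_from: str,
    mutant_to: str,
    threshold: float = 2.0,
    pseudocount: float = 0.5,
    rule: str = "mutant_fold",
    control_to: str | None = None,
    level_fraction: float = 0.5,
) -> GenePartition:
    """Split control-course up-regulated genes into mutant-sensitive vs -resistant.

    Default rule ``mutant_fold``: sensitive genes have a mutant-course fold
    change ``(to + c)/(from + c) < T`` — they fail to reach the induction
    threshold in the mutant.  Alternative rule ``level``: sensitive genes'
    mutant endpoint RPKM is below ``level_fraction`` of the control endpoint
    (``control_to`` required).  Sensitive and resistant always cover the up
    set exactly.
    """
    if not up_in_control:
        warnings.warn("empty up-regulated set: sensitivity partition is empty")
    up = sorted(up_in_control)
    mfrom = _rpkm(expr, mutant_from).loc[up] + pseudocount
    mto = _rpkm(expr, mutant_to).loc[up] + pseudocount
    if rule == "mutant_fold":
        sensitive = set(mfrom.index[(mto / mfrom) < threshold])
    elif rule == "level":
        if control_to is None:
            raise ValueError("rule='level' requires control_to")
        cto = _rpkm(expr, control_to).loc[up] + pseudocount
        sensitive = set(mto.index[mto < level_fraction * cto])
    else:
        raise ValueError(f"unknown sensitivity rule {rule!r}")
    return GenePartition(
        scheme=f"sensitivity:{mutant_from}->{mutant_to}",
        sets={"sensitive": sensitive, "resistant": set(up) - sensitive},
        params={"threshold": threshold, "pseudocount": pseudocount, "rule": rule},
    )


@dataclass(frozen=True)
class OverlapResult:
    """Venn decomposition of two gene sets."""

    a_only: frozenset[str]
    shared: frozenset[str]
    b_only: frozenset[str]

    @property
    def counts(self) -> dict[str, int]:
        return {"a_only": len(self.a_only), "shared": len(self.shared),
                "b_only": len(self.b_only)}


def overlap(set_a: set[str], set_b: set[str]) -> OverlapResult:
    """Exact set algebra behind a two-set Venn diagram."""
    a, b = set(set_a), set(set_b)
    return OverlapResult(frozenset(a - b), frozenset(a & b), frozenset(b - a))


def rank_selectivity(expr: ExpressionTable, cond_a: str, cond_b: str,
                     n_top: int = 1_000, pseudocount: float = 0.5) -> SelectivityRanking:
    """Rank genes by log2((A + c)/(B + c)) and flag top-N per direction.

    Rank 1 is the most A-selective gene; ties are broken by gene_id so the
    ordering is strict and deterministic.  The most negative N genes are
    B-selective; a gene already A-selected is never also B-selected.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    a = _rpkm(expr, cond_a) + pseudocount
    b = _rpkm(expr, cond_b) + pseudocount
    log2fc = np.log2(a / b)
    tab = pd.DataFrame({"log2fc": log2fc})
    order = np.lexsort((np.array(tab.index, dtype=object),
                        -tab["log2fc"].to_numpy()))
    tab = tab.iloc[order]
    tab["rank"] = np.arange(1, len(tab) + 1)
    n = min(n_top, len(tab))
    if n_top > len(tab):
        warnings.warn(f"n_top={n_top} exceeds gene count {len(tab)}; selecting all")
    selected = np.array([""] * len(tab), dtype=object)
    selected[:n] = "A"
    bottom = [i for i in range(len(tab) - 1, -1, -1) if selected[i] != "A"][:n]
    selected[bottom] = "B"
    tab["selected"] = selected
    if tab["log2fc"].nunique() == 1:
        warnings.warn("all genes have identical log2 fold change; "
                      "selectivity ranking is degenerate")
    return SelectivityRanking(cond_a=cond_a, cond_b=cond_b, n_top=n_top, table=tab)


def heatmap_matrix(expr: ExpressionTable,
                   contrasts: list[tuple[str, str]],
                   ranking: SelectivityRanking | None = None,
                   pseudocount: float = 0.5,
                   selected_only: bool = True) -> pd.DataFrame:
    """log2 fold-change matrix: one column per (A, B) contrast, rows in rank order.

    With a ranking given, rows follow its order (restricted to selected genes
    by default) — the layout of a selectivity heatmap whose first column is
    the ranking contrast itself.
    """
    if ranking is not None:
        order = list(ranking.table.index)
        if selected_only:
            flags = ranking.table["selected"]
            order = [g for g in order if flags.loc[g] != ""]
    else:
        order = list(expr.df.index)
    cols = {}
    for ca, cb in contrasts:
        a = _rpkm(expr, ca).loc[order] + pseudocount
        b = _rpkm(expr, cb).loc[order] + pseudocount
        cols[f"{ca}_vs_{cb}"] = np.log2(a / b)
    return pd.DataFrame(cols, index=pd.Index(order, name="gene_id"))


def summarize_fractions(partition: GenePartition, total_genes: int) -> dict[str, float]:
    """Percentage of ``total_genes`` in each set, to one decimal place."""
    if total_genes <= 0:
        raise ValueError("total_genes must be positive")
    if total_genes < len(partition.union()):
        raise ValueError("total_genes smaller than the partition's union")
    return {name: round(100.0 * len(gids) / total_genes, 1)
            for name, gids in partition.sets.items()}
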