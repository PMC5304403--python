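"""Concordance typing of the aging x sponge DEG intersection.

Genes differentially expressed both during aging and under miRNA-sponge
antagonism are classified by direction of regulation:

=====  ===========  ============
type   aging        sponge
=====  ===========  ============
1      up           up
2      up           down
3      down         down
4      down         up
=====  ===========  ============

Types 1 and 3 are *concordant* (same direction in both contrasts); a large
concordant fraction indicates that losing the miRNA phenocopies aging at
the transcriptome level. The module also provides the fold-change
correlation over the intersection and a Fisher overlap test of a DEG set
against an externally defined gene set (e.g. lifespan-correlated genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from scipy import stats as sps

from .errors import InputError
from .stats import pearson

logger = logging.getLogger(__name__)

_DEG_COLUMNS = ("gene_id", "log2FC")


def _check_deg_table(table: pd.DataFrame, label: str) -> pd.DataFrame:
    for col in _DEG_COLUMNS:
        if col not in table.columns:
            raise InputError(f"{label} DEG table lacks required column {col!r}")
    if table["gene_id"].duplicated().any():
        dup = table.loc[table["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise InputError(f"{label} DEG table has duplicate gene id {dup!r}")
    return table


def intersect_degs(
    aging: pd.DataFrame, sponge: pd.DataFrame, fdr: Optional[float] = None
) -> set[str]:
    """Genes present in both DEG tables, optionally after an FDR filter."""
    aging = _check_deg_table(aging, "aging")
    sponge = _check_deg_table(sponge, "sponge")
    if fdr is not None:
        aging = aging[aging["FDR"] < fdr]
        sponge = sponge[sponge["FDR"] < fdr]
    return set(aging["gene_id"]) & set(sponge["gene_id"])


def classify_types(aging: pd.DataFrame, sponge: pd.DataFrame) -> pd.DataFrame:
    """Assign each intersected gene a type 1-4 from its two log2FC signs.

    Genes with a zero log2FC in either contrast have no direction and are
    excluded with a warning; the returned frame has columns ``gene_id``,
    ``type``, ``log2FC_aging``, ``log2FC_sponge``.
    """
    aging = _check_deg_table(aging, "aging").set_index("gene_id")
    sponge = _check_deg_table(sponge, "sponge").set_index("gene_id")
    common = aging.index.intersection(sponge.index)
    fc_a = aging.loc[common, "log2FC"]
    fc_s = sponge.loc[common, "log2FC"]
    zero = (fc_a == 0) | (fc_s == 0)
    if zero.any():
        logger.warning(
            "excluding %d intersected gene(s) with zero log2FC: %s",
            int(zero.sum()), ", ".join(common[zero][:5]),
        )
    fc_a, fc_s = fc_a[~zero], fc_s[~zero]
    types = pd.Series(0, index=fc_a.index, dtype=int)
    types[(fc_a > 0) & (fc_s > 0)] = 1
    types[(fc_a > 0) & (fc_s < 0)] = 2
    types[(fc_a < 0) & (fc_s < 0)] = 3
    types[(fc_a < 0) & (fc_s > 0)] = 4
    return pd.DataFrame(
        {
            "gene_id": types.index,
            "type": types.to_numpy(),
            "log2FC_aging": fc_a.to_numpy(),
            "log2FC_sponge": fc_s.to_numpy(),
        }
    ).reset_index(drop=True)


@dataclass
class ConcordanceSummary:
    counts: tuple[int, int, int, int]
    intersection_size: int  # denominator actually used for the percentages
    classified: int  # genes that received a type
    concordant: int
    concordant_percent: int
    discordant_percent: int
    chi2: float
    chi2_p: float
    fisher_fallback: bool = False


def concordance(
    typed: pd.DataFrame, total_override: Optional[int] = None
) -> ConcordanceSummary:
    """Summarise a typed intersection: counts, concordant %, 2x2 chi-square.

    The chi-square tests independence of the aging and sponge directions
    on the 2x2 sign table, without continuity correction; when any
    expected count falls below 5 the exact Fisher p is reported instead
    (flagged). ``total_override`` substitutes an externally printed
    intersection total as the percentage denominator while the internally
    classified count is still reported.
    """
    if typed.empty:
        raise InputError("typed gene list is empty")
    n = tuple(int((typed["type"] == t).sum()) for t in (1, 2, 3, 4))
    classified = sum(n)
    total = total_override if total_override is not None else classified
    concordant = n[0] + n[2]
    # rows: aging up/down; cols: sponge up/down
    table = [[n[0], n[1]], [n[3], n[2]]]
    if classified == 0:
        raise InputError("no gene could be typed")
    fisher_fallback = False
    expected = sps.contingency.expected_freq(table)
    if (expected < 5).any():
        fisher_fallback = True
        chi2 = float("nan")
        p = float(sps.fisher_exact(table)[1])
        logger.warning("expected count < 5: reporting Fisher exact p instead of chi-square")
    else:
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        chi2, p = float(chi2), float(p)
    return ConcordanceSummary(
        counts=n,
        intersection_size=total,
        classified=classified,
        concordant=concordant,
        concordant_percent=round(100 * concordant / total),
        discordant_percent=round(100 * (classified - concordant) / total),
        chi2=chi2,
        chi2_p=p,
        fisher_fallback=fisher_fallback,
    )


def foldchange_correlation(
    aging: pd.DataFrame, sponge: pd.DataFrame, intersection: Iterable[str]
) -> float:
    """Pearson r between aging and sponge log2 fold changes on the intersection."""
    genes = sorted(set(intersection))
    if not genes:
        raise InputError("empty intersection")
    fc_a = _check_deg_table(aging, "aging").set_index("gene_id").loc[genes, "log2FC"]
    fc_s = _check_deg_table(sponge, "sponge").set_index("gene_id").loc[genes, "log2FC"]
    return pearson(fc_a.to_numpy(), fc_s.to_numpy())


def overlap_fisher(
    deg_set: Iterable[str], trait_set: Iterable[str], universe: Iterable[str]
) -> tuple[float, float]:
    """Two-sided Fisher exact test of the overlap between two gene sets.

    Returns the sample odds ratio and p-value for the 2x2 table induced by
    membership in ``deg_set`` x membership in ``trait_set`` over the
    universe.
    """
    universe = set(universe)
    if not universe:
        raise InputError("empty universe")
    deg_set = set(deg_set)
    trait_set = set(trait_set)
    if not deg_set <= universe or not trait_set <= universe:
        raise InputError("gene sets must be subsets of the universe")
    a = len(deg_set & trait_set)
    b = len(deg_set - trait_set)
    c = len(trait_set - deg_set)
    d = len(universe) - a - b - c
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)
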