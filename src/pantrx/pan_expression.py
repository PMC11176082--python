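"""Presence-aware expression statistics over the pan-genome.

Abundance is the mean log2(TPM+1) over the isolates that carry a gene;
dispersion is the mean absolute deviation (MAD) over the same carriers,

    (1/n) * sum_i |x_i - xbar|,

which is robust to outliers and makes no normality assumption.  Genes
present in a single isolate, and genes not expressed in any carrier, are
excluded.  Core/accessory (and subcategory) contrasts use two-sided
rank-based tests.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "abundance_dispersion",
    "compare_gene_classes",
    "group_mean_correlation",
]


def abundance_dispersion(
    expr: ExpressionMatrix,
    presence: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene carrier count, abundance and MAD dispersion.

    Parameters
    ----------
    expr : log2(TPM+1) matrix.
    presence : boolean genes x isolates matrix; carriers of a gene are the
        isolates where it is True.
    annotation : optional table contributing ``class``/``subcategory``.
    """
    if expr.scale != "log2tpm1":
        raise ValueError("abundance_dispersion expects log2(TPM+1) expression")
    presence = presence.reindex(index=expr.gene_ids, columns=expr.isolate_ids)
    x = expr.values.to_numpy(dtype=float)
    mask = presence.to_numpy(dtype=bool)
    n = mask.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, (x * mask).sum(axis=1) / np.maximum(n, 1), np.nan)
        mad = (np.abs(x - mean[:, None]) * mask).sum(axis=1) / np.maximum(n, 1)
    expressed = ((x > 0) & mask).any(axis=1)
    keep = (n >= 2) & expressed
    dropped_core = 0
    if annotation is not None and "class" in annotation.columns:
        cls = annotation["class"].reindex(expr.gene_ids)
        dropped_core = int(((~keep) & (cls == "core").to_numpy()).sum())
    if dropped_core:
        logger.warning("%d core genes excluded (single carrier or unexpressed)", dropped_core)
    out = pd.DataFrame(
        {"n": n, "abundance": mean, "dispersion": mad},
        index=expr.gene_ids,
    ).loc[keep]
    if annotation is not None:
        for col in ("class", "subcategory"):
            if col in annotation.columns:
                out[col] = annotation[col].reindex(out.index)
    return out


def compare_gene_classes(
    stats_table: pd.DataFrame,
    grouping: pd.Series | str = "class",
    columns: Sequence[str] = ("abundance", "dispersion"),
    test: str = "rank-sum",
) -> pd.DataFrame:
    """Two-sided rank test between two gene groups on each statistic.

    ``test`` is ``"rank-sum"`` (Mann-Whitney U, the defined test for
    unpaired groups of unequal size; default) or ``"signed-rank"``
    (Wilcoxon, requires equal group sizes and pairs by position).
    Returns one row per tested column with the statistic, p-value and
    group medians.  All-tied groups are flagged.
    """
    if isinstance(grouping, str):
        grouping = stats_table[grouping]
    grouping = grouping.reindex(stats_table.index)
    labels = [lab for lab in pd.unique(grouping.dropna())]
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if len(labels) > 2:
        labels = labels[:2]
        logger.warning("more than two groups; comparing %s vs %s", *labels)
    rows = []
    for col in columns:
        a = stats_table.loc[grouping == labels[0], col].dropna()
        b = stats_table.loc[grouping == labels[1], col].dropna()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"group with fewer than 2 genes for {col!r}")
        all_tied = a.nunique() == 1 or b.nunique() == 1
        if test == "rank-sum":
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
        elif test == "signed-rank":
            if len(a) != len(b):
                raise ValueError("signed-rank requires equal group sizes")
            res = stats.wilcoxon(a.to_numpy(), b.to_numpy(), alternative="two-sided")
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            {
                "column": col,
                "group_a": labels[0],
                "group_b": labels[1],
                "n_a": len(a),
                "n_b": len(b),
                "median_a": float(a.median()),
                "median_b": float(b.median()),
                "statistic": float(res.statistic),
                "p": float(res.pvalue),
                "all_tied_group": bool(all_tied),
            }
        )
    return pd.DataFrame(rows)


def group_mean_correlation(
    expr: ExpressionMatrix,
    gene_ids: Sequence,
    carrier_groups: Mapping,
) -> Tuple[pd.DataFrame, dict]:
    """Per-gene paired means between two disjoint isolate groups + Pearson r.

    ``carrier_groups[gene] = (isolates_a, isolates_b)``.  Genes missing
    isolates in either group are excluded and counted in the summary.
    Returns (per-gene table with mean_a / mean_b, summary dict with
    ``r``, ``p``, ``n_genes``, ``n_excluded`` and the mean deviation from
    the identity line).
    """
    rows, excluded = [], 0
    for g in gene_ids:
        grp_a, grp_b = carrier_groups[g]
        grp_a = [i for i in grp_a if i in expr.isolate_ids]
        grp_b = [i for i in grp_b if i in expr.isolate_ids]
        if len(grp_a) == 0 or len(grp_b) == 0 or g not in expr.gene_ids:
            excluded += 1
            continue
        if set(grp_a) & set(grp_b):
            raise ValueError(f"carrier groups for {g} overlap")
        rows.append(
            {
                "gene_id": g,
                "mean_a": float(expr.values.loc[g, grp_a].mean()),
                "mean_b": float(expr.values.loc[g, grp_b].mean()),
            }
        )
    table = pd.DataFrame(rows, columns=["gene_id", "mean_a", "mean_b"])
    if len(table) < 3:
        raise ValueError("fewer than 3 genes with both groups; correlation undefined")
    r, p = stats.pearsonr(table["mean_a"], table["mean_b"])
    summary = {
        "r": float(r),
        "p": float(p),
        "n_genes": len(table),
        "n_excluded": excluded,
        "mean_identity_deviation": float((table["mean_a"] - table["mean_b"]).abs().mean()),
    }
    return table, summary
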