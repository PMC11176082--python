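"""One-vs-rest subpopulation differential expression.

Each clade is contrasted against all remaining isolates with a per-gene
negative-binomial log-linear model that includes mating type as a
covariate (haploid MATa / MATalpha; diploids as a third level) and
library-size offsets from median-of-ratios size factors.  Because FDR
alone favours large clades (small effects reach significance with more
isolates), significance additionally requires |log2FC| above a cutoff
chosen by sweeping a grid and testing when the hit-count vs clade-size
dependency disappears.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "size_factors",
    "clade_de",
    "cutoff_sweep",
    "significant_hits",
    "differential_expression_gene_set",
]


def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios library size factors, geometric mean 1.

    Rows with a zero anywhere are excluded from the reference geometric
    mean (the standard estimator); if no all-positive row exists the
    geometric mean falls back to positive counts only, with a warning.
    """
    if counts.n_isolates < 2:
        raise ValueError("need at least 2 isolates")
    x = counts.values.to_numpy(dtype=float)
    all_pos = (x > 0).all(axis=1)
    if all_pos.any():
        ref = x[all_pos]
        geo = np.exp(np.log(ref).mean(axis=1))
        ratios = ref / geo[:, None]
    else:
        logger.warning("no gene positive in every isolate; using positive counts only")
        with np.errstate(divide="ignore"):
            logx = np.where(x > 0, np.log(x), np.nan)
        geo = np.exp(np.nanmean(logx, axis=1))
        ratios = np.where(x > 0, x / geo[:, None], np.nan)
    factors = np.nanmedian(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.isolate_ids, name="size_factor")


def _mom_dispersion(norm_counts: np.ndarray) -> float:
    mu = norm_counts.mean()
    var = norm_counts.var(ddof=1)
    if mu <= 0:
        return 1e-8
    return float(max((var - mu) / mu**2, 1e-8))


def clade_de(
    counts: ExpressionMatrix,
    clades: pd.Series,
    mating_type: pd.Series,
    target_clade: str,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Wald tests of a one-vs-rest clade effect per gene.

    Model per gene: log mu = log(size factor) + b0 + b_mating * mating
    + b_clade * 1[clade == target]; negative-binomial errors with a
    per-gene method-of-moments dispersion (floored at 1e-8, no shrinkage).
    Returns a table (gene_id, clade, log2fc, se, p, padj) BH-adjusted
    across genes.  A clade perfectly confounded with mating type makes the
    design singular and raises.
    """
    if counts.scale != "raw_count":
        raise ValueError("clade_de expects raw counts")
    clades = clades.reindex(counts.isolate_ids)
    mating_type = mating_type.reindex(counts.isolate_ids)
    in_clade = (clades == target_clade).to_numpy(dtype=float)
    if in_clade.sum() < 2 or (1 - in_clade).sum() < 2:
        raise ValueError("target clade and rest each need >= 2 isolates")
    if factors is None:
        factors = size_factors(counts)
    factors = factors.reindex(counts.isolate_ids)
    offset = np.log(factors.to_numpy(dtype=float))

    mating_dummies = pd.get_dummies(mating_type, drop_first=True, dtype=float)
    design = np.column_stack(
        [np.ones(counts.n_isolates), mating_dummies.to_numpy(), in_clade]
    )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            f"design singular for clade {target_clade!r} (confounded with mating type)"
        )
    clade_col = design.shape[1] - 1

    norm = counts.values.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    rows = []
    ln2 = np.log(2.0)
    for gi, gene in enumerate(counts.gene_ids):
        y = counts.values.iloc[gi].to_numpy(dtype=float)
        if y.sum() == 0:
            continue
        alpha = _mom_dispersion(norm[gi])
        try:
            model = sm.GLM(
                y,
                design,
                family=sm.families.NegativeBinomial(alpha=alpha),
                offset=offset,
            )
            res = model.fit(maxiter=100, tol=1e-8)
            beta, se = res.params[clade_col], res.bse[clade_col]
        except Exception:  # IRLS failure on degenerate genes
            logger.warning("GLM failed for gene %s; skipping", gene)
            continue
        if not np.isfinite(beta) or not np.isfinite(se) or se == 0:
            continue
        z = beta / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "gene_id": gene,
                "clade": target_clade,
                "log2fc": beta / ln2,
                "se": se / ln2,
                "p": p,
            }
        )
    table = pd.DataFrame(rows, columns=["gene_id", "clade", "log2fc", "se", "p"])
    if len(table):
        table["padj"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["padj"] = []
    return table


def cutoff_sweep(
    de_tables: Mapping[str, pd.DataFrame],
    clade_sizes: Mapping[str, int],
    grid: np.ndarray | None = None,
    fdr: float = 0.05,
    independence_p: float = 0.05,
) -> tuple[float, pd.DataFrame]:
    """Choose the |log2FC| cutoff that removes the hit-count size bias.

    For every grid value t, hits are records with padj < ``fdr`` and
    |log2fc| > t; the Spearman correlation between per-clade hit counts and
    clade sizes is computed, and the chosen cutoff is the smallest t whose
    correlation p-value is >= ``independence_p`` (an undefined correlation,
    e.g. all counts zero or equal clade sizes, counts as independence).
    Returns (cutoff, diagnostics table of t / rho / p / counts).
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0001, 0.05), 2)
    clades = sorted(de_tables)
    if len(clades) < 3:
        raise ValueError("need >= 3 clades for a meaningful size-bias sweep")
    sizes = np.array([clade_sizes[c] for c in clades], dtype=float)
    rows, chosen = [], None
    for t in grid:
        hit_counts = np.array(
            [
                int(
                    (
                        (de_tables[c]["padj"] < fdr)
                        & (de_tables[c]["log2fc"].abs() > t)
                    ).sum()
                )
                for c in clades
            ],
            dtype=float,
        )
        if np.all(hit_counts == hit_counts[0]) or np.all(sizes == sizes[0]):
            rho, p = np.nan, np.nan
            independent = True
        else:
            rho, p = stats.spearmanr(hit_counts, sizes)
            independent = (not np.isfinite(p)) or p >= independence_p
        rows.append(
            {"cutoff": float(t), "rho": rho, "p": p, "total_hits": hit_counts.sum()}
        )
        if independent and chosen is None:
            chosen = float(t)
    diagnostics = pd.DataFrame(rows)
    if chosen is None:
        logger.warning("size dependency persisted over the whole grid; using max cutoff")
        chosen = float(grid[-1])
    return chosen, diagnostics


def significant_hits(
    de_table: pd.DataFrame,
    lfc_cut: float = 0.3,
    fdr: float = 0.05,
    coexpression_genes=None,
) -> pd.DataFrame:
    """Final significance filter: |log2fc| > lfc_cut (strict) and padj < fdr.

    Adds a ``direction`` column (up/down by the sign of log2fc) and, when
    ``coexpression_genes`` is given, an ``in_coexpression`` flag for hits
    overlapping the coexpression node set (those are excluded from the
    exported differential-expression gene set).
    """
    keep = (de_table["log2fc"].abs() > lfc_cut) & (de_table["padj"] < fdr)
    hits = de_table.loc[keep].copy()
    hits["direction"] = np.where(hits["log2fc"] > 0, "up", "down")
    if coexpression_genes is not None:
        hits["in_coexpression"] = hits["gene_id"].isin(set(coexpression_genes))
    return hits.reset_index(drop=True)


def differential_expression_gene_set(
    hits_by_clade: Mapping[str, pd.DataFrame],
    coexpression_genes=None,
) -> set:
    """Union of significant genes across clades, minus coexpression nodes."""
    exclude = set(coexpression_genes) if coexpression_genes is not None else set()
    genes: set = set()
    for table in hits_by_clade.values():
        genes |= set(table["gene_id"])
    return genes - exclude
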