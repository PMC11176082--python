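"""Expression quantification and sample-level QC.

Covers the path from raw read counts to analysis-ready matrices:

* TPM computation and the log2(TPM + 1) convention,
* the low-expression filter and homolog merging of accessory features,
* a closed-form negative-binomial variance-stabilizing transform,
* sample-identity validation from shared rare SNPs,
* a dosage-response statistic for aneuploid chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Set

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, log2_tpm1

logger = logging.getLogger(__name__)

__all__ = [
    "compute_tpm",
    "filter_and_merge_genes",
    "variance_stabilize",
    "validate_sample_identity",
    "dosage_response",
]


def compute_tpm(counts: ExpressionMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Transcripts-per-million from raw counts and gene lengths in bp.

    Per isolate: rate_g = count_g / length_g, TPM_g = 1e6 * rate_g / sum(rate).
    Columns with no counts at all stay all-zero (and are logged).
    """
    if counts.scale != "raw_count":
        raise ValueError("compute_tpm expects raw counts")
    lengths = lengths.reindex(counts.gene_ids)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:5].tolist()
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.values.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero_cols = denom[denom == 0].index
    if len(zero_cols):
        logger.warning("all-zero count columns left as zero TPM: %s", list(zero_cols))
    denom = denom.replace(0, np.nan)
    tpm = rate.div(denom, axis=1).fillna(0.0) * 1e6
    return ExpressionMatrix(tpm, "tpm")


@dataclass
class FilterMergeReport:
    n_input: int
    n_low_expression_filtered: int
    n_merged: int
    n_retained: int


def filter_and_merge_genes(
    tpm: ExpressionMatrix,
    annotation: pd.DataFrame,
    log2_threshold: float = 1.0,
    min_fraction_below: float = 0.5,
) -> tuple[ExpressionMatrix, FilterMergeReport]:
    """Low-expression filter on reference genes + homolog merging.

    Reference-set genes (those that are not merge sources, i.e. have no
    ``homolog_of`` link) are dropped when log2(TPM + 1) < ``log2_threshold``
    in at least ``min_fraction_below`` of the isolates.  Accessory features
    carrying a ``homolog_of`` link have their abundance summed into the
    homolog row and are dropped.  TPM is renormalized afterwards, because
    column sums are not preserved under subsetting.
    """
    if tpm.scale != "tpm":
        raise ValueError("filter_and_merge_genes expects a TPM matrix")
    values = tpm.values.copy()
    ann = annotation.reindex(values.index)
    homolog = ann.get("homolog_of")
    if homolog is None:
        homolog = pd.Series(None, index=values.index, dtype=object)
    homolog = homolog.where(homolog.notna(), None).where(homolog != "", None)

    # detect homolog cycles / chains before touching the matrix
    targets = homolog.dropna()
    for g, t in targets.items():
        if t in targets.index:
            raise ValueError(f"homolog chain or cycle involving {g} -> {t}")

    is_source = homolog.notna()
    log2v = np.log2(values + 1.0)
    frac_below = (log2v < log2_threshold).mean(axis=1)
    low = (frac_below >= min_fraction_below) & ~is_source
    n_low = int(low.sum())
    values = values.loc[~low]

    n_merged = 0
    for g, target in homolog.dropna().items():
        if g not in values.index:
            continue
        if target in values.index:
            values.loc[target] += values.loc[g]
            n_merged += 1
        values = values.drop(index=g)

    # recompute TPM normalization after subsetting
    col_sums = values.sum(axis=0)
    col_sums = col_sums.replace(0, np.nan)
    values = values.div(col_sums, axis=1).fillna(0.0) * 1e6
    report = FilterMergeReport(
        n_input=tpm.n_genes,
        n_low_expression_filtered=n_low,
        n_merged=n_merged,
        n_retained=values.shape[0],
    )
    return ExpressionMatrix(values, "tpm"), report


# ---------------------------------------------------------------------------
# variance-stabilizing transform


def _fit_dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a0 + a1/mu by least squares with positivity clamps."""
    x = 1.0 / mu
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, alpha, rcond=None)
    a0 = float(max(coef[0], 1e-4))
    a1 = float(max(coef[1], 0.0))
    return a0, a1


def variance_stabilize(
    counts: ExpressionMatrix,
    size_factors: pd.Series | None = None,
    min_expressed_fraction: float = 0.5,
) -> ExpressionMatrix:
    """Closed-form NB variance-stabilizing transform of raw counts.

    Genes with a zero count in more than ``min_expressed_fraction`` of the
    isolates are excluded first.  Counts are normalized by median-of-ratios
    size factors; a two-parameter dispersion trend alpha(mu) = a0 + a1/mu is
    fitted by method-of-moments, and the transform is the NB asymptotic
    stabilizer

        vst(x) = log2( (1 + a1 + 2 a0 x + 2 sqrt(a0 x (1 + a1 + a0 x)))
                       / (4 a0) )

    which is monotone in x and flattens the mean-variance relationship.
    """
    if counts.scale != "raw_count":
        raise ValueError("variance_stabilize expects raw counts")
    if counts.n_isolates < 2:
        raise ValueError("need at least 2 isolates")
    values = counts.values
    if (values.to_numpy() == 0).all():
        raise ValueError("all-zero count matrix")
    zero_frac = (values == 0).mean(axis=1)
    keep = zero_frac <= min_expressed_fraction
    values = values.loc[keep]

    from .diffexpr import size_factors as _size_factors

    if size_factors is None:
        size_factors = _size_factors(ExpressionMatrix(values, "raw_count"))
    norm = values.div(size_factors, axis=1)
    mu = norm.mean(axis=1).to_numpy()
    var = norm.var(axis=1, ddof=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mu) / mu**2
    ok = np.isfinite(alpha) & (mu > 0)
    alpha = np.clip(alpha[ok], 1e-8, None)
    a0, a1 = _fit_dispersion_trend(mu[ok], alpha)

    x = norm.to_numpy()
    inner = 1 + a1 + 2 * a0 * x + 2 * np.sqrt(a0 * x * (1 + a1 + a0 * x))
    vst = np.log2(inner / (4 * a0))
    return ExpressionMatrix(
        pd.DataFrame(vst, index=values.index, columns=values.columns), "vst"
    )


# ---------------------------------------------------------------------------
# sample identity from shared rare variants


def validate_sample_identity(
    sample_rare_variants: Set,
    reference_panel: Mapping[str, Set],
    expected_strain: str,
    top_k: int = 3,
) -> tuple[pd.DataFrame, str]:
    """Rank panel strains by shared rare SNPs and call a verdict.

    Returns (ranking table, verdict) with verdict one of ``validated``
    (expected strain within the top ``top_k``), ``reassign_candidate``
    (another strain uniquely top-ranked) or ``unresolved`` (no rare variant
    shared with any strain).  Ties are broken lexicographically on the
    strain identifier, making the ranking invariant to panel order.
    """
    if not reference_panel:
        raise ValueError("reference panel is empty")
    sample = set(sample_rare_variants)
    counts = {
        strain: len(sample & set(vset)) for strain, vset in reference_panel.items()
    }
    ranking = (
        pd.Series(counts, name="shared_rare_snps")
        .rename_axis("strain")
        .reset_index()
        .sort_values(["shared_rare_snps", "strain"], ascending=[False, True])
        .reset_index(drop=True)
    )
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    if ranking["shared_rare_snps"].iloc[0] == 0:
        return ranking, "unresolved"
    top_strains = ranking["strain"].head(top_k).tolist()
    if expected_strain in top_strains:
        return ranking, "validated"
    top1, runner = ranking["shared_rare_snps"].iloc[0], (
        ranking["shared_rare_snps"].iloc[1] if len(ranking) > 1 else -1
    )
    if top1 > runner:
        return ranking, "reassign_candidate"
    return ranking, "unresolved"


# ---------------------------------------------------------------------------
# aneuploid dosage response


def dosage_response(
    expr: ExpressionMatrix,
    karyotypes: pd.DataFrame,
    base_ploidy: pd.Series,
    gene_chrom: pd.Series,
) -> pd.DataFrame:
    """Observed vs expected expression ratios on aneuploid chromosomes.

    For each (isolate, chromosome) whose copy number differs from the
    isolate's base ploidy, the observed ratio is the median across that
    chromosome's genes of linear-scale expression (2^x - 1 from
    log2(TPM+1)) in the aneuploid isolate divided by the median over
    isolates euploid for that chromosome.  Because TPM is compositional —
    an amplified chromosome dilutes the apparent expression of every gene
    — each aneuploid isolate's ratios are first renormalized by the median
    ratio of its genes on chromosomes where it is euploid.  The expected
    ratio is copy / base ploidy, and

        attenuation = (expected - observed) / (expected - 1)

    is 0 for no dosage compensation and 1 for complete compensation.
    Chromosomes with expected ratio 1 are skipped.
    """
    if expr.scale != "log2tpm1":
        raise ValueError("dosage_response expects log2(TPM+1) expression")
    linear = np.power(2.0, expr.values) - 1.0
    # per-chromosome euploid reference profile (median over euploid isolates)
    ref_by_chrom, genes_by_chrom = {}, {}
    for chrom in karyotypes.columns:
        genes = gene_chrom.index[gene_chrom == chrom].intersection(expr.gene_ids)
        if len(genes) == 0:
            continue
        copies = karyotypes[chrom]
        euploid = copies.index[(copies == base_ploidy).to_numpy()]
        if len(euploid) < 2:
            continue
        ref = linear.loc[genes, euploid].median(axis=1)
        genes_by_chrom[chrom] = genes[ref > 0]
        ref_by_chrom[chrom] = ref[ref > 0]
    rows = []
    for chrom, genes in genes_by_chrom.items():
        copies = karyotypes[chrom]
        aneuploid = copies.index[(copies != base_ploidy).to_numpy()]
        ref = ref_by_chrom[chrom]
        for iso in aneuploid:
            expected = float(copies.loc[iso]) / float(base_ploidy.loc[iso])
            if expected == 1.0:
                logger.warning(
                    "isolate %s chrom %s: expected ratio 1, attenuation undefined",
                    iso,
                    chrom,
                )
                continue
            # compositional correction from this isolate's euploid chromosomes
            baseline_ratios = [
                linear.loc[g2, iso] / ref_by_chrom[c2]
                for c2, g2 in genes_by_chrom.items()
                if c2 != chrom and karyotypes.loc[iso, c2] == base_ploidy.loc[iso]
            ]
            correction = (
                float(np.median(pd.concat(baseline_ratios)))
                if baseline_ratios
                else 1.0
            )
            if correction <= 0:
                correction = 1.0
            ratios = linear.loc[genes, iso] / ref / correction
            observed = float(np.median(ratios))
            rows.append(
                {
                    "isolate_id": iso,
                    "chrom": chrom,
                    "copy_number": float(copies.loc[iso]),
                    "expected_ratio": expected,
                    "observed_ratio": observed,
                    "attenuation": (expected - observed) / (expected - 1.0),
                    "n_genes": len(genes),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "isolate_id",
            "chrom",
            "copy_number",
            "expected_ratio",
            "observed_ratio",
            "attenuation",
            "n_genes",
        ],
    )
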