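"""eQTL mapping with a kinship mixed model and permutation thresholds.

Association model per expression trait y (TPM) and variant x:

    y = mu + x b + g + e,   g ~ N(0, sg^2 K),  e ~ N(0, se^2 I)

with K the SNP-derived kinship matrix.  The variance ratio
delta = se^2 / sg^2 is estimated once per trait on the null model through
the spectral decomposition of K and reused for every variant, which turns
each association into a weighted regression in the rotated space.

Trait-specific significance thresholds come from permutations: phenotype
values are permuted between isolates, the genome-wide minimum p recorded,
and the threshold is the 5% quantile of the minima (the fifth lowest of
100).  Tests are corrected by genomic control when the inflation factor
exceeds one.  Significant variants in linkage disequilibrium (genotype
R^2 > 0.6, transitively) are conflated into linkage groups represented by
their most significant member; SNP eQTLs within 25 kb of the target gene
are local, CNV eQTLs only when variant and trait share the same ORF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "prepare_variants",
    "kinship",
    "LmmContext",
    "lmm_assoc",
    "permutation_threshold",
    "genomic_control",
    "conflate_linkage_groups",
    "classify_eqtls",
    "catalog_summary",
    "hotspot_summary",
    "map_eqtls",
]


# ---------------------------------------------------------------------------
# variant preparation


def prepare_variants(
    genotypes: GenotypeMatrix,
    chrom_lengths: dict,
    subtelomere_bp: int = 20_000,
    maf_min: float = 0.05,
    snp_mask: bool = True,
) -> GenotypeMatrix:
    """MAF filter plus subtelomeric masking of SNPs.

    Variants with MAF not strictly above ``maf_min`` are dropped.  When
    ``snp_mask`` is set, SNPs within ``subtelomere_bp`` of either
    chromosome end are removed; CNVs are never masked (most live in the
    subtelomeres).
    """
    unknown = set(genotypes.variants["chrom"]) - set(chrom_lengths)
    if unknown:
        raise ValueError(f"unknown chromosomes in genotype table: {sorted(unknown)}")
    maf = genotypes.maf()
    keep = maf > maf_min
    if snp_mask:
        meta = genotypes.variants
        lengths = meta["chrom"].map(chrom_lengths)
        in_subtel = (meta["pos"] <= subtelomere_bp) | (
            meta["pos"] > lengths - subtelomere_bp
        )
        keep &= ~((meta["type"] == "SNP") & in_subtel)
    return genotypes.subset(genotypes.variant_ids[keep])


def kinship(snps: GenotypeMatrix | pd.DataFrame) -> pd.DataFrame:
    """Kinship K = Z'Z / m over column-standardized SNP dosages.

    Monomorphic SNPs are skipped.  K is symmetric and positive
    semidefinite by construction.
    """
    dosage = snps.values if isinstance(snps, GenotypeMatrix) else snps
    x = dosage.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 SNPs for kinship")
    sd = x.std(axis=1)
    poly = sd > 0
    if (~poly).any():
        logger.warning("skipping %d monomorphic SNPs in kinship", int((~poly).sum()))
    z = (x[poly] - x[poly].mean(axis=1, keepdims=True)) / sd[poly, None]
    k = z.T @ z / z.shape[0]
    k = (k + k.T) / 2.0
    return pd.DataFrame(k, index=dosage.columns, columns=dosage.columns)


# ---------------------------------------------------------------------------
# the mixed model


@dataclass
class LmmContext:
    """Spectral decomposition of K shared across traits and permutations."""

    eigenvalues: np.ndarray  # (n,)
    rotation: np.ndarray  # U, (n, n); rotated v = U.T @ v
    isolate_ids: pd.Index

    @classmethod
    def from_kinship(cls, K: pd.DataFrame) -> "LmmContext":
        k = K.to_numpy(dtype=float)
        vals, vecs = np.linalg.eigh((k + k.T) / 2.0)
        if vals.min() < -1e-8:
            raise ValueError("kinship matrix is not positive semidefinite")
        return cls(np.maximum(vals, 0.0), vecs, K.index)


_DELTA_GRID = np.logspace(-5, 5, 61)


def _null_delta(y_rot: np.ndarray, ones_rot: np.ndarray, s: np.ndarray) -> float:
    """ML estimate of delta = se^2/sg^2 on the intercept-only model."""
    n = len(y_rot)
    best_delta, best_ll = None, -np.inf
    for delta in _DELTA_GRID:
        w = s + delta
        iw = 1.0 / w
        b0 = (ones_rot * y_rot * iw).sum() / (ones_rot**2 * iw).sum()
        resid = y_rot - ones_rot * b0
        sigma2 = (resid**2 * iw).sum() / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + np.log(w).sum() + n)
        if ll > best_ll:
            best_ll, best_delta = ll, delta
    return float(best_delta)


def _scan(
    y_rot: np.ndarray,
    x_rot: np.ndarray,
    ones_rot: np.ndarray,
    s: np.ndarray,
    delta: float,
    var_y: float,
):
    """Weighted single-variant regressions in the rotated space.

    ``x_rot`` is (m variants, n isolates) of rotated standardized dosages.
    Returns (beta, se, p, variance_explained) arrays; degenerate variants
    get NaN.
    """
    n = len(y_rot)
    iw = 1.0 / (s + delta)
    # With an intercept, work with weighted cross-moments of (1_rot, x, y).
    s1y = (y_rot * iw * ones_rot).sum()
    s11 = (ones_rot**2 * iw).sum()
    syy = (y_rot**2 * iw).sum()
    s1x = x_rot @ (ones_rot * iw)
    sxy = x_rot @ (y_rot * iw)
    sxx = (x_rot**2) @ iw
    vx = sxx - s1x**2 / s11
    cxy = sxy - s1x * s1y / s11
    vy = syy - s1y**2 / s11
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = cxy / vx
        rss = vy - beta * cxy
        df = n - 2
        sigma2 = rss / df
        se = np.sqrt(sigma2 / vx)
        tstat = beta / se
    bad = ~np.isfinite(tstat) | (vx <= 1e-12)
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p[bad] = np.nan
    beta = np.where(bad, np.nan, beta)
    se = np.where(bad, np.nan, se)
    ve = np.clip(beta**2 / var_y, 0.0, 1.0) if var_y > 0 else np.full(len(beta), np.nan)
    ve = np.where(bad, np.nan, ve)
    return beta, se, p, ve


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    sd[sd == 0] = 1.0
    return (x - mean) / sd, ok


def lmm_assoc(
    trait: pd.Series,
    genotypes: GenotypeMatrix,
    K: pd.DataFrame,
    context: LmmContext | None = None,
    delta: float | None = None,
) -> pd.DataFrame:
    """Per-variant mixed-model association for one expression trait.

    Returns a table indexed by variant id with p_raw, effect_size
    (|beta| on standardized dosage), variance_explained and the
    fitted variance ratio in ``attrs['delta']``.
    """
    trait = trait.reindex(genotypes.isolate_ids).astype(float)
    if trait.var() == 0:
        raise ValueError("trait has zero variance")
    if context is None:
        context = LmmContext.from_kinship(K)
    u, s = context.rotation, context.eigenvalues
    y = trait.to_numpy()
    y_rot = u.T @ y
    ones_rot = u.T @ np.ones(len(y))
    if delta is None:
        delta = _null_delta(y_rot, ones_rot, s)
    x = genotypes.values.to_numpy(dtype=float)
    x_std, ok = _standardize_rows(x)
    if (~ok).any():
        logger.warning("%d monomorphic variants skipped in scan", int((~ok).sum()))
    x_rot = x_std @ u
    beta, se, p, ve = _scan(y_rot, x_rot, ones_rot, s, delta, float(np.var(y)))
    p[~ok] = np.nan
    result = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "p_raw": p,
            "effect_size": np.abs(beta),
            "variance_explained": ve,
        },
        index=genotypes.variant_ids,
    )
    result.attrs["delta"] = delta
    return result


def permutation_threshold(
    trait: pd.Series,
    genotypes: GenotypeMatrix,
    K: pd.DataFrame,
    n_perm: int = 100,
    rng: np.random.Generator | int | None = 0,
    context: LmmContext | None = None,
    quantile: float = 0.05,
    return_minima: bool = False,
):
    """Trait-specific significance threshold from phenotype permutations.

    Permutes trait values between isolates ``n_perm`` times, records the
    genome-wide minimum p of each permutation (with the variance ratio
    re-estimated on the permuted phenotype), and returns the ``quantile``
    order statistic of the minima — the fifth lowest for 100 permutations
    at the default 5%.
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20: the 5% quantile of minima is undefined")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if context is None:
        context = LmmContext.from_kinship(K)
    u, s = context.rotation, context.eigenvalues
    y = trait.reindex(genotypes.isolate_ids).to_numpy(dtype=float)
    ones_rot = u.T @ np.ones(len(y))
    x_std, ok = _standardize_rows(genotypes.values.to_numpy(dtype=float))
    x_rot = (x_std @ u)[ok]
    var_y = float(np.var(y))
    minima = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = y[rng.permutation(len(y))]
        y_rot = u.T @ y_perm
        delta = _null_delta(y_rot, ones_rot, s)
        _, _, p, _ = _scan(y_rot, x_rot, ones_rot, s, delta, var_y)
        minima[b] = np.nanmin(p)
    k = max(1, int(np.floor(quantile * n_perm)))
    threshold = float(np.sort(minima)[k - 1])
    if return_minima:
        return threshold, minima
    return threshold


def genomic_control(p_values: np.ndarray | pd.Series):
    """Genomic-control inflation factor and (if lambda > 1) corrected p.

    lambda = median(qchisq(1 - p, 1)) / qchisq(0.5, 1); when lambda > 1
    the association chi-squares are deflated by lambda and p recomputed,
    otherwise p-values pass through unchanged.
    """
    arr = np.asarray(p_values, dtype=float)
    finite = np.isfinite(arr)
    if finite.sum() < 10:
        logger.warning("fewer than 10 p-values: genomic inflation estimate unreliable")
    chi2 = stats.chi2.isf(arr[finite], df=1)
    lam = float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
    corrected = arr.copy()
    if lam > 1:
        corrected[finite] = stats.chi2.sf(chi2 / lam, df=1)
    if isinstance(p_values, pd.Series):
        corrected = pd.Series(corrected, index=p_values.index)
    return lam, corrected


# ---------------------------------------------------------------------------
# post-processing of significant records


def _connected_components(ids, edges):
    parent = {v: v for v in ids}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    return {v: find(v) for v in ids}


def conflate_linkage_groups(
    significant: pd.DataFrame,
    genotypes: GenotypeMatrix,
    r2_threshold: float = 0.6,
) -> pd.DataFrame:
    """Group significant variants per trait by genotype R^2 > threshold.

    Linkage groups are connected components of the R^2 graph (transitive);
    within each group only the variant with the smallest p is the
    representative, ties broken by genomic position then variant id.
    Returns the input annotated with ``linkage_group`` and
    ``is_group_representative``.
    """
    out = significant.copy()
    out["linkage_group"] = ""
    out["is_group_representative"] = False
    meta = genotypes.variants
    for trait, grp in out.groupby("gene_id", sort=False):
        vids = list(grp["variant_id"])
        dos = genotypes.values.loc[vids].to_numpy(dtype=float)
        edges = []
        if len(vids) > 1:
            sd = dos.std(axis=1)
            sd[sd == 0] = np.nan
            z = (dos - dos.mean(axis=1, keepdims=True)) / sd[:, None]
            r2 = np.nan_to_num((z @ z.T / dos.shape[1]) ** 2)
            ia, ib = np.nonzero(np.triu(r2 > r2_threshold, k=1))
            edges = [(vids[a], vids[b]) for a, b in zip(ia, ib)]
        roots = _connected_components(vids, edges)
        group_names = {}
        for _, rec in grp.iterrows():
            root = roots[rec["variant_id"]]
            if root not in group_names:
                group_names[root] = f"{trait}:LG{len(group_names) + 1}"
        out.loc[grp.index, "linkage_group"] = [
            group_names[roots[v]] for v in grp["variant_id"]
        ]
        for root in set(roots.values()):
            members = grp.index[[roots[v] == root for v in grp["variant_id"]]]
            ranked = sorted(
                members,
                key=lambda i: (
                    out.loc[i, "p_corrected"],
                    meta.loc[out.loc[i, "variant_id"], "pos"],
                    out.loc[i, "variant_id"],
                ),
            )
            out.loc[ranked[0], "is_group_representative"] = True
    return out


def classify_eqtls(
    records: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    genotypes: GenotypeMatrix,
    local_window_bp: int = 25_000,
) -> pd.DataFrame:
    """Label records local / distant / unknown.

    SNPs: local iff on the trait gene's chromosome with distance to the
    nearest gene boundary <= ``local_window_bp`` (0 inside the gene).
    CNVs: local iff the variant's ORF is the trait gene.  Records whose
    trait gene has no coordinates get ``unknown``.
    """
    out = records.copy()
    meta = genotypes.variants
    var_info = {
        v: (row.chrom, row.pos, row.type, getattr(row, "orf", None))
        for v, row in zip(meta.index, meta.itertuples())
    }
    gene_info = {
        g: (row.chrom, row.start, row.end)
        for g, row in zip(gene_annotation.index, gene_annotation.itertuples())
    }
    localities = []
    for vid, gene in zip(out["variant_id"], out["gene_id"]):
        chrom, pos, vtype, orf = var_info[vid]
        if vtype == "CNV":
            localities.append("local" if orf == gene else "distant")
            continue
        if gene not in gene_info:
            localities.append("unknown")
            continue
        g_chrom, g_start, g_end = gene_info[gene]
        if chrom != g_chrom:
            localities.append("distant")
            continue
        dist = 0 if g_start <= pos <= g_end else min(abs(pos - g_start), abs(pos - g_end))
        localities.append("local" if dist <= local_window_bp else "distant")
    out["locality"] = localities
    return out


def catalog_summary(records: pd.DataFrame, genotypes: GenotypeMatrix) -> dict:
    """Headline counts of a classified, conflated eQTL catalog.

    Counts representatives only: total eQTLs, SNP- and CNV-associated
    totals, local/distant SNP eQTLs, the percentage of SNP eQTLs that are
    local and the number of distinct trait genes.
    """
    reps = records[records["is_group_representative"]]
    vtype = genotypes.variants["type"]
    is_snp = reps["variant_id"].map(vtype) == "SNP"
    snp = reps[is_snp]
    n_local_snp = int((snp["locality"] == "local").sum())
    n_distant_snp = int((snp["locality"] == "distant").sum())
    return {
        "n_eqtls": len(reps),
        "n_snp_eqtls": int(is_snp.sum()),
        "n_cnv_eqtls": int((~is_snp).sum()),
        "n_local_snp_eqtls": n_local_snp,
        "n_distant_snp_eqtls": n_distant_snp,
        "pct_local_snp_eqtls": 100.0 * n_local_snp / max(len(snp), 1),
        "n_trait_genes": int(reps["gene_id"].nunique()),
    }


def hotspot_summary(records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Traits per representative variant, sorted descending; singleton fraction."""
    reps = records[records["is_group_representative"]]
    counts = (
        reps.groupby("variant_id")["gene_id"]
        .nunique()
        .sort_values(ascending=False)
        .rename("n_traits")
        .reset_index()
    )
    singleton_fraction = (
        float((counts["n_traits"] == 1).mean()) if len(counts) else float("nan")
    )
    return counts, singleton_fraction


# ---------------------------------------------------------------------------
# pipeline


def map_eqtls(
    expression: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    gene_annotation: pd.DataFrame,
    traits=None,
    K: pd.DataFrame | None = None,
    n_perm: int = 100,
    seed: int = 0,
    r2_threshold: float = 0.6,
    local_window_bp: int = 25_000,
) -> pd.DataFrame:
    """Full per-trait eQTL scan with permutation thresholds.

    ``expression`` should be on the TPM scale.  ``K`` defaults to the
    kinship from the SNPs of ``genotypes``.  For every trait the scan
    p-values are genomic-control corrected when inflated, thresholded at
    the trait's permutation threshold, conflated into linkage groups and
    classified local/distant.  A trait-level BH correction across traits
    on each trait's best-hit empirical permutation p is reported alongside
    (``trait_padj``).
    """
    if traits is None:
        traits = list(expression.gene_ids)
    if K is None:
        snps = genotypes.of_type("SNP")
        K = kinship(snps if len(snps.variant_ids) >= 2 else genotypes)
    context = LmmContext.from_kinship(K)
    master = np.random.default_rng(seed)
    all_records = []
    trait_best_emp_p = {}
    for t_i, gene in enumerate(traits):
        y = expression.values.loc[gene]
        if y.var() == 0:
            logger.warning("trait %s has zero variance; skipped", gene)
            continue
        assoc = lmm_assoc(y, genotypes, K, context=context)
        lam, corrected = genomic_control(assoc["p_raw"])
        assoc["p_corrected"] = corrected
        rng = np.random.default_rng(master.integers(2**31))
        threshold, minima = permutation_threshold(
            y, genotypes, K, n_perm=n_perm, rng=rng, context=context, return_minima=True
        )
        best = np.nanmin(assoc["p_corrected"].to_numpy())
        trait_best_emp_p[gene] = (1 + (minima <= best).sum()) / (n_perm + 1)
        sig = assoc[assoc["p_corrected"] < threshold]
        for vid, rec in sig.iterrows():
            all_records.append(
                {
                    "variant_id": vid,
                    "gene_id": gene,
                    "p_raw": rec["p_raw"],
                    "p_corrected": rec["p_corrected"],
                    "effect_size": rec["effect_size"],
                    "variance_explained": rec["variance_explained"],
                    "genomic_inflation": lam,
                    "threshold": threshold,
                }
            )
    records = pd.DataFrame(
        all_records,
        columns=[
            "variant_id",
            "gene_id",
            "p_raw",
            "p_corrected",
            "effect_size",
            "variance_explained",
            "genomic_inflation",
            "threshold",
        ],
    )
    if len(records) == 0:
        records["linkage_group"] = []
        records["is_group_representative"] = []
        records["locality"] = []
        records["trait_padj"] = []
        return records
    records = conflate_linkage_groups(records, genotypes, r2_threshold=r2_threshold)
    records = classify_eqtls(
        records, gene_annotation, genotypes, local_window_bp=local_window_bp
    )
    from statsmodels.stats.multitest import multipletests

    emp = pd.Series(trait_best_emp_p)
    padj = pd.Series(multipletests(emp, method="fdr_bh")[1], index=emp.index)
    records["trait_padj"] = records["gene_id"].map(padj)
    return records
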