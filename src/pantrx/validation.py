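"""Self-validation experiments: accounting examples and planted-truth recovery.

Two families of checks live here so that the test suite and the
reproduction script share one implementation:

* worked accounting examples at the scale of a species-wide yeast
  expression catalog (thousands of ORFs, thousands of eQTL records),
  exercising the filter/merge bookkeeping, the inclusion rules of the
  abundance/dispersion statistics and the local/distant classification
  arithmetic on constructed inputs with known composition;

* recovery experiments that simulate data with planted effects
  (coexpression modules, clade DE, local/distant eQTLs, aneuploidy
  dosage) and measure how well the pipeline recovers the truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ase import ase_test, compute_aar, filter_sites
from .coexpression import build_network, compute_tom, detect_modules
from .datatypes import ExpressionMatrix, GenotypeMatrix, log2_tpm1
from .diffexpr import clade_de, significant_hits
from .eqtl import (
    LmmContext,
    catalog_summary,
    classify_eqtls,
    kinship,
    lmm_assoc,
    map_eqtls,
    permutation_threshold,
    prepare_variants,
)
from .pan_expression import abundance_dispersion
from .quantify import (
    compute_tpm,
    dosage_response,
    filter_and_merge_genes,
    variance_stabilize,
)
from .simulate import (
    SimConfig,
    karyotype_table,
    null_config,
    simulate_ase_counts,
    simulate_population,
)

# ---------------------------------------------------------------------------
# worked accounting examples


def orf_filter_merge_example(
    n_reference: int = 6285,
    n_low: int = 196,
    n_accessory: int = 395,
    n_with_homolog: int = 39,
    n_isolates: int = 4,
):
    """Filter + merge bookkeeping on a constructed reference catalog.

    Builds a TPM matrix with ``n_reference`` reference genes of which
    ``n_low`` sit below the log2(TPM+1) < 1 threshold in every isolate,
    plus ``n_accessory`` accessory features of which ``n_with_homolog``
    carry a homolog link, and returns the filter/merge report.
    """
    ref_ids = [f"ref{i:04d}" for i in range(n_reference)]
    acc_ids = [f"acc{i:04d}" for i in range(n_accessory)]
    gene_ids = ref_ids + acc_ids
    tpm_values = np.full((len(gene_ids), n_isolates), 100.0)
    tpm_values[:n_low] = 0.5  # log2(1.5) < 1 in every isolate
    homolog = [None] * len(gene_ids)
    for k in range(n_with_homolog):
        # merge targets are well-expressed reference genes
        homolog[n_reference + k] = ref_ids[n_low + k]
    annotation = pd.DataFrame(
        {
            "class": ["core"] * n_reference + ["accessory"] * n_accessory,
            "subcategory": "none",
            "chrom": "chr1",
            "start": np.arange(len(gene_ids)) * 2000 + 1,
            "end": np.arange(len(gene_ids)) * 2000 + 1500,
            "strand": "+",
            "length": 1500,
            "homolog_of": homolog,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    tpm = ExpressionMatrix(
        pd.DataFrame(
            tpm_values, index=gene_ids, columns=[f"iso{j}" for j in range(n_isolates)]
        ),
        "tpm",
    )
    _, report = filter_and_merge_genes(tpm, annotation)
    return report


def inclusion_accounting_example(
    n_core: int = 4977,
    n_accessory: int = 1468,
    n_core_included: int = 4847,
    n_accessory_included: int = 1291,
    n_isolates: int = 6,
) -> dict:
    """Carrier-based inclusion rules on a constructed pan-genome.

    Core and accessory genes beyond the included counts are made
    ineligible (unexpressed everywhere or carried by a single isolate);
    returns the per-class counts the abundance/dispersion statistics keep.
    """
    gene_ids = [f"core{i:04d}" for i in range(n_core)] + [
        f"acc{i:04d}" for i in range(n_accessory)
    ]
    classes = ["core"] * n_core + ["accessory"] * n_accessory
    isolates = [f"iso{j}" for j in range(n_isolates)]
    values = np.tile(np.linspace(2.0, 4.0, n_isolates), (len(gene_ids), 1))
    presence = np.ones((len(gene_ids), n_isolates), dtype=bool)
    # excluded core genes: expressed in no isolate
    values[n_core_included:n_core] = 0.0
    # excluded accessory genes: present in a single isolate
    excl_acc = slice(n_core + n_accessory_included, n_core + n_accessory)
    presence[excl_acc] = False
    presence[excl_acc, 0] = True
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=isolates), "log2tpm1"
    )
    presence_df = pd.DataFrame(presence, index=gene_ids, columns=isolates)
    annotation = pd.DataFrame({"class": classes}, index=pd.Index(gene_ids, name="gene_id"))
    stats = abundance_dispersion(expr, presence_df, annotation)
    by_class = stats["class"].value_counts()
    return {
        "n_included": len(stats),
        "n_core": int(by_class.get("core", 0)),
        "n_accessory": int(by_class.get("accessory", 0)),
    }


def eqtl_catalog_example(
    n_local_snp: int = 1901,
    n_distant_snp: int = 5372,
    n_cnv: int = 2197,
) -> dict:
    """Local/distant classification arithmetic on a constructed catalog.

    Places ``n_local_snp`` SNP records within the 25-kb window of their
    trait gene, ``n_distant_snp`` far outside it, and ``n_cnv`` CNV
    records on other ORFs, classifies them, and summarizes the catalog.
    """
    trait = "trait_gene"
    annotation = pd.DataFrame(
        {
            "class": ["core"],
            "chrom": ["chr1"],
            "start": [1_000_000],
            "end": [1_002_000],
            "length": [2_000],
        },
        index=pd.Index([trait], name="gene_id"),
    )
    n_total = n_local_snp + n_distant_snp + n_cnv
    rng = np.random.default_rng(0)
    positions = np.concatenate(
        [
            rng.integers(1_000_000 - 25_000, 1_002_000 + 25_001, n_local_snp),
            rng.integers(2_000_000, 5_000_000, n_distant_snp),
            rng.integers(1, 5_000_000, n_cnv),
        ]
    )
    types = ["SNP"] * (n_local_snp + n_distant_snp) + ["CNV"] * n_cnv
    vids = [f"v{i:05d}" for i in range(n_total)]
    meta = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": positions,
            "type": types,
            "orf": [None] * (n_local_snp + n_distant_snp) + ["other_orf"] * n_cnv,
        },
        index=pd.Index(vids, name="variant_id"),
    )
    values = pd.DataFrame(
        np.ones((n_total, 2)), index=vids, columns=["isoA", "isoB"]
    )
    genotypes = GenotypeMatrix(meta, values)
    records = pd.DataFrame(
        {
            "variant_id": vids,
            "gene_id": trait,
            "p_corrected": 1e-8,
            "is_group_representative": True,
        }
    )
    records = classify_eqtls(records, annotation, genotypes)
    return catalog_summary(records, genotypes)


# ---------------------------------------------------------------------------
# recovery experiments on planted truth


def module_recovery(seeds) -> list[float]:
    """Adjusted Rand index of detected vs planted modules per seed."""
    from sklearn.metrics import adjusted_rand_score

    scores = []
    for seed in seeds:
        ds = simulate_population(SimConfig(seed=seed))
        vst = variance_stabilize(ds.counts)
        net = build_network(vst)
        _, dissim = compute_tom(net.correlation)
        modules = detect_modules(dissim, vst.subset_genes(net.nodes))
        truth = (
            ds.truth["modules"]
            .set_index("gene_id")["module"]
            .reindex(net.nodes)
            .fillna(0)
            .astype(int)
        )
        scores.append(
            float(adjusted_rand_score(truth, modules.assignments.loc[net.nodes]))
        )
    return scores


def eqtl_recovery(seed: int, n_null_traits: int = 10, n_perm: int = 100) -> dict:
    """Planted local/distant eQTL recovery through the full pipeline.

    A planted eQTL counts as recovered when a significant representative
    record for its trait names the planted variant or one in linkage
    (R^2 > 0.6) with it; representatives matching no planted effect count
    toward the false-discovery proportion.
    """
    ds = simulate_population(SimConfig(seed=seed))
    tpm = compute_tpm(ds.counts, ds.gene_annotation["length"])
    snps = prepare_variants(ds.genotypes.of_type("SNP"), ds.chrom_lengths, snp_mask=True)
    K = kinship(snps)
    truth = ds.truth["eqtl"]
    planted_traits = list(truth["gene_id"])
    null_traits = [
        g for g in ds.gene_annotation.index if g not in set(planted_traits)
    ][:n_null_traits]
    records = map_eqtls(
        tpm.subset_genes(planted_traits + null_traits),
        snps,
        ds.gene_annotation,
        K=K,
        n_perm=n_perm,
        seed=seed + 1,
    )
    reps = records[records["is_group_representative"]]
    dosage = snps.values

    def linked(a: str, b: str) -> bool:
        if a == b:
            return True
        if a not in dosage.index or b not in dosage.index:
            return False
        va, vb = dosage.loc[a].to_numpy(), dosage.loc[b].to_numpy()
        if va.std() == 0 or vb.std() == 0:
            return False
        return np.corrcoef(va, vb)[0, 1] ** 2 > 0.6

    matched_rep_idx: set = set()
    n_recovered = n_local_recovered = n_local_correct = 0
    for rec in truth.itertuples():
        sub = reps[reps["gene_id"] == rec.gene_id]
        for idx, rrow in sub.iterrows():
            if linked(rrow["variant_id"], rec.variant_id):
                matched_rep_idx.add(idx)
                n_recovered += 1
                if rec.locality == "local":
                    n_local_recovered += 1
                    if rrow["locality"] == "local":
                        n_local_correct += 1
                break
    n_local_planted = int((truth["locality"] == "local").sum())
    fdp = (len(reps) - len(matched_rep_idx)) / max(len(reps), 1)
    return {
        "n_planted": len(truth),
        "n_recovered": n_recovered,
        "local_recovery": n_local_correct / max(n_local_planted, 1),
        "fdp": float(fdp),
        "n_representatives": len(reps),
    }


def de_recovery(seed: int) -> dict:
    """Estimated vs planted log2 fold changes for one clade's DE genes."""
    ds = simulate_population(SimConfig(seed=seed))
    iso = ds.isolate_annotation
    truth = ds.truth["de"]
    clade = sorted(truth["clade"].unique())[0]
    table = clade_de(ds.counts, iso["clade"], iso["mating_type"], clade)
    planted = truth[truth["clade"] == clade].set_index("gene_id")
    est = table.set_index("gene_id").reindex(planted.index)
    err = (est["log2fc"] - planted["log2fc"]).abs()
    return {
        "mean_abs_error": float(err.mean()),
        "mean_abs_estimate": float(est["log2fc"].abs().mean()),
        "n_planted": len(planted),
        "n_detected": int((est["padj"] < 0.05).sum()),
    }


def de_null_false_positives(seed: int, clade: str = "clade3") -> dict:
    """Significant-hit count on a simulation with no planted clade effects."""
    ds = simulate_population(null_config(seed=seed))
    iso = ds.isolate_annotation
    table = clade_de(ds.counts, iso["clade"], iso["mating_type"], clade)
    hits = significant_hits(table, lfc_cut=0.0, fdr=0.05)
    return {"n_tested": len(table), "n_hits": len(hits)}


def ase_calibration(seed: int, n_sites: int = 10_000) -> dict:
    """Type-I error of the empirical-null ASE test under global bias 0.02."""
    sites = compute_aar(
        simulate_ase_counts(SimConfig(ase_bias=0.02, ase_n_sites=n_sites, seed=seed))
    )
    kept, _ = filter_sites(sites)
    out, summary = ase_test(kept)
    return {
        "p0": summary["p0"],
        "type1_rate": float((out["p"] < 0.05).mean()),
        "fdr_rate": float((out["q"] < 0.05).mean()),
        "n_sites": len(out),
    }


def eqtl_fwer(seed: int, n_traits: int = 200, n_isolates: int = 100, n_perm: int = 100) -> dict:
    """Family-wise error of the permutation threshold on null traits."""
    cfg = null_config(n_isolates=n_isolates, n_snps=300, seed=seed)
    ds = simulate_population(cfg)
    snps = prepare_variants(
        ds.genotypes.of_type("SNP"), ds.chrom_lengths, snp_mask=False
    )
    K = kinship(snps)
    context = LmmContext.from_kinship(K)
    rng = np.random.default_rng(seed + 1)
    n_rejections = 0
    for t in range(n_traits):
        y = pd.Series(rng.normal(size=n_isolates), index=snps.isolate_ids)
        assoc = lmm_assoc(y, snps, K, context=context)
        threshold = permutation_threshold(
            y,
            snps,
            K,
            n_perm=n_perm,
            rng=np.random.default_rng(seed + 100 + t),
            context=context,
        )
        if np.nanmin(assoc["p_raw"].to_numpy()) < threshold:
            n_rejections += 1
    return {"fwer": n_rejections / n_traits, "n_traits": n_traits}


def gsea_null_uniformity(seed: int, n_sets: int = 500, n_perm: int = 500) -> dict:
    """KS test of GSEA p-values for random sets under a random ranking."""
    from scipy import stats as sps

    from .enrichment import preranked_gsea

    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(1000)]
    ranking = pd.Series(rng.normal(size=1000), index=genes)
    sets = {
        f"s{k}": list(rng.choice(genes, size=rng.integers(10, 50), replace=False))
        for k in range(n_sets)
    }
    res = preranked_gsea(ranking, sets, n_perm=n_perm, seed=seed + 1)
    tested = res[res["status"] == "tested"]
    ks = sps.kstest(tested["p"], "uniform")
    return {"ks_p": float(ks.pvalue), "n_sets": len(tested)}


def cutoff_sweep_example(seed: int = 0) -> dict:
    """Fold-change cutoff sweep on a constructed size-biased DE fixture.

    Small-effect hits (|log2FC| < 0.3) scale 5x with clade size while
    larger effects are constant across clades, so the hit-count vs size
    dependency disappears exactly at the 0.3 grid point.
    """
    from .diffexpr import cutoff_sweep

    rng = np.random.default_rng(seed)
    clade_sizes = {f"c{i}": s for i, s in enumerate((20, 40, 80, 120, 160, 200))}
    tables = {}
    for clade, size in clade_sizes.items():
        n_small = 5 * size
        small = rng.uniform(0.05, 0.28, n_small) * rng.choice([-1, 1], n_small)
        big = rng.uniform(0.35, 1.0, 30) * rng.choice([-1, 1], 30)
        lfc = np.concatenate([small, big])
        tables[clade] = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(lfc))],
                "clade": clade,
                "log2fc": lfc,
                "p": 0.001,
                "padj": 0.01,
            }
        )
    chosen, _ = cutoff_sweep(tables, clade_sizes)
    return {"chosen_cutoff": float(chosen)}


def dosage_attenuation(seed: int, compensation: float) -> dict:
    """Mean recovered attenuation on simulated aneuploid isolates."""
    ds = simulate_population(
        SimConfig(seed=seed, dosage_compensation=compensation, n_aneuploid_isolates=10)
    )
    expr = log2_tpm1(compute_tpm(ds.counts, ds.gene_annotation["length"]))
    dr = dosage_response(
        expr,
        karyotype_table(ds),
        ds.isolate_annotation["ploidy"],
        ds.gene_annotation["chrom"],
    )
    return {
        "planted_compensation": compensation,
        "mean_attenuation": float(dr["attenuation"].mean()),
        "n_aneuploid": len(dr),
    }
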