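"""Synthetic pan-transcriptome datasets with planted ground truth.

The generator emulates the statistical structure of a species-wide RNA-seq
panel over a clade-structured population: a pan-genome of core genes
(present in every isolate) and accessory genes (present in a clade-biased
subset), negative-binomial read counts whose log-means carry planted
coexpression factors, clade differential-expression effects, mating-type
effects, SNP/CNV eQTL effects and aneuploidy dosage effects, plus a
companion allele-count table for allele-specific expression with a global
reference-ward mapping bias.

Counts are structural zeros wherever a gene is absent from an isolate's
genome, which is what distinguishes accessory-gene zeros from sampling
zeros downstream.

Genotypes get their clade structure from a Balding-Nichols model: each
SNP has an ancestral frequency p drawn from ``maf_range`` and clade-level
frequencies drawn from Beta(p(1-F)/F, (1-p)(1-F)/F), so the kinship matrix
seen by the eQTL mixed model shows realistic block structure without any
sequence simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GenotypeMatrix, SyntheticDataset

__all__ = ["SimConfig", "simulate_population", "simulate_ase_counts"]


@dataclass
class SimConfig:
    """Parameters of the population simulator.

    Defaults describe a desk-scale population: 200 isolates in 5 clades of
    unequal size, a pan-genome of 400 core + 100 accessory genes on 4
    chromosomes, 6 planted coexpression modules of 25 genes, 10 planted
    differentially expressed genes per clade at |log2FC| = 1, and 20 local
    plus 20 distant SNP eQTLs with per-allele effects of 0.75-1.25 on the
    log2 expression scale.
    """

    n_isolates: int = 200
    n_clades: int = 5
    clade_sizes: Sequence[int] | None = None  # default: unequal split
    n_core_genes: int = 400
    n_accessory_genes: int = 100
    accessory_presence_freq: float = 0.6
    accessory_clade_bias: float = 3.0  # odds multiplier in the gene's home clade
    n_chromosomes: int = 4
    n_snps: int = 300
    n_cnvs: int = 30
    maf_range: tuple = (0.05, 0.5)
    bn_fst: float = 0.1  # Balding-Nichols differentiation of clade allele freqs
    n_modules: int = 6
    module_sizes: Sequence[int] | None = None  # default: 25 genes each
    module_factor_sd: float = 1.0  # log2-scale sd of the shared latent factor
    n_de_genes_per_clade: int = 10
    de_log2fc: float = 1.0
    n_local_eqtl: int = 20
    n_distant_eqtl: int = 20
    eqtl_beta_range: tuple = (0.75, 1.25)  # |effect| per allele on log2 scale
    cnv_dosage_effect: bool = True  # CNV copy number scales its own ORF
    nb_dispersion: float = 0.05
    mean_log2tpm_range: tuple = (3.0, 9.0)
    library_depth: float = 5e5  # expected reads per isolate before size factors
    library_size_sd: float = 0.3  # log-normal sd of per-isolate size factors
    mating_type_fraction: float = 0.1  # fraction of haploid isolates
    mating_effect_genes: int = 5
    mating_log2fc: float = 1.0
    n_aneuploid_isolates: int = 5
    aneuploid_copy_ratio: float = 1.5  # e.g. trisomy in a diploid
    dosage_compensation: float = 0.0  # 0 = none, 1 = full attenuation
    ase_bias: float = 0.02  # reference-ward shift of the null AAR
    ase_n_sites: int = 2000
    ase_coverage_mean: float = 60.0
    ase_n_imbalanced: int = 0
    ase_imbalance_prob: float = 0.8
    local_window_bp: int = 25_000
    subtelomere_bp: int = 20_000
    seed: int = 0

    def resolved_clade_sizes(self) -> np.ndarray:
        if self.clade_sizes is not None:
            return np.asarray(self.clade_sizes, dtype=int)
        # unequal split mimicking dominant + minor subpopulations
        weights = np.linspace(2.0, 0.7, self.n_clades)
        sizes = np.floor(self.n_isolates * weights / weights.sum()).astype(int)
        sizes[0] += self.n_isolates - sizes.sum()
        return sizes

    def resolved_module_sizes(self) -> np.ndarray:
        if self.module_sizes is not None:
            return np.asarray(self.module_sizes, dtype=int)
        return np.full(self.n_modules, 25, dtype=int)

    def validate(self) -> None:
        sizes = self.resolved_clade_sizes()
        if sizes.sum() != self.n_isolates:
            raise ValueError(
                f"clade_sizes sum to {sizes.sum()}, expected n_isolates={self.n_isolates}"
            )
        if (sizes <= 0).any():
            raise ValueError("clade sizes must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in (
            "accessory_presence_freq",
            "mating_type_fraction",
            "dosage_compensation",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.ase_bias < 0.5:
            raise ValueError("ase_bias must be in [0, 0.5)")
        n_genes = self.n_core_genes + self.n_accessory_genes
        if self.resolved_module_sizes().sum() > self.n_core_genes:
            raise ValueError("module sizes exceed the number of core genes")
        if self.n_local_eqtl + self.n_distant_eqtl > self.n_snps:
            raise ValueError("more planted eQTLs than SNPs")
        if n_genes < 1:
            raise ValueError("need at least one gene")
        if self.ase_coverage_mean <= 0:
            raise ValueError("ase_coverage_mean must be positive")


def null_config(**overrides) -> SimConfig:
    """A configuration with every planted effect switched off."""
    cfg = SimConfig(
        module_factor_sd=0.0,
        n_de_genes_per_clade=0,
        de_log2fc=0.0,
        n_local_eqtl=0,
        n_distant_eqtl=0,
        eqtl_beta_range=(0.0, 0.0),
        cnv_dosage_effect=False,
        mating_effect_genes=0,
        n_aneuploid_isolates=0,
        ase_bias=0.0,
        ase_n_imbalanced=0,
    )
    return replace(cfg, **overrides)


# ---------------------------------------------------------------------------
# genome layout


def _layout_genes(cfg: SimConfig, rng: np.random.Generator):
    """Place genes on linear chromosomes, 1-based inclusive intervals.

    Genes start beyond the subtelomeric mask so that variant masking does
    not interact with planted local eQTLs.
    """
    n_genes = cfg.n_core_genes + cfg.n_accessory_genes
    gene_ids = [f"gene{i:04d}" for i in range(n_genes)]
    classes = ["core"] * cfg.n_core_genes + ["accessory"] * cfg.n_accessory_genes
    sub = ["none"] * cfg.n_core_genes + [
        rng.choice(["introgression", "HGT", "none"], p=[0.4, 0.2, 0.4])
        for _ in range(cfg.n_accessory_genes)
    ]
    chrom_of = np.arange(n_genes) % cfg.n_chromosomes
    lengths = rng.integers(500, 3001, size=n_genes)
    rows = []
    cursor = {c: cfg.subtelomere_bp + 5_000 for c in range(cfg.n_chromosomes)}
    for i in range(n_genes):
        c = int(chrom_of[i])
        start = cursor[c]
        end = start + int(lengths[i]) - 1
        cursor[c] = end + 1_001  # intergenic gap
        rows.append(
            {
                "gene_id": gene_ids[i],
                "class": classes[i],
                "subcategory": sub[i],
                "chrom": f"chr{c + 1}",
                "start": start,
                "end": end,
                "strand": "+" if rng.random() < 0.5 else "-",
                "length": int(lengths[i]),
                "homolog_of": None,
            }
        )
    annotation = pd.DataFrame(rows).set_index("gene_id")
    chrom_lengths = {
        f"chr{c + 1}": int(cursor[c] + cfg.subtelomere_bp + 5_000)
        for c in range(cfg.n_chromosomes)
    }
    return annotation, chrom_lengths


def _simulate_isolates(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    sizes = cfg.resolved_clade_sizes()
    clades = np.repeat([f"clade{i + 1}" for i in range(cfg.n_clades)], sizes)
    isolate_ids = [f"iso{i:04d}" for i in range(cfg.n_isolates)]
    n_haploid = int(round(cfg.mating_type_fraction * cfg.n_isolates))
    haploid_idx = rng.choice(cfg.n_isolates, size=n_haploid, replace=False)
    ploidy = np.full(cfg.n_isolates, 2, dtype=int)
    ploidy[haploid_idx] = 1
    mating = np.full(cfg.n_isolates, "a/alpha", dtype=object)
    mating[haploid_idx] = rng.choice(["MATa", "MATalpha"], size=n_haploid)
    return pd.DataFrame(
        {"clade": clades, "ploidy": ploidy, "mating_type": mating},
        index=pd.Index(isolate_ids, name="isolate_id"),
    )


def _simulate_presence(
    cfg: SimConfig, annotation: pd.DataFrame, isolates: pd.DataFrame, rng
) -> pd.DataFrame:
    presence = pd.DataFrame(
        True, index=annotation.index, columns=isolates.index
    )
    accessory = annotation.index[annotation["class"] == "accessory"]
    clade_labels = isolates["clade"].to_numpy()
    clade_names = [f"clade{i + 1}" for i in range(cfg.n_clades)]
    base = cfg.accessory_presence_freq
    for g in accessory:
        home = clade_names[int(rng.integers(cfg.n_clades))]
        odds = base / (1 - base) if base < 1 else np.inf
        p_home = min(1.0, odds * cfg.accessory_clade_bias / (1 + odds * cfg.accessory_clade_bias))
        probs = np.where(clade_labels == home, p_home, base)
        carried = rng.random(cfg.n_isolates) < probs
        if carried.sum() < 2:  # keep every gene analysable
            carried[rng.choice(cfg.n_isolates, size=2, replace=False)] = True
        presence.loc[g] = carried
    return presence


# ---------------------------------------------------------------------------
# genotypes


def _balding_nichols_snp(p: float, clade_sizes, fst: float, rng) -> np.ndarray:
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    dosages = []
    for n_c in clade_sizes:
        pc = rng.beta(a, b)
        dosages.append(rng.binomial(2, pc, size=n_c))
    return np.concatenate(dosages)


def _constructive_dosage(p: float, n: int, rng) -> np.ndarray:
    """Dosage vector whose empirical allele frequency is exactly round(2np)/2n."""
    k = int(round(p * 2 * n))
    k = min(max(k, 1), 2 * n - 1)
    alleles = np.zeros(2 * n, dtype=int)
    alleles[rng.choice(2 * n, size=k, replace=False)] = 1
    return alleles.reshape(n, 2).sum(axis=1)


def _simulate_snps(cfg: SimConfig, chrom_lengths, rng) -> tuple[pd.DataFrame, np.ndarray]:
    lo, hi = cfg.maf_range
    sizes = cfg.resolved_clade_sizes()
    chroms = list(chrom_lengths)
    rows, dosage_rows = [], []
    for i in range(cfg.n_snps):
        target = rng.uniform(lo, hi)
        dos = None
        for _ in range(200):
            cand = _balding_nichols_snp(target, sizes, cfg.bn_fst, rng)
            f = cand.mean() / 2
            if lo <= min(f, 1 - f) <= hi:
                dos = cand
                break
        if dos is None:  # degenerate draw streak: build the frequency directly
            dos = _constructive_dosage(target, cfg.n_isolates, rng)
        c = chroms[int(rng.integers(len(chroms)))]
        pos = int(
            rng.integers(
                cfg.subtelomere_bp + 1, chrom_lengths[c] - cfg.subtelomere_bp
            )
        )
        rows.append({"variant_id": f"snp{i:05d}", "chrom": c, "pos": pos, "type": "SNP", "orf": None})
        dosage_rows.append(dos)
    return pd.DataFrame(rows).set_index("variant_id"), np.asarray(dosage_rows)


def _simulate_cnvs(
    cfg: SimConfig, annotation: pd.DataFrame, rng, candidate_genes=None
) -> tuple[pd.DataFrame, np.ndarray]:
    empty_meta = pd.DataFrame(
        columns=["chrom", "pos", "type", "orf"],
        index=pd.Index([], name="variant_id"),
    )
    if cfg.n_cnvs == 0:
        return empty_meta, np.empty((0, cfg.n_isolates), dtype=int)
    lo, hi = cfg.maf_range
    sizes = cfg.resolved_clade_sizes()
    pool = (
        np.asarray(candidate_genes)
        if candidate_genes is not None
        else annotation.index.to_numpy()
    )
    genes = rng.choice(pool, size=cfg.n_cnvs, replace=False)
    rows, value_rows = [], []
    for i, g in enumerate(genes):
        freq = rng.uniform(max(lo, 0.1), hi)
        alt_copy = int(rng.choice([1, 3]))
        carrier = None
        for _ in range(200):
            cand_parts = []
            a = freq * (1 - cfg.bn_fst) / cfg.bn_fst
            b = (1 - freq) * (1 - cfg.bn_fst) / cfg.bn_fst
            for n_c in sizes:
                fc = rng.beta(a, b)
                cand_parts.append(rng.random(n_c) < fc)
            cand = np.concatenate(cand_parts)
            f = cand.mean()
            if lo <= min(f, 1 - f):
                carrier = cand
                break
        if carrier is None:
            carrier = np.zeros(cfg.n_isolates, dtype=bool)
            k = max(1, int(round(freq * cfg.n_isolates)))
            carrier[rng.choice(cfg.n_isolates, size=k, replace=False)] = True
        cn = np.where(carrier, alt_copy, 2)
        rows.append(
            {
                "variant_id": f"cnv{i:04d}",
                "chrom": annotation.loc[g, "chrom"],
                "pos": int(annotation.loc[g, "start"]),
                "type": "CNV",
                "orf": g,
            }
        )
        value_rows.append(cn)
    return pd.DataFrame(rows).set_index("variant_id"), np.asarray(value_rows)


# ---------------------------------------------------------------------------
# planting effects


def _plant_eqtls(cfg, annotation, snp_meta, chrom_lengths, rng, target_genes):
    """Relocate designated SNPs into/out of the target genes' 25-kb windows
    and return the truth table of (variant, gene, beta, locality)."""
    n_eqtl = cfg.n_local_eqtl + cfg.n_distant_eqtl
    if n_eqtl == 0:
        return pd.DataFrame(columns=["variant_id", "gene_id", "beta", "locality"])
    genes = np.asarray(target_genes[:n_eqtl])
    if len(genes) < n_eqtl:
        raise ValueError("not enough unplanted genes for the requested eQTLs")
    snp_ids = rng.choice(snp_meta.index.to_numpy(), size=n_eqtl, replace=False)
    lo, hi = cfg.eqtl_beta_range
    records = []
    for k in range(n_eqtl):
        g, v = genes[k], snp_ids[k]
        gene = annotation.loc[g]
        local = k < cfg.n_local_eqtl
        if local:
            c = gene["chrom"]
            lo_pos = max(cfg.subtelomere_bp + 1, gene["start"] - cfg.local_window_bp)
            hi_pos = min(
                chrom_lengths[c] - cfg.subtelomere_bp, gene["end"] + cfg.local_window_bp
            )
            pos = int(rng.integers(lo_pos, hi_pos + 1))
        else:
            others = [c for c in chrom_lengths if c != gene["chrom"]]
            c = others[int(rng.integers(len(others)))]
            pos = int(
                rng.integers(cfg.subtelomere_bp + 1, chrom_lengths[c] - cfg.subtelomere_bp)
            )
        snp_meta.loc[v, ["chrom", "pos"]] = [c, pos]
        beta = rng.uniform(lo, hi) * (1 if rng.random() < 0.5 else -1)
        records.append(
            {
                "variant_id": v,
                "gene_id": g,
                "beta": beta,
                "locality": "local" if local else "distant",
            }
        )
    return pd.DataFrame(records)


def simulate_population(config: SimConfig) -> SyntheticDataset:
    """Simulate a full dataset; deterministic for a fixed ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    annotation, chrom_lengths = _layout_genes(config, rng)
    isolates = _simulate_isolates(config, rng)
    presence = _simulate_presence(config, annotation, isolates, rng)
    snp_meta, snp_dosage = _simulate_snps(config, chrom_lengths, rng)

    n_genes, n_iso = len(annotation), config.n_isolates
    gene_pos = {g: i for i, g in enumerate(annotation.index)}

    # baseline log2 expression per gene
    log2mu = np.tile(
        rng.uniform(*config.mean_log2tpm_range, size=n_genes)[:, None], (1, n_iso)
    )

    # coexpression modules: shared latent factor per module, positive loadings
    module_sizes = config.resolved_module_sizes()
    core_ids = list(annotation.index[annotation["class"] == "core"])
    perm = rng.permutation(len(core_ids))
    module_rows, offset = [], 0
    for m, size in enumerate(module_sizes, start=1):
        members = [core_ids[i] for i in perm[offset : offset + size]]
        offset += size
        factor = rng.normal(size=n_iso)
        for g in members:
            loading = config.module_factor_sd * rng.uniform(0.8, 1.2)
            log2mu[gene_pos[g]] += loading * factor
            module_rows.append({"gene_id": g, "module": m})
    modules_truth = pd.DataFrame(module_rows, columns=["gene_id", "module"])
    if config.module_factor_sd == 0:
        modules_truth = modules_truth.iloc[0:0]

    # clade DE, mating and eQTL effects are planted on disjoint pools of
    # core genes (remaining shuffled order), so each planted effect can be
    # recovered without interference from the others or from the
    # clade-biased structural zeros of accessory genes
    free = [core_ids[i] for i in perm[offset:]]
    de_rows = []
    clade_names = [f"clade{i + 1}" for i in range(config.n_clades)]
    cursor = 0
    clade_mask = {c: (isolates["clade"] == c).to_numpy() for c in clade_names}
    for c in clade_names:
        for _ in range(config.n_de_genes_per_clade):
            if cursor >= len(free):
                break
            g = free[cursor]
            cursor += 1
            lfc = config.de_log2fc * (1 if rng.random() < 0.5 else -1)
            if lfc != 0:
                log2mu[gene_pos[g], clade_mask[c]] += lfc
                de_rows.append({"gene_id": g, "clade": c, "log2fc": lfc})
    de_truth = pd.DataFrame(de_rows, columns=["gene_id", "clade", "log2fc"])

    # mating-type effects on haploid MATa isolates
    mating_rows = []
    is_mata = (isolates["mating_type"] == "MATa").to_numpy()
    for _ in range(config.mating_effect_genes):
        if cursor >= len(free):
            break
        g = free[cursor]
        cursor += 1
        log2mu[gene_pos[g], is_mata] += config.mating_log2fc
        mating_rows.append({"gene_id": g, "log2fc": config.mating_log2fc})
    mating_truth = pd.DataFrame(mating_rows, columns=["gene_id", "log2fc"])

    # SNP eQTL effects on the next block of unplanted core genes
    n_eqtl = config.n_local_eqtl + config.n_distant_eqtl
    eqtl_targets = free[cursor : cursor + n_eqtl]
    cursor += n_eqtl
    eqtl_truth = _plant_eqtls(
        config, annotation, snp_meta, chrom_lengths, rng, eqtl_targets
    )
    snp_index = {v: i for i, v in enumerate(snp_meta.index)}
    for rec in eqtl_truth.itertuples():
        if rec.beta != 0:
            log2mu[gene_pos[rec.gene_id]] += rec.beta * snp_dosage[snp_index[rec.variant_id]]
    eqtl_truth = eqtl_truth[eqtl_truth["beta"] != 0].reset_index(drop=True)

    # CNVs live on genes carrying no other planted effect
    used = set(modules_truth["gene_id"]) | set(free[:cursor])
    cnv_candidates = [g for g in annotation.index if g not in used]
    cnv_meta, cnv_values = _simulate_cnvs(config, annotation, rng, cnv_candidates)

    # CNV dosage effect on the CNV's own ORF
    cnv_rows = []
    if config.cnv_dosage_effect:
        for i, (v, meta) in enumerate(cnv_meta.iterrows()):
            g = meta["orf"]
            ratio = cnv_values[i] / 2.0
            with np.errstate(divide="ignore"):
                shift = np.where(ratio > 0, np.log2(np.maximum(ratio, 1e-12)), -20.0)
            log2mu[gene_pos[g]] += shift
            cnv_rows.append({"variant_id": v, "gene_id": g})
    cnv_truth = pd.DataFrame(cnv_rows, columns=["variant_id", "gene_id"])

    # aneuploidy: extra chromosome copies attenuated by dosage compensation
    iso_ann = isolates.copy()
    iso_ann["aneuploid_chrom"] = ""
    iso_ann["aneuploid_copy"] = iso_ann["ploidy"]
    dosage_rows = []
    diploids = np.flatnonzero((isolates["ploidy"] == 2).to_numpy())
    n_aneu = min(config.n_aneuploid_isolates, len(diploids))
    aneu_idx = rng.choice(diploids, size=n_aneu, replace=False)
    gene_chrom = annotation["chrom"].to_numpy()
    for j in aneu_idx:
        c = f"chr{int(rng.integers(config.n_chromosomes)) + 1}"
        base = int(isolates["ploidy"].iloc[j])
        copy = int(round(base * config.aneuploid_copy_ratio))
        ratio = copy / base
        effect = np.log2(ratio) * (1 - config.dosage_compensation)
        log2mu[gene_chrom == c, j] += effect
        iso_ann.iloc[j, iso_ann.columns.get_loc("aneuploid_chrom")] = c
        iso_ann.iloc[j, iso_ann.columns.get_loc("aneuploid_copy")] = copy
        dosage_rows.append(
            {
                "isolate_id": isolates.index[j],
                "chrom": c,
                "copy_number": copy,
                "copy_ratio": ratio,
                "dosage_compensation": config.dosage_compensation,
            }
        )
    dosage_truth = pd.DataFrame(
        dosage_rows,
        columns=["isolate_id", "chrom", "copy_number", "copy_ratio", "dosage_compensation"],
    )

    # negative-binomial counts with library-size factors and structural zeros
    size_factors = np.exp(rng.normal(0, config.library_size_sd, size=n_iso))
    rel = np.power(2.0, log2mu) * presence.to_numpy()
    lengths = annotation["length"].to_numpy()[:, None]
    mass = rel * lengths
    col_mass = mass.sum(axis=0, keepdims=True)
    col_mass[col_mass == 0] = 1.0
    mu = config.library_depth * size_factors[None, :] * mass / col_mass
    r = 1.0 / config.nb_dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    counts[~presence.to_numpy()] = 0

    counts_df = pd.DataFrame(counts, index=annotation.index, columns=isolates.index)
    truth = {
        "modules": modules_truth,
        "de": de_truth,
        "eqtl": eqtl_truth,
        "mating": mating_truth,
        "cnv_effects": cnv_truth,
        "dosage": dosage_truth,
    }
    genotypes = GenotypeMatrix(
        pd.concat([snp_meta, cnv_meta]),
        pd.DataFrame(
            np.vstack([snp_dosage, cnv_values]) if len(cnv_values) else snp_dosage,
            index=pd.concat([snp_meta, cnv_meta]).index,
            columns=isolates.index,
        ),
    )
    return SyntheticDataset(
        counts=ExpressionMatrix(counts_df, "raw_count"),
        gene_annotation=annotation,
        presence=presence,
        isolate_annotation=iso_ann,
        genotypes=genotypes,
        chrom_lengths=chrom_lengths,
        truth=truth,
    )


def karyotype_table(dataset: SyntheticDataset) -> pd.DataFrame:
    """Per-isolate chromosome copy numbers derived from the simulation truth."""
    iso = dataset.isolate_annotation
    chroms = list(dataset.chrom_lengths)
    kary = pd.DataFrame(
        np.repeat(iso["ploidy"].to_numpy()[:, None], len(chroms), axis=1),
        index=iso.index,
        columns=chroms,
    )
    for rec in dataset.truth["dosage"].itertuples():
        kary.loc[rec.isolate_id, rec.chrom] = rec.copy_number
    return kary


def simulate_ase_counts(config: SimConfig) -> pd.DataFrame:
    """Allele counts at heterozygous sites with truth labels.

    Null sites draw alt counts from Binomial(coverage, 0.5 - ase_bias); the
    ``ase_n_imbalanced`` first sites are planted with allele probability
    ``ase_imbalance_prob`` (reference- or alternative-skewed at random).
    Coverage is Poisson with mean ``ase_coverage_mean``.
    """
    config.validate()
    if config.ase_n_sites <= 0:
        raise ValueError("ase_n_sites must be positive")
    rng = np.random.default_rng(config.seed + 1)
    n = config.ase_n_sites
    coverage = np.maximum(1, rng.poisson(config.ase_coverage_mean, size=n))
    p_null = 0.5 - config.ase_bias
    probs = np.full(n, p_null)
    imbalanced = np.zeros(n, dtype=bool)
    k = min(config.ase_n_imbalanced, n)
    if k:
        imbalanced[:k] = True
        flip = rng.random(k) < 0.5
        probs[:k] = np.where(flip, 1 - config.ase_imbalance_prob, config.ase_imbalance_prob)
    alt = rng.binomial(coverage, probs)
    ref = coverage - alt
    genetic_ab = np.clip(rng.normal(0.5, 0.05, size=n), 0.05, 0.95)
    mappable = rng.random(n) > 0.02
    return pd.DataFrame(
        {
            "isolate_id": [f"iso{i % 50:04d}" for i in range(n)],
            "gene_id": [f"gene{i % 400:04d}" for i in range(n)],
            "chrom": [f"chr{(i % 4) + 1}" for i in range(n)],
            "pos": np.arange(1, n + 1) * 37,
            "ref_count": ref,
            "alt_count": alt,
            "genetic_AB": genetic_ab,
            "mappable": mappable,
            "true_imbalanced": imbalanced,
            "true_prob": probs,
        }
    )
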