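"""Core in-memory containers shared across the pipeline.

The pipeline is pandas-centric: matrices are DataFrames with genes as rows
and isolates as columns, annotation tables are DataFrames indexed by
``gene_id`` / ``isolate_id`` / ``variant_id``.  The thin wrappers here only
add the bookkeeping the analyses need (which scale an expression matrix is
on, which columns of a genotype table are dosages) and validate the
invariants that downstream stages rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Recognised expression scales, in the order transformations produce them.
EXPRESSION_SCALES = ("raw_count", "tpm", "log2tpm1", "vst")

#: Metadata columns of a genotype table; everything else is per-isolate dosage.
VARIANT_META_COLUMNS = ["chrom", "pos", "type", "orf"]


@dataclass
class ExpressionMatrix:
    """Genes x isolates expression values tagged with their scale.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene id, columns by isolate id.
    scale : str
        One of :data:`EXPRESSION_SCALES`.
    """

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in EXPRESSION_SCALES:
            raise ValueError(f"unknown expression scale {self.scale!r}")
        if self.scale == "raw_count":
            arr = self.values.to_numpy()
            if (arr < 0).any():
                raise ValueError("raw counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def isolate_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_isolates(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[gene_ids], self.scale)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({self.n_genes} genes x {self.n_isolates} "
            f"isolates, scale={self.scale})"
        )


def log2_tpm1(tpm: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1) transform of a TPM matrix."""
    if tpm.scale != "tpm":
        raise ValueError("log2_tpm1 expects a TPM-scale matrix")
    return ExpressionMatrix(np.log2(tpm.values + 1.0), "log2tpm1")


def validate_gene_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check a pan-genome gene annotation table.

    Expected columns: ``class`` (core/accessory), ``subcategory``
    (none/introgression/HGT), ``chrom``, ``start``, ``end``, ``strand``,
    ``length``, ``homolog_of``; index is the gene id.  Coordinates are
    1-based inclusive.
    """
    required = {"class", "chrom", "start", "end", "length"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
    if (annotation["start"] > annotation["end"]).any():
        raise ValueError("gene annotation has start > end")
    if (annotation["length"] <= 0).any():
        raise ValueError("gene annotation has non-positive length")
    if "homolog_of" in annotation.columns:
        links = annotation["homolog_of"].dropna()
        links = links[links != ""]
        unknown = set(links) - set(annotation.index)
        if unknown:
            raise ValueError(f"homolog_of points at unknown genes: {sorted(unknown)[:5]}")
    return annotation


@dataclass
class GenotypeMatrix:
    """Variants x isolates genotype values with positional metadata.

    ``variants`` holds one row per variant (chrom, pos, type, orf) indexed by
    variant id; ``values`` holds allele dosage (0/1/2) for SNPs and integer
    copy number for CNVs, same index, isolates as columns.
    """

    variants: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.variants.index.equals(self.values.index):
            raise ValueError("variant metadata and values must share an index")
        for col in ("chrom", "pos", "type"):
            if col not in self.variants.columns:
                raise ValueError(f"variant table missing column {col!r}")

    @property
    def variant_ids(self) -> pd.Index:
        return self.variants.index

    @property
    def isolate_ids(self) -> pd.Index:
        return self.values.columns

    def subset(self, variant_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.variants.loc[variant_ids], self.values.loc[variant_ids])

    def of_type(self, variant_type: str) -> "GenotypeMatrix":
        keep = self.variants.index[self.variants["type"] == variant_type]
        return self.subset(keep)

    def maf(self) -> pd.Series:
        """Minor allele frequency per variant.

        SNP dosages are counted as biallelic diploid calls; for CNVs the
        minor frequency is the fraction of isolates not carrying the modal
        copy number.
        """
        out = pd.Series(index=self.variants.index, dtype=float)
        snps = self.variants["type"] == "SNP"
        if snps.any():
            dos = self.values.loc[snps.index[snps]].to_numpy(dtype=float)
            p = dos.mean(axis=1) / 2.0
            out.loc[snps.index[snps]] = np.minimum(p, 1.0 - p)
        cnvs = ~snps
        if cnvs.any():
            cn = self.values.loc[cnvs.index[cnvs]]
            modal_frac = cn.apply(
                lambda row: row.value_counts().iloc[0] / len(row), axis=1
            )
            out.loc[cnvs.index[cnvs]] = 1.0 - modal_frac
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_snp = int((self.variants["type"] == "SNP").sum())
        n_cnv = int((self.variants["type"] == "CNV").sum())
        return (
            f"GenotypeMatrix({n_snp} SNPs + {n_cnv} CNVs x "
            f"{self.values.shape[1]} isolates)"
        )


@dataclass
class SyntheticDataset:
    """A complete simulated dataset with planted ground truth.

    ``truth`` is a dict of DataFrames recording every planted effect:
    ``modules`` (gene_id, module), ``de`` (gene_id, clade, log2fc),
    ``eqtl`` (variant_id, gene_id, beta, locality), ``dosage``
    (isolate_id, chrom, copy_ratio, dosage_compensation) and
    ``mating`` (gene_id, log2fc).
    """

    counts: ExpressionMatrix
    gene_annotation: pd.DataFrame
    presence: pd.DataFrame
    isolate_annotation: pd.DataFrame
    genotypes: GenotypeMatrix
    chrom_lengths: dict
    truth: dict = field(default_factory=dict)
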