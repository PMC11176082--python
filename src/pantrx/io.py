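"""Plain-text readers and writers (TSV matrices, GMT gene sets).

Every on-disk artifact of the pipeline is tab-separated text so that runs
can be archived and diffed.  Matrices are written genes-as-rows with the
index in the first column.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List

import pandas as pd

from .datatypes import ExpressionMatrix, GenotypeMatrix, VARIANT_META_COLUMNS


def read_matrix_tsv(path: str, scale: str | None = None):
    """Read a genes x isolates TSV; returns ExpressionMatrix if scale given."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if scale is None:
        return df
    return ExpressionMatrix(df, scale)


def write_matrix_tsv(matrix, path: str) -> None:
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    df.to_csv(path, sep="\t")


def read_gene_annotation(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "homolog_of" in df.columns:
        df["homolog_of"] = df["homolog_of"].where(df["homolog_of"].notna(), None)
    return df


def read_genotypes_tsv(path: str) -> GenotypeMatrix:
    """Genotype TSV: variant_id, chrom, pos, type[, orf], then one column
    per isolate (dosage for SNPs, copy number for CNVs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_cols = [c for c in VARIANT_META_COLUMNS if c in df.columns]
    variants = df[meta_cols].copy()
    values = df.drop(columns=meta_cols)
    return GenotypeMatrix(variants, values)


def write_genotypes_tsv(genotypes: GenotypeMatrix, path: str) -> None:
    meta = genotypes.variants
    pd.concat([meta, genotypes.values], axis=1).to_csv(path, sep="\t")


def read_gmt(path: str) -> Dict[str, List[str]]:
    """Read a GMT file: one set per line, name <tab> description <tab> genes."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Dict[str, Iterable[str]], path: str, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *map(str, members)]) + "\n")


def write_dataset(dataset, outdir: str) -> None:
    """Write all components of a SyntheticDataset as TSV/GMT under outdir."""
    os.makedirs(outdir, exist_ok=True)
    write_matrix_tsv(dataset.counts, os.path.join(outdir, "counts.tsv"))
    dataset.presence.astype(int).to_csv(os.path.join(outdir, "presence.tsv"), sep="\t")
    dataset.gene_annotation.to_csv(os.path.join(outdir, "gene_annotation.tsv"), sep="\t")
    dataset.isolate_annotation.to_csv(
        os.path.join(outdir, "isolate_annotation.tsv"), sep="\t"
    )
    write_genotypes_tsv(dataset.genotypes, os.path.join(outdir, "genotypes.tsv"))
    pd.Series(dataset.chrom_lengths, name="length").rename_axis("chrom").to_csv(
        os.path.join(outdir, "chrom_lengths.tsv"), sep="\t"
    )
    for name, table in dataset.truth.items():
        table.to_csv(os.path.join(outdir, f"truth_{name}.tsv"), sep="\t", index=False)
    modules = dataset.truth.get("modules")
    if modules is not None and len(modules):
        sets = {
            f"module_{m}": sorted(g)
            for m, g in modules.groupby("module")["gene_id"].apply(list).items()
        }
        write_gmt(sets, os.path.join(outdir, "modules.gmt"), "planted coexpression module")
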