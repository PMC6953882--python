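"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as minimal VCF (haploid GT per line) or as a TSV
matrix; methylation counts as allc-style long TSV; the TE annotation
as BED6+3; metadata, panels and all results as TSV with a one-line
``#`` schema header.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    GenotypeMatrix,
    LineMetadataTable,
    MethylCountTable,
    MutantPanel,
)

# ---------------------------------------------------------------------------
# genotypes


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF: biallelic sites REF=A ALT=T, haploid GT per line."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted(genotypes.snps["chrom"].unique()):
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = "\t".join(genotypes.line_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        G = genotypes.G
        for j, row in enumerate(genotypes.snps.itertuples(index=False)):
            gts = "\t".join("." if g < 0 else str(int(g)) for g in G[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a (plain-text) VCF of haploid biallelic sites via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    line_ids = list(vcf.samples)
    rows, cols = [], []
    for var in vcf:
        g = np.asarray(var.gt_types)
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=missing; haploid calls
        # surface as hom calls
        col = np.where(g == 3, -1, np.where(g >= 1, 1, 0)).astype(np.int8)
        cols.append(col)
        rows.append((var.ID, _chrom_to_int(var.CHROM), var.POS))
    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])
    G = np.stack(cols, axis=1)
    f = np.where(G >= 0, G, 0).sum(0) / np.maximum((G >= 0).sum(0), 1)
    snps["maf"] = np.minimum(f, 1 - f)
    return GenotypeMatrix(G, line_ids, snps)


def _chrom_to_int(chrom: str):
    try:
        return int(str(chrom).removeprefix("chr"))
    except ValueError:
        return chrom


def write_genotype_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        genotypes.G.T, index=genotypes.snps["snp_id"], columns=genotypes.line_ids
    )
    meta = genotypes.snps.set_index("snp_id")
    out = pd.concat([meta[["chrom", "pos", "maf"]], df], axis=1)
    out.to_csv(path, sep="\t", index_label="snp_id")


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="snp_id", comment="#")
    meta_cols = ["chrom", "pos", "maf"]
    snps = df[meta_cols].reset_index()
    G = df.drop(columns=meta_cols).to_numpy(dtype=np.int8).T
    return GenotypeMatrix(G, list(df.columns[len(meta_cols):]), snps)


# ---------------------------------------------------------------------------
# methylation counts and annotation


def write_allc_tsv(table: MethylCountTable, path: str | Path) -> None:
    df = table.to_long_frame()
    with open(path, "w") as fh:
        fh.write("#line_id\tte_id\tmc_count\ttotal_count\n")
        df.to_csv(fh, sep="\t", index=False, header=False)


def read_allc_tsv(path: str | Path) -> MethylCountTable:
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["line_id", "te_id", "mc_count", "total_count"],
    )
    return MethylCountTable.from_long_frame(df)


BED_COLUMNS = ["chrom", "start", "end", "te_id", "length", "strand",
               "family", "superfamily", "te_class"]


def write_annotation_bed(annotation: pd.DataFrame, path: str | Path) -> None:
    """BED6+3: name=te_id, score=length, extra columns family,
    superfamily, class (0-based half-open intervals)."""
    bed = pd.DataFrame(
        {
            "chrom": annotation["chrom"],
            "start": annotation["start"],
            "end": annotation["end"],
            "te_id": annotation["te_id"],
            "length": annotation["length"],
            "strand": "+",
            "family": annotation["family"],
            "superfamily": annotation["superfamily"],
            "te_class": annotation["te_class"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_annotation_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", names=BED_COLUMNS)
    if (df["start"] > df["end"]).any():
        raise ValueError("BED interval with start > end")
    center = df.groupby("chrom")["end"].transform("max") / 2
    df["pericentromeric"] = (df["start"] + df["length"] / 2 - center).abs() < center / 5
    return df


# ---------------------------------------------------------------------------
# metadata / panel / generic tables


def write_metadata_tsv(metadata: LineMetadataTable, path: str | Path) -> None:
    write_table(metadata.table, path)


def read_metadata_tsv(path: str | Path) -> LineMetadataTable:
    return LineMetadataTable(read_table(path))


def write_mutant_panel_tsv(panel: MutantPanel, path: str | Path) -> None:
    df = panel.dml.reset_index(names="mutant_id")
    write_table(df, path)


def read_mutant_panel_tsv(path: str | Path, **kwargs) -> MutantPanel:
    df = read_table(path).set_index("mutant_id")
    return MutantPanel(dml=df, **kwargs)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """TSV with a one-line ``#`` schema header."""
    with open(path, "w") as fh:
        cols = ([df.index.name or "index"] if index else []) + list(df.columns)
        fh.write("#" + "\t".join(str(c) for c in cols) + "\n")
        df.to_csv(fh, sep="\t", index=index, header=False)


def read_table(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip().split("\t")
    return pd.read_csv(path, sep="\t", comment="#", names=header)
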