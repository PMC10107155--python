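"""Readers and writers for the package's plain-text interchange formats.

Allele depths travel as minimal VCF v4.2 (AD format field, read back with
cyvcf2) or TSV; binned coverage as 4-column bedGraph-like TSV; karyotypes
as one-row-per-spore TSV with values in {0, A, B, AB, AA, BB}.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genome import ChromosomeTable

__all__ = [
    "write_allele_depths_tsv",
    "read_allele_depths_tsv",
    "write_allele_depths_vcf",
    "read_allele_depths_vcf",
    "write_coverage_bedgraph",
    "read_coverage_bedgraph",
    "write_karyotypes_tsv",
    "read_karyotypes_tsv",
]

_CODE_TO_LABEL = {0: "0", 1: "A", 2: "B", 3: "AB", 4: "AA", 5: "BB"}
_LABEL_TO_CODE = {v: k for k, v in _CODE_TO_LABEL.items()}


def write_allele_depths_tsv(allele_depths: pd.DataFrame, path: str | Path) -> None:
    allele_depths.to_csv(path, sep="\t", index=False)


def read_allele_depths_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_allele_depths_vcf(
    allele_depths: pd.DataFrame,
    snps: pd.DataFrame,
    table: ChromosomeTable,
    path: str | Path,
    sample: str = "spore",
) -> None:
    """Minimal VCF v4.2 with per-SNP parental allele depths in the AD field.

    REF is the parent-A allele, ALT the parent-B allele; the single sample
    carries GT=./. (ploidy varies per chromosome) and AD=countA,countB.
    """
    merged = allele_depths.merge(snps, on=["chrom", "pos"], how="left")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Parental allele read depths">\n'
        )
        for name, length in zip(table.names, table.lengths_bp):
            fh.write(f"##contig=<ID={name},length={int(length)}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + sample + "\n"
        )
        for row in merged.itertuples(index=False):
            ref = getattr(row, "alleleA", "A")
            alt = getattr(row, "alleleB", "C")
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t.\t{ref}\t{alt}\t.\tPASS\t.\t"
                f"GT:AD\t./.:{int(row.countA)},{int(row.countB)}\n"
            )


def read_allele_depths_vcf(path: str | Path) -> pd.DataFrame:
    """Read a VCF with an AD field back into (chrom, pos, countA, countB)."""
    from cyvcf2 import VCF

    records = []
    for v in VCF(str(path)):
        ad = v.format("AD")[0]
        records.append((v.CHROM, v.POS, int(ad[0]), int(ad[1])))
    return pd.DataFrame(records, columns=["chrom", "pos", "countA", "countB"])


def write_coverage_bedgraph(coverage: pd.DataFrame, path: str | Path) -> None:
    """4-column bedGraph-like TSV (chrom, start, end, depth), no header."""
    coverage[["chrom", "start", "end", "depth"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_coverage_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "depth"], header=None
    )


def write_karyotypes_tsv(
    cohort: np.ndarray, table: ChromosomeTable, path: str | Path,
    samples: list[str] | None = None,
) -> None:
    """One row per spore, columns sample + chromosome names, values in
    {0, A, B, AB, AA, BB}."""
    cohort = np.atleast_2d(np.asarray(cohort))
    if samples is None:
        samples = [f"spore{i + 1}" for i in range(cohort.shape[0])]
    df = pd.DataFrame(
        [[_CODE_TO_LABEL[int(s)] for s in row] for row in cohort],
        columns=list(table.names),
    )
    df.insert(0, "sample", samples)
    df.to_csv(path, sep="\t", index=False)


def read_karyotypes_tsv(
    path: str | Path, table: ChromosomeTable
) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    samples = df["sample"].tolist()
    cohort = np.array(
        [[_LABEL_TO_CODE[df.loc[i, c]] for c in table.names] for i in df.index],
        dtype=np.uint8,
    )
    return cohort, samples
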