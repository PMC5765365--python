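"""Readers/writers for the plain-text interchange formats of the pipeline."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED_COLUMNS = ["contig", "start", "end", "gene_id"]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS)


def write_bed(spans: pd.DataFrame, path) -> None:
    spans[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def write_vcf(
    records: Iterable[tuple],
    contig_lengths: Mapping[str, int],
    sample_names: Iterable[str],
    path,
) -> None:
    """Write a minimal VCF v4.2 with GT-only genotypes.

    ``records`` yields (contig, pos 1-based, ref, alt, list of diploid
    genotype strings like "0/1").
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = "\t".join(
            ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        )
        fh.write(cols + "\t" + "\t".join(sample_names) + "\n")
        for contig, pos, ref, alt, gts in records:
            fh.write(
                f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
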