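"""Readers and writers for the on-disk formats used across the pipeline.

All genomic intervals are 0-based half-open in memory. GFF3 is 1-based
inclusive on disk and is converted here, at the boundary, and nowhere else.
"""
from __future__ import annotations

from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import gffutils

METHYLATION_COLUMNS = ["chrom", "pos", "strand", "context", "coverage", "methylated"]
EXPRESSION_COLUMNS = ["gene_id", "tissue", "replicate", "tpm"]
ANCHOR_COLUMNS = ["gene_a", "gene_b", "score"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")  # wraps at 60 columns


def read_gff3(path) -> pd.DataFrame:
    """Read gene features from a GFF3 file into a gene table.

    Returns a DataFrame with columns ``gene_id, chrom, start, end, strand``
    where ``start``/``end`` are 0-based half-open.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append((gene_id, feat.seqid, feat.start - 1, feat.end, feat.strand))
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    return genes.sort_values(["chrom", "start", "gene_id"]).reset_index(drop=True)


def write_gff3(genes: pd.DataFrame, path, source: str = "allelomethyl") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.sort_values(["chrom", "start", "gene_id"]).itertuples():
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def _read_tsv(path, columns, dtypes) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df[columns].astype(dtypes)


def read_methylation(path) -> pd.DataFrame:
    df = _read_tsv(path, METHYLATION_COLUMNS,
                   {"pos": "int64", "coverage": "int64", "methylated": "int64"})
    bad = df.index[(df.methylated < 0) | (df.methylated > df.coverage)]
    if len(bad):
        raise ValueError(f"{path}: methylated > coverage at line {bad[0] + 2}")
    return df


def write_methylation(calls: pd.DataFrame, path) -> None:
    calls[METHYLATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    return _read_tsv(path, EXPRESSION_COLUMNS, {"tpm": "float64"})


def write_expression(expr: pd.DataFrame, path) -> None:
    expr[EXPRESSION_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_anchors(path) -> pd.DataFrame:
    return _read_tsv(path, ANCHOR_COLUMNS, {"score": "float64"})


def write_anchors(anchors: pd.DataFrame, path) -> None:
    anchors[ANCHOR_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.2f")
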