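"""File-format helpers: FASTA/FASTQ via Biopython, tables via pandas."""

from __future__ import annotations

from collections.abc import Iterable
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .pangenome import GeneSequence
from .qc import QualityRead


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def read_fastq(path: str | Path) -> list[QualityRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            QualityRead(
                rec.id,
                str(rec.seq).upper(),
                np.array(rec.letter_annotations["phred_quality"], dtype=np.int16),
            )
        )
    return out


def write_fastq(reads: Iterable[QualityRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = "".join(chr(int(q) + 33) for q in read.qualities)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


def read_gene_map(path: str | Path) -> pd.DataFrame:
    """TSV with columns gene_id, species_id, strain_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "species_id", "strain_id"} - set(df.columns)
    if missing:
        raise ValueError(f"gene map is missing columns: {sorted(missing)}")
    return df


def genes_from_fasta_and_map(
    fasta_path: str | Path, map_path: str | Path
) -> list[GeneSequence]:
    """Combine a multi-FASTA of genes with a (gene_id, species_id, strain_id)
    mapping table into GeneSequence records."""
    seqs = dict(read_fasta(fasta_path))
    gmap = read_gene_map(map_path)
    genes = []
    for row in gmap.itertuples(index=False):
        if row.gene_id not in seqs:
            raise ValueError(f"gene {row.gene_id!r} in map but not in FASTA")
        genes.append(
            GeneSequence(row.gene_id, row.species_id, row.strain_id, seqs[row.gene_id])
        )
    return genes


def read_abundance_table(path: str | Path) -> pd.DataFrame:
    """Feature-by-sample count table (first column = feature labels)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("abundance table has negative entries")
    if df.index.has_duplicates:
        raise ValueError("abundance table has duplicate feature labels")
    return df
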