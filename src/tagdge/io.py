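"""Plain-text readers and writers: FASTA, '#'-headed TSV, tag streams.

Everything is diff-able text.  TSV files start with a single '#'-prefixed
header line declaring the column schema.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import TAG_LEN, LibraryId, RawTagLibrary, ReferenceGene, TruthTable


def write_fasta(genes: list[ReferenceGene], path: str | Path) -> None:
    records = [SeqRecord(Seq(g.sequence), id=g.gene_id, description="")
               for g in genes]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[ReferenceGene]:
    return [ReferenceGene(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def write_tsv(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    """TSV with a '#'-prefixed header line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, float_format=float_format)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: expected a '#'-prefixed header line")
        names = header[1:].rstrip("\n").split("\t")
        return pd.read_csv(fh, sep="\t", names=names, **kwargs)


def write_tags(library: RawTagLibrary, path: str | Path, fastq: bool = False) -> None:
    """One 21-nt tag per line, or FASTQ with dummy qualities."""
    path = Path(path)
    tags = library.tags.astype(str)
    with open(path, "w") as fh:
        if fastq:
            qual = "I" * TAG_LEN
            for i, t in enumerate(tags):
                fh.write(f"@{library.library_id}_{i + 1}\n{t}\n+\n{qual}\n")
        else:
            fh.write("\n".join(tags))
            if len(tags):
                fh.write("\n")


def read_tags(path: str | Path, library_id: LibraryId | str | None = None) -> RawTagLibrary:
    """Read a tag-per-line text file or a FASTQ file (auto-detected)."""
    path = Path(path)
    if library_id is None:
        try:
            library_id = LibraryId.parse(path.stem.split(".")[0])
        except ValueError:
            library_id = LibraryId("WT", 120)
    elif isinstance(library_id, str):
        library_id = LibraryId.parse(library_id)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("@"):
        tags = [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]
    else:
        with open(path) as fh:
            tags = [line.strip() for line in fh if line.strip()]
    return RawTagLibrary(library_id=library_id,
                         tags=np.asarray(tags, dtype=f"S{TAG_LEN}"))


def read_counted_tsv(path: str | Path, library_id: LibraryId | str) -> pd.DataFrame:
    """Pre-counted (tag, count) TSV as accepted by the QC stage."""
    df = read_tsv(path)
    if not {"tag", "count"} <= set(df.columns):
        raise ValueError("counted TSV needs 'tag' and 'count' columns")
    if "tpm" not in df.columns:
        df["tpm"] = np.nan
    return df


def write_truth(truth: TruthTable, path: str | Path) -> None:
    df = truth.genes.copy()
    df.attrs = {}
    write_tsv(df, path, float_format="%.10g")


def read_truth(path: str | Path, planted_terms: set[str] | None = None) -> TruthTable:
    df = read_tsv(path)
    df["shallow"] = df["shallow"].astype(bool)
    return TruthTable(genes=df, planted_terms=planted_terms or set())
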