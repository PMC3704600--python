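"""Readers and writers for the plain-text formats used throughout the pipeline.

FASTA/FASTQ handling goes through Biopython's parsers; GFF3 and BED are
written as plain tab-separated text and read back with pandas, which is all
the simple single-feature annotations used here require.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

GFF_COLUMNS = [
    "seqid",
    "source",
    "type",
    "start",
    "end",
    "score",
    "strand",
    "phase",
    "attributes",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping.

    Only the first whitespace-delimited token of each header is used as the
    identifier, which tolerates miRBase-style ``>gma-miR156a MIMAT...``
    headers.
    """
    out: dict[str, str] = {}
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            out[header.split()[0]] = seq.upper()
    return out


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) triples from a FASTQ file."""
    with open(path) as fh:
        yield from FastqGeneralIterator(fh)


def read_gff(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=GFF_COLUMNS)
    return df


def write_gff(path: str | os.PathLike, rows: Iterable[dict]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in rows:
            fh.write(
                "\t".join(
                    str(r.get(c, ".")) for c in GFF_COLUMNS
                )
                + "\n"
            )


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df.columns = BED_COLUMNS[: df.shape[1]]
    return df


def write_bed(path: str | os.PathLike, rows: Iterable[dict]) -> None:
    """Write BED6; input rows carry 1-based inclusive start/end which are
    converted to BED's 0-based half-open convention."""
    with open(path, "w") as fh:
        for r in rows:
            fh.write(
                f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\t"
                f"{r.get('name', '.')}\t{r.get('score', 0)}\t{r.get('strand', '+')}\n"
            )
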