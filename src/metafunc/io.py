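"""Readers and writers for the standard formats the pipeline consumes.

FASTQ goes through Biopython (gzip-transparent), SAM through pysam, and
BLAST tabular reports (the 12-column ``-outfmt 6`` dialect) through pandas.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .readqc import ReadRecord

BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path, phred_offset: int = 33) -> Iterator[ReadRecord]:
    """Yield :class:`ReadRecord` from a (possibly gzipped) FASTQ file."""
    fmt = "fastq" if phred_offset == 33 else "fastq-illumina"
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, fmt):
            yield ReadRecord(
                read_id=rec.id,
                bases=str(rec.seq),
                quals=tuple(rec.letter_annotations["phred_quality"]),
            )


def write_fastq(reads: Iterable[ReadRecord], path: str | Path, phred_offset: int = 33) -> int:
    """Write reads to FASTQ; returns the number of records written."""
    fmt = "fastq" if phred_offset == 33 else "fastq-illumina"
    n = 0
    with _open_text(path, "wt") as handle:
        for read in reads:
            rec = SeqRecord(Seq(read.bases), id=read.read_id, description="")
            rec.letter_annotations["phred_quality"] = list(read.quals)
            SeqIO.write(rec, handle, fmt)
            n += 1
    return n


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` dict."""
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for name, seq in seqs.items():
            handle.write(f">{name}\n{seq}\n")


def read_blast_tabular(path: str | Path) -> pd.DataFrame:
    """Read a 12-column BLAST tabular report into a DataFrame."""
    df = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#")
    return df.astype({"pident": float, "length": int, "evalue": float, "bitscore": float})


def write_blast_tabular(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=BLAST6_COLUMNS)


def read_sam_mapped_ids(path: str | Path) -> set[str]:
    """Return query names with a primary mapped record in a SAM file."""
    mapped: set[str] = set()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            mapped.add(rec.query_name)
    return mapped


def write_sam(
    mapped_ids: Iterable[str],
    references: dict[str, int],
    path: str | Path,
    target: dict[str, str] | None = None,
) -> None:
    """Write a minimal single-end SAM file mapping each read to a reference.

    ``target`` maps read id -> reference name; when absent, reads map to the
    first reference. Alignments are written as perfect-match placeholders —
    downstream consumers only look at mapped/unmapped state.
    """
    refs = list(references)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": name, "LN": length} for name, length in references.items()],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for qname in mapped_ids:
            ref = target.get(qname, refs[0]) if target else refs[0]
            a = pysam.AlignedSegment(header)
            a.query_name = qname
            a.flag = 0
            a.reference_id = refs.index(ref)
            a.reference_start = 0
            a.mapping_quality = 60
            a.cigarstring = "50M"
            a.query_sequence = "A" * 50
            sam.write(a)


def write_tsv(df: pd.DataFrame, path: str | Path, provenance: str | None = None) -> None:
    """Write a TSV, optionally preceded by ``#``-prefixed provenance lines."""
    with _open_text(path, "wt") as handle:
        if provenance:
            for line in provenance.splitlines():
                handle.write(f"# {line}\n")
        df.to_csv(handle, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
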