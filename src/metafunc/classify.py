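"""Hierarchical read classification from alignment evidence.

In a community without reference genomes, each post-QC read is assigned to
exactly one category by a fixed precedence ladder over heterogeneous
evidence streams:

    adaptor > rRNA > mouse (transcript, then genome) > bacterial nucleotide
    > bacterial peptide > unassigned

rRNA calls come from BLAST hits against an rRNA reference with a strict
bit-score cutoff (> 50 bits). Host (mouse) and bacterial-nucleotide calls
come from SAM mapping records: a read counts as mapped when it has a
primary, non-unmapped record. Bacterial-peptide calls come from translated
(BLASTX-style) hits against a protein database; by default only
high-quality hits qualify — at least 85% identity over more than 65% of the
read length — since weaker translated matches of ~25-residue peptides carry
little information.

The ladder makes categories disjoint, so per-sample yield accounting is a
partition of the input reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import round_half_up

logger = logging.getLogger(__name__)

RRNA_MIN_BITSCORE = 50.0  # strict: a 50.0-bit hit is NOT rRNA
HQ_MIN_IDENTITY = 85.0
HQ_MIN_COVERAGE = 0.65


class SubjectDB(str, Enum):
    RRNA = "rrna"
    MOUSE_TX = "mouse_tx"
    MOUSE_GENOME = "mouse_genome"
    BACT_GENOME = "bact_genome"
    PROTEIN = "protein"
    COG = "cog"
    ENZYME = "enzyme"
    ECOLI = "ecoli"


class Category(str, Enum):
    ADAPTOR = "adaptor"
    RRNA = "rrna"
    MOUSE = "mouse"
    BACTERIAL_NT = "bacterial_nt"
    BACTERIAL_PEPTIDE = "bacterial_peptide"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class HitRecord:
    """One alignment line linking a query to a subject sequence."""

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    bitscore: float
    evalue: float
    subject_db: SubjectDB

    def __post_init__(self) -> None:
        if not 0 <= self.percent_identity <= 100:
            raise ValueError(f"percent_identity out of range: {self.percent_identity}")
        if self.align_length < 1:
            raise ValueError("align_length must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass(frozen=True)
class ReadClass:
    read_id: str
    category: Category
    best_subject: str | None = None
    mouse_ref: str | None = None  # "transcript" or "genome" when category == MOUSE


def hits_from_frame(df: pd.DataFrame, subject_db: SubjectDB) -> list[HitRecord]:
    """Convert a BLAST tabular DataFrame into typed hit records."""
    return [
        HitRecord(
            query_id=str(row.qseqid),
            subject_id=str(row.sseqid),
            percent_identity=float(row.pident),
            align_length=int(row.length),
            bitscore=float(row.bitscore),
            evalue=float(row.evalue),
            subject_db=subject_db,
        )
        for row in df.itertuples(index=False)
    ]


def is_rrna(hit: HitRecord) -> bool:
    """rRNA filter: the hit marks a ribosomal read iff bit score > 50 (strict)."""
    if hit.subject_db is not SubjectDB.RRNA:
        raise ValueError(f"is_rrna expects an rRNA-database hit, got {hit.subject_db}")
    return hit.bitscore > RRNA_MIN_BITSCORE


def is_hq_peptide_hit(hit: HitRecord, read_len_nt: int) -> bool:
    """High-quality translated hit: ≥85% identity over >65% of the read.

    ``align_length`` is in amino-acid residues for translated searches, so
    coverage is ``3 * align_length / read_len_nt``.
    """
    if hit.subject_db is not SubjectDB.PROTEIN:
        raise ValueError(f"is_hq_peptide_hit expects a protein-database hit, got {hit.subject_db}")
    if read_len_nt <= 0:
        raise ValueError("read_len_nt must be positive")
    coverage = 3.0 * hit.align_length / read_len_nt
    return hit.percent_identity >= HQ_MIN_IDENTITY and coverage > HQ_MIN_COVERAGE


def best_hit(hits: Iterable[HitRecord]) -> HitRecord | None:
    """Deterministic best hit: highest bit score, then lowest E-value, then
    lexicographically smallest subject id."""
    return min(
        hits,
        key=lambda h: (-h.bitscore, h.evalue, h.subject_id),
        default=None,
    )


def _group_hits(hits: Iterable[HitRecord], known: set[str]) -> dict[str, list[HitRecord]]:
    grouped: dict[str, list[HitRecord]] = {}
    orphans = 0
    for hit in hits:
        if hit.query_id not in known:
            orphans += 1
            continue
        grouped.setdefault(hit.query_id, []).append(hit)
    if orphans:
        logger.warning("ignored %d hits whose query_id is not in the read set", orphans)
    return grouped


def classify_reads(
    read_lengths: Mapping[str, int],
    adaptor_ids: set[str] = frozenset(),
    rrna_hits: Iterable[HitRecord] = (),
    mouse_tx_mapped: set[str] = frozenset(),
    mouse_genome_mapped: set[str] = frozenset(),
    bact_nt_mapped: set[str] = frozenset(),
    peptide_hits: Iterable[HitRecord] = (),
    hq_peptide_only: bool = True,
) -> list[ReadClass]:
    """Assign every read to exactly one category by the precedence ladder.

    ``read_lengths`` defines the read universe (post-QC lengths in nt);
    hits naming unknown reads are counted and ignored with a warning.
    """
    known = set(read_lengths)
    rrna_by_read = _group_hits(rrna_hits, known)
    pep_by_read = _group_hits(peptide_hits, known)

    classes: list[ReadClass] = []
    for read_id in read_lengths:
        if read_id in adaptor_ids:
            classes.append(ReadClass(read_id, Category.ADAPTOR))
            continue
        rhits = [h for h in rrna_by_read.get(read_id, ()) if is_rrna(h)]
        if rhits:
            classes.append(ReadClass(read_id, Category.RRNA, best_hit(rhits).subject_id))
            continue
        if read_id in mouse_tx_mapped:
            classes.append(ReadClass(read_id, Category.MOUSE, mouse_ref="transcript"))
            continue
        if read_id in mouse_genome_mapped:
            classes.append(ReadClass(read_id, Category.MOUSE, mouse_ref="genome"))
            continue
        if read_id in bact_nt_mapped:
            classes.append(ReadClass(read_id, Category.BACTERIAL_NT))
            continue
        phits = pep_by_read.get(read_id, ())
        if hq_peptide_only:
            phits = [h for h in phits if is_hq_peptide_hit(h, read_lengths[read_id])]
        top = best_hit(phits)
        if top is not None:
            classes.append(ReadClass(read_id, Category.BACTERIAL_PEPTIDE, top.subject_id))
        else:
            classes.append(ReadClass(read_id, Category.UNASSIGNED))
    return classes


YIELD_COUNT_COLUMNS = [
    "total",
    "adaptor",
    "rrna",
    "mouse_tx",
    "mouse_genome",
    "bact_nt",
    "bact_peptide",
]


def count_classes(classes: Sequence[ReadClass]) -> dict[str, int]:
    """Collapse per-read classes into the yield-table count columns."""
    counts = dict.fromkeys(YIELD_COUNT_COLUMNS, 0)
    counts["total"] = len(classes)
    for c in classes:
        if c.category is Category.ADAPTOR:
            counts["adaptor"] += 1
        elif c.category is Category.RRNA:
            counts["rrna"] += 1
        elif c.category is Category.MOUSE:
            key = "mouse_tx" if c.mouse_ref == "transcript" else "mouse_genome"
            counts[key] += 1
        elif c.category is Category.BACTERIAL_NT:
            counts["bact_nt"] += 1
        elif c.category is Category.BACTERIAL_PEPTIDE:
            counts["bact_peptide"] += 1
    return counts


def yield_table(counts_per_sample: pd.DataFrame) -> pd.DataFrame:
    """Derive per-sample yield percentages from category counts.

    Input: one row per sample (index = sample id) with the columns in
    :data:`YIELD_COUNT_COLUMNS`. Percentages are of non-adaptor reads:

    - ``pct_mouse``     = 100 * (mouse_tx + mouse_genome) / (total - adaptor)
    - ``pct_rrna``      = 100 * rrna / (total - adaptor)
    - ``pct_bacterial`` = 100 * bact_peptide / (total - adaptor)

    Percentages are rounded half-up to one decimal place. Samples whose
    reads are all adaptor get null percentages.
    """
    df = counts_per_sample.copy()
    denom = (df["total"] - df["adaptor"]).astype(float)
    bad = denom <= 0
    if bad.any():
        logger.warning("samples with no non-adaptor reads: %s", list(df.index[bad]))
    denom[bad] = float("nan")
    df["pct_mouse"] = (100.0 * (df["mouse_tx"] + df["mouse_genome"]) / denom).map(
        lambda x: x if pd.isna(x) else round_half_up(x, 1)
    )
    df["pct_rrna"] = (100.0 * df["rrna"] / denom).map(
        lambda x: x if pd.isna(x) else round_half_up(x, 1)
    )
    df["pct_bacterial"] = (100.0 * df["bact_peptide"] / denom).map(
        lambda x: x if pd.isna(x) else round_half_up(x, 1)
    )
    return df
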