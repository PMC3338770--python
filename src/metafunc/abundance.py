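"""RPKM normalization and aggregation into functional classes.

Transcript abundance is expressed as Reads Per Kilobase of transcript per
Million mapped reads:

    RPKM = 1e9 * C / (L * N)

where C is the number of reads mapped to the transcript in a sample, L the
transcript length in nt, and N the total number of reads mapped to
bacterial transcripts in that sample. N is fixed per sample at
classification time; RPKM is comparable across samples only through this
normalization.

Class-level abundance is the sum of member-transcript RPKMs. A transcript
carrying k labels (e.g. a multi-letter COG assignment) contributes rpkm/k
to each label, so aggregation conserves total RPKM mass for any label map
covering all transcripts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import format_percent
from .classify import HitRecord, best_hit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampleContext:
    """Per-sample normalization context: N = reads mapped to bacterial transcripts."""

    sample_id: str
    N: int

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1 to compute abundances")


def rpkm(C: int, L: int, N: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if L < 1:
        raise ValueError("transcript length L must be >= 1")
    if N < 1:
        raise ValueError("mapped-read total N must be >= 1")
    if C < 0:
        raise ValueError("mapped-read count C must be >= 0")
    return 1e9 * C / (L * N)


def transcript_abundances(
    counts: Mapping[str, int],
    lengths: Mapping[str, int],
    N: int | None = None,
) -> pd.DataFrame:
    """Per-transcript RPKM table with columns C, L, rpkm.

    ``N`` defaults to the sum of mapped counts (the usual definition);
    passing it explicitly supports contexts where N was fixed upstream.
    """
    if N is None:
        N = sum(counts.values())
    rows = []
    for tid, c in counts.items():
        if tid not in lengths:
            raise KeyError(f"no length for transcript {tid!r}")
        rows.append((tid, c, lengths[tid], rpkm(c, lengths[tid], N)))
    return pd.DataFrame(rows, columns=["transcript_id", "C", "L", "rpkm"]).set_index("transcript_id")


def aggregate_by_class(
    abundances: pd.DataFrame | Mapping[str, float],
    class_map: Mapping[str, Sequence[str]],
) -> dict[str, float]:
    """Sum transcript RPKM into class labels with the equal-split rule.

    ``abundances`` is either the frame from :func:`transcript_abundances`
    or a plain ``{transcript_id: rpkm}`` mapping. A transcript with k
    labels contributes rpkm/k to each, so total mass is conserved.
    Transcripts in the map but absent from the abundance table are skipped
    with a warning; labels with no members are absent from the result.
    """
    if isinstance(abundances, pd.DataFrame):
        values = abundances["rpkm"].to_dict()
    else:
        values = dict(abundances)
    out: dict[str, float] = {}
    missing = 0
    for tid, labels in class_map.items():
        if tid not in values:
            missing += 1
            continue
        labels = list(labels)
        if not labels:
            continue
        share = values[tid] / len(labels)
        for label in labels:
            out[label] = out.get(label, 0.0) + share
    if missing:
        logger.warning("class map names %d transcripts with no abundance; skipped", missing)
    return out


def rank_classes(values: Mapping[str, float]) -> dict[str, int]:
    """Dense 1..n ranking, largest value first; ties broken lexicographically."""
    if not values:
        raise ValueError("cannot rank an empty class table")
    ordered = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    return {label: i + 1 for i, (label, _) in enumerate(ordered)}


def taxon_profile_from_counts(
    counts: Mapping[str, int],
    listed_taxa: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Taxon read counts and percents of the classified total.

    Taxa outside ``listed_taxa`` (when given) are pooled under ``Other``.
    Percents follow the printed-table convention: half-up to 1 decimal
    place, 2 decimals below 1%.
    """
    pooled: Counter[str] = Counter()
    for taxon, n in counts.items():
        if listed_taxa is not None and taxon not in listed_taxa:
            pooled["Other"] += n
        else:
            pooled[taxon] += n
    total = sum(pooled.values())
    if total == 0:
        raise ValueError("no classified reads to profile")
    rows = [
        (taxon, n, format_percent(100.0 * n / total))
        for taxon, n in sorted(pooled.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["taxon", "reads", "percent"]).set_index("taxon")


def taxon_profile(
    hits: Iterable[HitRecord],
    taxonomy: Mapping[str, str],
    listed_taxa: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Profile taxa from classified hits: best hit per query, subject -> taxon.

    Subjects missing from the taxonomy are pooled under ``Other`` and
    counted with a warning.
    """
    by_query: dict[str, list[HitRecord]] = {}
    for hit in hits:
        by_query.setdefault(hit.query_id, []).append(hit)
    counts: Counter[str] = Counter()
    unknown = 0
    for qhits in by_query.values():
        top = best_hit(qhits)
        taxon = taxonomy.get(top.subject_id)
        if taxon is None:
            unknown += 1
            counts["Other"] += 1
        else:
            counts[taxon] += 1
    if unknown:
        logger.warning("%d best hits had subjects missing from the taxonomy", unknown)
    return taxon_profile_from_counts(counts, listed_taxa)
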