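"""COG-category and EC-number assignment and enrichment testing.

Transcripts are assigned to broad functional categories (COG single-letter
classes) and to enzyme activities (EC numbers) by their best hit against
annotated reference sets, each with its own E-value cap: a permissive
1e-3 for COG, and a stricter 1e-10 for EC, since misassigned enzyme
activities propagate into the metabolic network.

RPKM-weighted category frequencies are compared against the background
distribution of categories in the reference database with a one-sample
proportion Z-score per category,

    z = (p_s - p_b) / sqrt(p_b (1 - p_b) / n),

where p_s is the sample frequency, p_b the background frequency, and n
the number of reads underlying the classified transcripts (a sampling
variance needs a count, so n is read-based even though the frequencies
are RPKM-weighted). |z| > 2 is called significant; no multiplicity
correction is applied.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

from .classify import HitRecord, best_hit

logger = logging.getLogger(__name__)

COG_MAX_EVALUE = 1e-3
EC_MAX_EVALUE = 1e-10
UNCHARACTERIZED = "Uncharacterized"
Z_SIGNIFICANT = 2.0

_EC_FIELD = r"(\d+|-)"
_EC_RE = re.compile(rf"^{_EC_FIELD}\.{_EC_FIELD}\.{_EC_FIELD}\.{_EC_FIELD}$")


@dataclass(frozen=True)
class CategoryDistribution:
    """Relative category frequencies plus the read count behind them."""

    freqs: Mapping[str, float]
    n_effective: int

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if self.freqs and abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies must sum to 1, got {total}")


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    p_sample: float
    p_background: float
    z: float

    @property
    def significant(self) -> bool:
        return abs(self.z) > Z_SIGNIFICANT


def normalize_ec(ec: str) -> str:
    """Validate/normalize an EC string to four dot-separated fields.

    Truncated strings like ``3.2.1`` are padded with trailing dashes
    (``3.2.1.-``) with a warning; anything else malformed raises.
    """
    ec = ec.strip()
    parts = ec.split(".")
    if 1 <= len(parts) < 4 and all(p.isdigit() or p == "-" for p in parts):
        padded = ".".join(parts + ["-"] * (4 - len(parts)))
        logger.warning("EC %r padded to %r", ec, padded)
        ec = padded
    if not _EC_RE.match(ec):
        raise ValueError(f"malformed EC number: {ec!r}")
    return ec


def _assign_best(
    hits: Iterable[HitRecord],
    subject_annotation: Mapping[str, str],
    max_evalue: float,
) -> dict[str, str]:
    """transcript -> annotation of its best hit under the E-value cap."""
    by_query: dict[str, list[HitRecord]] = {}
    for hit in hits:
        if hit.evalue < max_evalue and hit.subject_id in subject_annotation:
            by_query.setdefault(hit.query_id, []).append(hit)
    return {
        q: subject_annotation[best_hit(qhits).subject_id] for q, qhits in by_query.items()
    }


def assign_cog(
    hits: Iterable[HitRecord],
    subject_cogs: Mapping[str, str],
    max_evalue: float = COG_MAX_EVALUE,
) -> dict[str, frozenset[str]]:
    """transcript -> set of COG letters from its best qualifying hit.

    Multi-category subjects (e.g. "EG") pass through as letter sets; the
    abundance module splits mass between them. Transcripts with no
    qualifying hit are absent (treated as Uncharacterized downstream).
    """
    raw = _assign_best(hits, subject_cogs, max_evalue)
    return {t: frozenset(letters) for t, letters in raw.items() if letters}


def assign_ec(
    hits: Iterable[HitRecord],
    subject_ecs: Mapping[str, str],
    max_evalue: float = EC_MAX_EVALUE,
) -> dict[str, frozenset[str]]:
    """transcript -> set of EC numbers from its best qualifying hit."""
    normalized = {s: normalize_ec(e) for s, e in subject_ecs.items()}
    raw = _assign_best(hits, normalized, max_evalue)
    return {t: frozenset([ec]) for t, ec in raw.items()}


def category_distribution(
    cog_map: Mapping[str, frozenset[str]],
    abundances,
    include_uncharacterized: bool = True,
) -> CategoryDistribution:
    """RPKM-weighted COG category frequencies.

    ``abundances`` is the frame from ``abundance.transcript_abundances``
    (columns C and rpkm). Transcripts absent from ``cog_map`` contribute
    their mass to ``Uncharacterized`` when ``include_uncharacterized``.
    n_effective counts the reads underlying the transcripts in the
    distribution.
    """
    from .abundance import aggregate_by_class

    full_map: dict[str, list[str]] = {t: sorted(s) for t, s in cog_map.items()}
    transcripts = set(full_map)
    if include_uncharacterized:
        for tid in abundances.index:
            if tid not in full_map:
                full_map[tid] = [UNCHARACTERIZED]
        transcripts = set(full_map)
    mass = aggregate_by_class(abundances, full_map)
    total = sum(mass.values())
    if total == 0:
        raise ValueError("no RPKM mass in any category")
    n_eff = int(abundances.loc[abundances.index.isin(transcripts), "C"].sum())
    return CategoryDistribution({k: v / total for k, v in mass.items()}, n_eff)


def enrichment_z(
    sample: CategoryDistribution,
    background: CategoryDistribution,
    exclude: Iterable[str] = (UNCHARACTERIZED,),
) -> list[EnrichmentResult]:
    """Per-category one-sample proportion Z against the background.

    Categories with degenerate background frequency (0 or 1) are skipped
    with a warning; ``Uncharacterized`` is excluded by default (it appears
    in distributions but is not a functional category).
    """
    excluded = set(exclude)
    results = []
    for cat in sorted(set(background.freqs) | set(sample.freqs)):
        if cat in excluded:
            continue
        p_b = background.freqs.get(cat, 0.0)
        if p_b <= 0.0 or p_b >= 1.0:
            logger.warning("category %s has degenerate background %.3f; skipped", cat, p_b)
            continue
        p_s = sample.freqs.get(cat, 0.0)
        se = math.sqrt(p_b * (1.0 - p_b) / sample.n_effective)
        results.append(EnrichmentResult(cat, p_s, p_b, (p_s - p_b) / se))
    return results
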