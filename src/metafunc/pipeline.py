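"""End-to-end orchestration: QC -> classify -> abundance -> families -> profiles.

Ties the stage modules together for a single sample, either in memory
(:func:`analyze_sample`, used on synthetic communities) or through files
(the CLI's ``run-all``). Each stage consumes only the standard containers
the stage modules define, so this module contains no science of its own.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from . import abundance, classify, genefam, readqc
from .classify import Category, SubjectDB, hits_from_frame
from .simulate import Evidence, SyntheticCommunity


@dataclass
class SampleAnalysis:
    qc: readqc.QCResult
    classes: list[classify.ReadClass]
    counts: dict[str, int]
    yields: pd.DataFrame
    abundances: pd.DataFrame  # per-transcript C, L, rpkm
    families: list[genefam.GeneFamily]
    taxon_profile: pd.DataFrame


def analyze_sample(
    community: SyntheticCommunity,
    evidence: Evidence,
    params: readqc.QCParams = readqc.QCParams(),
    mcl_params: genefam.MCLParams = genefam.MCLParams(),
    sample_id: str = "sample",
) -> SampleAnalysis:
    """Run the full ladder on one synthetic sample, in memory."""
    qc = readqc.run_qc(community.reads, community.adaptors, params)
    adaptor_ids = {o.read_id for o in qc.outcomes if o.fate is readqc.Fate.BINNED_ADAPTOR}
    # classification universe: surviving reads (trimmed lengths) + adaptor bin;
    # reads discarded as too short never reach the classifier
    read_lengths = {r.read_id: len(r) for r in qc.kept}
    read_lengths.update(dict.fromkeys(adaptor_ids, community.spec.read_length))

    classes = classify.classify_reads(
        read_lengths,
        adaptor_ids=adaptor_ids,
        rrna_hits=hits_from_frame(evidence.rrna_hits, SubjectDB.RRNA),
        mouse_tx_mapped=evidence.mouse_tx_mapped,
        mouse_genome_mapped=evidence.mouse_genome_mapped,
        bact_nt_mapped=evidence.bact_nt_mapped,
        peptide_hits=hits_from_frame(evidence.peptide_hits, SubjectDB.PROTEIN),
    )
    counts = classify.count_classes(classes)
    yields = classify.yield_table(pd.DataFrame([counts], index=[sample_id]))

    # transcript counts from best peptide hits of peptide-classified reads
    tx_counts: Counter[str] = Counter(
        c.best_subject for c in classes if c.category is Category.BACTERIAL_PEPTIDE
    )
    lengths = dict(
        zip(community.transcripts["transcript_id"], community.transcripts["length"])
    )
    abund = abundance.transcript_abundances(dict(tx_counts), lengths)

    graph = genefam.build_similarity_graph(
        hits_from_frame(evidence.allvall_hits, SubjectDB.PROTEIN)
    )
    # transcripts never hit in the all-vs-all search are singleton families
    for tid in community.transcripts["transcript_id"]:
        graph.add_node(tid)
    families = genefam.mcl(graph, mcl_params)

    taxonomy = dict(evidence.rrna_taxonomy)
    rrna_hit_records = hits_from_frame(evidence.rrna_hits, SubjectDB.RRNA)
    rrna_read_ids = {c.read_id for c in classes if c.category is Category.RRNA}
    profile = abundance.taxon_profile(
        (h for h in rrna_hit_records if h.query_id in rrna_read_ids), taxonomy
    )
    return SampleAnalysis(qc, classes, counts, yields, abund, families, profile)
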