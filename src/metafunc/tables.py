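"""Worked-example fixtures: published per-sample count tables.

Twelve cecal/colon RNA preparations from gnotobiotic mice colonized with
the eight-species Altered Schaedler Flora were sequenced on one Illumina
lane; the published study reports per-sample read yields by category
(sequence yield table) and the family-level distribution of small-subunit
rRNA reads (taxon table). The raw reads live in the SRA (accession
SRA051354) and are not needed here: these count tables are the inputs for
the yield-accounting and taxon-profile worked examples.
"""

from __future__ import annotations

import pandas as pd

from .classify import YIELD_COUNT_COLUMNS

# sample, total, adaptor, rrna, mouse_tx, mouse_genome, bact_nt, bact_peptide
_TABLE1 = [
    ("NOD501CecQN", 1_343_095, 361_868, 907_767, 742, 1_252, 5_505, 17_701),
    ("NOD501CecQY", 2_071_165, 893_317, 458_168, 14_562, 22_322, 31_722, 305_991),
    ("NOD501ColQN", 1_305_960, 25_203, 1_240_577, 761, 1_679, 3_351, 11_598),
    ("NOD502CecQN", 2_065_733, 458_401, 1_477_991, 1_554, 3_211, 11_074, 32_223),
    ("NOD502CecQY", 1_409_494, 688_903, 514_693, 5_156, 5_860, 11_649, 61_766),
    ("NOD502ColQN", 1_090_373, 63_823, 888_879, 16_530, 40_698, 5_603, 23_376),
    ("NOD503CecMN", 2_073_136, 360_711, 726_392, 70_744, 191_760, 36_855, 288_111),
    ("NOD503CecQN", 1_566_243, 244_192, 1_227_864, 890, 2_449, 8_065, 27_483),
    ("NOD504CecMN", 2_562_571, 371_299, 653_110, 240_133, 413_699, 47_167, 188_358),
    ("NOD504CecQN", 1_918_268, 324_513, 1_453_905, 2_286, 6_889, 12_471, 29_393),
    ("NOD504CecQY", 2_626_735, 1_012_199, 1_152_379, 16_372, 14_597, 27_756, 130_581),
    ("NOD504ColQN", 1_647_255, 241_169, 836_427, 37_329, 129_217, 19_435, 117_819),
]

# family-level small-subunit rRNA classification, pooled over all samples
_TABLE2 = [
    ("Microbacteriaceae", "Actinobacteria", 5_620),
    ("Bacteroidaceae", "Bacteroidetes", 994_924),
    ("Porphyromonadaceae", "Bacteroidetes", 485_948),
    ("Flavobacteriaceae", "Bacteroidetes", 16_570),
    ("Deferribacteraceae", "Deferribacteres", 1_454),
    ("Clostridiaceae", "Firmicutes", 415_630),
    ("Lachnospiraceae", "Firmicutes", 434_676),
    ("Ruminococcaceae", "Firmicutes", 3_055),
    ("Veillonellaceae", "Firmicutes", 43_627),
    ("Lactobacillaceae", "Firmicutes", 37_903),
    ("Spirochaetaceae", "Spirochaetes", 2_764),
    ("Other", "", 31_312),
]

TABLE2_TOTAL_READS = 2_473_483


def table1_fixture() -> pd.DataFrame:
    """Published per-sample read-category counts, one row per sample.

    Columns match :data:`metafunc.classify.YIELD_COUNT_COLUMNS`, ready for
    :func:`metafunc.classify.yield_table`.
    """
    df = pd.DataFrame(_TABLE1, columns=["sample_id"] + YIELD_COUNT_COLUMNS)
    return df.set_index("sample_id")


def table2_fixture() -> dict[str, int]:
    """Published pooled family-level rRNA read counts (taxon -> reads)."""
    return {taxon: reads for taxon, _, reads in _TABLE2}


def table2_phyla() -> dict[str, str]:
    """Family -> phylum lookup for the taxon table."""
    return {taxon: phylum for taxon, phylum, _ in _TABLE2 if phylum}
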