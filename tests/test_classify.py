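"""Classification ladder, threshold gates, and yield accounting."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metafunc.classify import (
    Category,
    HitRecord,
    ReadClass,
    SubjectDB,
    best_hit,
    classify_reads,
    count_classes,
    is_hq_peptide_hit,
    is_rrna,
    yield_table,
)


def _hit(db, query="r1", subject="s1", bits=100.0, evalue=1e-20, pident=95.0, length=20):
    return HitRecord(query, subject, pident, length, bits, evalue, db)


class TestRrnaGate:
    @pytest.mark.parametrize("bits, expected", [(51.0, True), (50.0, False), (0.1, False), (50.0001, True)])
    def test_strict_bitscore_threshold(self, bits, expected):
        assert is_rrna(_hit(SubjectDB.RRNA, bits=bits)) is expected

    def test_wrong_database_is_a_contract_violation(self):
        with pytest.raises(ValueError):
            is_rrna(_hit(SubjectDB.PROTEIN))


class TestHqPeptideGate:
    @pytest.mark.parametrize(
        "pident, aa_len, read_len, expected",
        [
            (85.0, 17, 76, True),   # 51/76 = 0.671 > 0.65, identity at the boundary
            (84.9, 25, 76, False),  # identity gate
            (100.0, 16, 76, False), # 48/76 = 0.632: coverage gate
        ],
    )
    def test_identity_and_coverage_gates(self, pident, aa_len, read_len, expected):
        hit = _hit(SubjectDB.PROTEIN, pident=pident, length=aa_len)
        assert is_hq_peptide_hit(hit, read_len) is expected

    def test_nonpositive_read_length_rejected(self):
        with pytest.raises(ValueError):
            is_hq_peptide_hit(_hit(SubjectDB.PROTEIN), 0)


class TestBestHit:
    def test_orders_by_bitscore_then_evalue_then_subject(self):
        hits = [
            _hit(SubjectDB.PROTEIN, subject="b", bits=90, evalue=1e-10),
            _hit(SubjectDB.PROTEIN, subject="a", bits=90, evalue=1e-12),
            _hit(SubjectDB.PROTEIN, subject="z", bits=99, evalue=1e-5),
        ]
        assert best_hit(hits).subject_id == "z"
        assert best_hit(hits[:2]).subject_id == "a"
        tied = [
            _hit(SubjectDB.PROTEIN, subject="m", bits=90, evalue=1e-10),
            _hit(SubjectDB.PROTEIN, subject="k", bits=90, evalue=1e-10),
        ]
        assert best_hit(tied).subject_id == "k"
        assert best_hit([]) is None


class TestLadder:
    def test_rrna_outranks_mouse(self):
        classes = classify_reads(
            {"r1": 76},
            rrna_hits=[_hit(SubjectDB.RRNA, bits=80)],
            mouse_tx_mapped={"r1"},
        )
        assert classes[0].category is Category.RRNA

    def test_no_evidence_is_unassigned(self):
        (c,) = classify_reads({"lonely": 76})
        assert c.category is Category.UNASSIGNED and c.best_subject is None

    def test_hq_peptide_hit_bottoms_out_the_ladder(self):
        (c,) = classify_reads(
            {"r1": 76},
            peptide_hits=[_hit(SubjectDB.PROTEIN, pident=97.0, length=20)],
        )
        assert c.category is Category.BACTERIAL_PEPTIDE and c.best_subject == "s1"

    def test_low_quality_peptide_hit_stays_unassigned(self):
        (c,) = classify_reads(
            {"r1": 76},
            peptide_hits=[_hit(SubjectDB.PROTEIN, pident=70.0, length=20)],
        )
        assert c.category is Category.UNASSIGNED

    def test_adaptor_outranks_everything(self):
        (c,) = classify_reads(
            {"r1": 76},
            adaptor_ids={"r1"},
            rrna_hits=[_hit(SubjectDB.RRNA, bits=80)],
        )
        assert c.category is Category.ADAPTOR

    def test_mouse_transcript_takes_precedence_over_genome(self):
        (c,) = classify_reads({"r1": 76}, mouse_tx_mapped={"r1"}, mouse_genome_mapped={"r1"})
        assert c.category is Category.MOUSE and c.mouse_ref == "transcript"

    def test_unknown_query_ids_are_ignored(self):
        classes = classify_reads(
            {"r1": 76}, rrna_hits=[_hit(SubjectDB.RRNA, query="ghost", bits=80)]
        )
        assert classes[0].category is Category.UNASSIGNED

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_each_read_gets_exactly_one_category(self, data):
        read_ids = [f"r{i}" for i in range(data.draw(st.integers(1, 12)))]
        lengths = dict.fromkeys(read_ids, 76)
        pick = lambda: set(data.draw(st.lists(st.sampled_from(read_ids), max_size=6)))
        rrna = [
            _hit(SubjectDB.RRNA, query=r, bits=data.draw(st.floats(0, 200)))
            for r in pick()
        ]
        pep = [
            _hit(SubjectDB.PROTEIN, query=r, pident=data.draw(st.floats(50, 100)), length=20)
            for r in pick()
        ]
        classes = classify_reads(
            lengths,
            adaptor_ids=pick(),
            rrna_hits=rrna,
            mouse_tx_mapped=pick(),
            mouse_genome_mapped=pick(),
            bact_nt_mapped=pick(),
            peptide_hits=pep,
        )
        assert sorted(c.read_id for c in classes) == sorted(read_ids)
        counts = count_classes(classes)
        assert (
            counts["adaptor"] + counts["rrna"] + counts["mouse_tx"] + counts["mouse_genome"]
            + counts["bact_nt"] + counts["bact_peptide"]
            + sum(c.category is Category.UNASSIGNED for c in classes)
            == counts["total"]
        )

    def test_adding_lower_precedence_evidence_never_reclassifies(self):
        base = classify_reads({"r1": 76}, rrna_hits=[_hit(SubjectDB.RRNA, bits=80)])
        more = classify_reads(
            {"r1": 76},
            rrna_hits=[_hit(SubjectDB.RRNA, bits=80)],
            mouse_tx_mapped={"r1"},
            bact_nt_mapped={"r1"},
            peptide_hits=[_hit(SubjectDB.PROTEIN, pident=99.0, length=25)],
        )
        assert base[0].category is more[0].category is Category.RRNA


class TestYieldTable:
    def test_percentages_are_of_non_adaptor_reads(self):
        counts = pd.DataFrame(
            [
                {
                    "total": 1000,
                    "adaptor": 200,
                    "rrna": 400,
                    "mouse_tx": 40,
                    "mouse_genome": 40,
                    "bact_nt": 20,
                    "bact_peptide": 100,
                }
            ],
            index=["s1"],
        )
        out = yield_table(counts)
        assert out.loc["s1", "pct_rrna"] == 50.0
        assert out.loc["s1", "pct_mouse"] == 10.0
        assert out.loc["s1", "pct_bacterial"] == 12.5

    def test_all_zero_categories_give_zero_percents(self):
        counts = pd.DataFrame(
            [dict(total=100, adaptor=0, rrna=0, mouse_tx=0, mouse_genome=0, bact_nt=0, bact_peptide=0)],
            index=["s"],
        )
        out = yield_table(counts)
        assert out.loc["s", ["pct_mouse", "pct_rrna", "pct_bacterial"]].tolist() == [0.0, 0.0, 0.0]

    def test_all_adaptor_sample_yields_null_percents(self):
        counts = pd.DataFrame(
            [dict(total=10, adaptor=10, rrna=0, mouse_tx=0, mouse_genome=0, bact_nt=0, bact_peptide=0)],
            index=["s"],
        )
        out = yield_table(counts)
        assert math.isnan(out.loc["s", "pct_rrna"])

    def test_rounding_is_half_up_to_one_decimal(self):
        counts = pd.DataFrame(
            [dict(total=1000, adaptor=0, rrna=125, mouse_tx=0, mouse_genome=0, bact_nt=0, bact_peptide=0)],
            index=["s"],
        )
        # 12.5% exactly: stays 12.5; 0.25 ties round away from zero
        assert yield_table(counts).loc["s", "pct_rrna"] == 12.5


def test_pipeline_recovers_truth_categories(community, evidence, analysis):
    """On noiseless synthetic evidence the ladder reproduces the truth table."""
    from conftest import TRUTH_TO_CLASS

    truth = dict(zip(community.read_truth["read_id"], community.read_truth["category"]))
    pred = {c.read_id: c.category.value for c in analysis.classes}
    mismatches = [r for r, t in truth.items() if r in pred and pred[r] != TRUTH_TO_CLASS[t]]
    assert mismatches == []
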