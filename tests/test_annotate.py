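import numpy as np
import pytest
from oracles import oracle_category

from cicfusion.annotate import (
    DISRUPTED,
    FIVE_PRIME_NONCODING,
    FIVE_PRIME_READTHROUGH,
    IN_FRAME,
    LOST,
    NATIVE_3PRIME,
    NONE_FOUND,
    NOT_ANNOTATABLE,
    OUT_OF_FRAME,
    PREMATURE,
    RETAINED,
    THREE_PRIME_UPSTREAM,
    UTR_FUSION,
    AnnotationError,
    ambiguous_assignment_diagnostic,
    annotate_database,
    classify_fusion,
    domain_status_genomic,
    domain_status_protein,
    predict_fusion_protein,
)
from cicfusion.breakpoints import BreakpointRecord, HarmonizedDatabase
from cicfusion.reference import DomainAnnotation, TranscriptReference, domain_nt_interval
from cicfusion.simulate import make_toy_reference


class TestClassify:
    def test_matching_phase_is_in_frame(self, toy5, toy3):
        ann = classify_fusion(toy5, toy5.cds_start + 29, toy3, toy3.cds_start + 3)
        assert ann.category == IN_FRAME
        assert (ann.n5_cds, ann.phase5) == (30, 0)
        assert (ann.p3_cds, ann.phase3) == (4, 0)

    def test_shifted_entry_is_out_of_frame(self, toy5, toy3):
        ann = classify_fusion(toy5, toy5.cds_start + 29, toy3, toy3.cds_start + 4)
        assert ann.category == OUT_OF_FRAME
        assert (ann.phase5, ann.phase3) == (0, 1)

    def test_three_prime_utr_entry(self, toy5, toy3):
        ann = classify_fusion(toy5, toy5.cds_start + 29, toy3, toy3.cds_end + 50)
        assert ann.category == UTR_FUSION
        assert ann.phase3 is None

    def test_five_prime_noncoding(self, toy5, toy3):
        ann = classify_fusion(toy5, toy5.cds_start - 1, toy3, toy3.cds_start)
        assert ann.category == FIVE_PRIME_NONCODING

    def test_readthrough_at_own_stop(self, toy5, toy3):
        ann = classify_fusion(toy5, toy5.cds_end, toy3, toy3.cds_start)
        assert ann.category == FIVE_PRIME_READTHROUGH

    def test_three_prime_upstream_of_cds(self, toy5, toy3):
        ann = classify_fusion(toy5, toy5.cds_start + 29, toy3, toy3.cds_start - 2)
        assert ann.category == THREE_PRIME_UPSTREAM

    def test_out_of_bounds_errors(self, toy5, toy3):
        with pytest.raises(AnnotationError):
            classify_fusion(toy5, 0, toy3, 1)
        with pytest.raises(AnnotationError):
            classify_fusion(toy5, 1, toy3, len(toy3) + 1)

    def test_agrees_with_translation_oracle(self, toy5, toy3):
        rng = np.random.default_rng(42)
        for _ in range(300):
            bp5 = int(rng.integers(1, len(toy5) + 1))
            bp3 = int(rng.integers(1, len(toy3) + 1))
            assert (
                classify_fusion(toy5, bp5, toy3, bp3).category
                == oracle_category(toy5, bp5, toy3, bp3)
            ), (bp5, bp3)

    def test_in_frame_call_has_period_three_in_bp5(self, toy5, toy3):
        bp3 = toy3.cds_start + 6
        cats = [
            classify_fusion(toy5, bp5, toy3, bp3).category
            for bp5 in range(toy5.cds_start, toy5.cds_start + 12)
        ]
        assert cats[0:12:3] == cats[0:1] * 4  # period 3
        assert sorted(set(cats)) == [IN_FRAME, OUT_OF_FRAME]
        phases = [
            classify_fusion(toy5, bp5, toy3, bp3).phase5
            for bp5 in range(toy5.cds_start, toy5.cds_start + 12)
        ]
        assert phases == [(i + 1) % 3 for i in range(12)]


class TestPredictProtein:
    def test_in_frame_concatenates_partner_translations(self, toy5, toy3):
        # junction after 5' codon 10, entering at 3' codon 6
        bp5 = toy5.cds_start + 30 - 1
        bp3 = toy3.cds_start + 15
        pred = predict_fusion_protein(toy5, bp5, toy3, bp3)
        assert pred.sequence == toy5.protein[:10] + toy3.protein[5:]
        assert pred.stop_origin == NATIVE_3PRIME
        assert pred.junction_residue_index == 11
        assert "*" not in pred.sequence

    def test_utr_fusion_premature_stop_near_junction(self, toy5):
        # 3' partner whose UTR carries TAA at in-frame offset 10..12
        utr3 = "CCCCCCCCC" + "TAA" + "C" * 20
        ref3 = TranscriptReference(
            accession="SYN_U.1", gene_symbol="U",
            sequence="ATG" + "GAA" * 5 + "TAA" + utr3,
            cds_start=1, cds_end=21,
        )
        bp5 = toy5.cds_start + 30 - 1  # phase 0 junction
        pred = predict_fusion_protein(toy5, bp5, ref3, 22)
        assert pred.stop_origin == PREMATURE
        assert pred.junction_to_stop_nt == 10
        assert pred.junction_to_stop_nt <= 12
        assert pred.sequence == toy5.protein[:10] + "PPP"  # CCC codons

    def test_full_five_prime_cds_keeps_native_stop(self, toy5, toy3):
        pred = predict_fusion_protein(toy5, toy5.cds_end, toy3, toy3.cds_start)
        assert pred.sequence == toy5.protein
        assert pred.stop_origin == PREMATURE  # 5' stop precedes any 3' content
        assert pred.junction_to_stop_nt == -2  # stop codon starts 2 nt before bp5

    def test_no_stop_runs_off_end(self, toy5):
        # stopless 3' tail: out-of-frame UTR of C's only
        ref3 = TranscriptReference(
            accession="SYN_NS.1", gene_symbol="NS",
            sequence="ATG" + "GAA" * 5 + "TAA" + "C" * 30,
            cds_start=1, cds_end=21,
        )
        bp5 = toy5.cds_start + 30 - 1
        pred = predict_fusion_protein(toy5, bp5, ref3, 22)
        assert pred.stop_origin == NONE_FOUND
        assert pred.junction_to_stop_nt is None

    def test_noncoding_five_prime_rejected(self, toy5, toy3):
        with pytest.raises(AnnotationError):
            predict_fusion_protein(toy5, toy5.cds_start - 2, toy3, toy3.cds_start)


class TestDomainStatusGenomic:
    @pytest.fixture(scope="class")
    @staticmethod
    def ref():
        return make_toy_reference(
            "G", 10, 50, 10,
            domains=(DomainAnnotation("D", 20, 29),), seed=7,
        )

    def test_five_prime_boundaries(self, ref):
        dom = ref.domains[0]
        d_s, d_e = domain_nt_interval(ref, dom)
        assert domain_status_genomic(ref, dom, d_e, "five_prime") == RETAINED
        assert domain_status_genomic(ref, dom, d_e - 1, "five_prime") == DISRUPTED
        assert domain_status_genomic(ref, dom, d_s, "five_prime") == DISRUPTED
        assert domain_status_genomic(ref, dom, d_s - 1, "five_prime") == LOST

    def test_three_prime_boundaries(self, ref):
        dom = ref.domains[0]
        d_s, d_e = domain_nt_interval(ref, dom)
        assert domain_status_genomic(ref, dom, d_s, "three_prime") == RETAINED
        assert domain_status_genomic(ref, dom, d_s + 1, "three_prime") == DISRUPTED
        assert domain_status_genomic(ref, dom, d_e, "three_prime") == DISRUPTED
        assert domain_status_genomic(ref, dom, d_e + 1, "three_prime") == LOST

    def test_five_prime_status_is_monotone_in_bp(self, ref):
        dom = ref.domains[0]
        order = {LOST: 0, DISRUPTED: 1, RETAINED: 2}
        statuses = [
            order[domain_status_genomic(ref, dom, bp, "five_prime")]
            for bp in range(1, len(ref) + 1)
        ]
        assert statuses == sorted(statuses)


class TestDomainStatusProtein:
    def test_in_frame_retention_matches_genomic(self, toy5, toy3):
        dom = toy5.domain("C1")
        _, d_e = domain_nt_interval(toy5, dom)
        bp5 = d_e  # exactly at the domain's last nucleotide
        bp3 = toy3.cds_start + ((bp5 - toy5.cds_start + 1) % 3)
        pred = predict_fusion_protein(toy5, bp5, toy3, bp3)
        assert domain_status_genomic(toy5, dom, bp5, "five_prime") == RETAINED
        assert domain_status_protein(pred, toy5, dom, "five_prime") == RETAINED

    def test_utr_fusion_stop_inside_domain_disrupts(self, toy5):
        # junction inside the C1 interval, immediate in-frame stop in the UTR
        dom = toy5.domain("C1")
        bp5 = toy5.cds_start + 3 * 32 - 1  # after codon 32 of domain 30..35
        ref3 = TranscriptReference(
            accession="SYN_U2.1", gene_symbol="U2",
            sequence="ATG" + "GAA" * 5 + "TAA" + "TAACCCCCC",
            cds_start=1, cds_end=21,
        )
        pred = predict_fusion_protein(toy5, bp5, ref3, 22)
        assert pred.stop_origin == PREMATURE
        assert domain_status_protein(pred, toy5, dom, "five_prime") == DISRUPTED
        assert domain_status_genomic(toy5, dom, bp5, "five_prime") == DISRUPTED

    def test_readthrough_keeps_all_five_prime_domains(self, toy5, toy3):
        pred = predict_fusion_protein(toy5, toy5.cds_end, toy3, toy3.cds_start)
        for dom in toy5.domains:
            assert domain_status_protein(pred, toy5, dom, "five_prime") == RETAINED

    def test_utr_fusion_loses_three_prime_domains(self, toy5, toy3):
        bp5 = toy5.cds_start + 30 - 1
        pred = predict_fusion_protein(toy5, bp5, toy3, toy3.cds_end + 5)
        for dom in toy3.domains:
            assert domain_status_protein(pred, toy3, dom, "three_prime") == LOST

    def test_out_of_frame_loses_three_prime_domain_identity(self, toy5, toy3):
        bp5 = toy5.cds_start + 30 - 1  # phase 0
        bp3 = toy3.cds_start + 1  # phase 1 -> frame shift
        pred = predict_fusion_protein(toy5, bp5, toy3, bp3)
        for dom in toy3.domains:
            assert domain_status_protein(pred, toy3, dom, "three_prime") == LOST


def _sim_record(case_id, bp5, bp3, toy5, toy3, **kw):
    base = dict(
        case_id=case_id, publication_id="p", five_prime_gene=toy5.gene_symbol,
        three_prime_gene=toy3.gene_symbol, evidence_source="RNA",
        resolution="nucleotide", five_prime_last_base=bp5,
        three_prime_first_base=bp3, ambiguous_junction_bases="",
        five_prime_accession=toy5.accession, three_prime_accession=toy3.accession,
    )
    base.update(kw)
    return BreakpointRecord(**base)


class TestAnnotateDatabase:
    def test_empty_database(self, toy5, toy3):
        out = annotate_database(HarmonizedDatabase([]), {})
        assert out == []

    def test_exon_level_gets_sentinel(self, toy5, toy3):
        rec = _sim_record("e", None, None, toy5, toy3, resolution="exon")
        out = annotate_database(HarmonizedDatabase([rec]), {})
        assert out[0].status == NOT_ANNOTATABLE

    def test_missing_reference_is_record_level_failure(self, toy5, toy3):
        rec = _sim_record("m", 30, 30, toy5, toy3, five_prime_accession="GONE.1")
        out = annotate_database(HarmonizedDatabase([rec]), {toy3.accession: toy3})
        assert out[0].status == "failed"
        assert "GONE.1" in out[0].reason

    def test_ambiguous_bases_assigned_before_classification(self, toy5, toy3):
        bp5 = toy5.cds_start + 29  # phase 0 after harmonization
        bases = toy5.sequence[bp5 - 2 : bp5]
        rec = _sim_record(
            "amb", bp5 - 2, toy3.cds_start + 3, toy5, toy3,
            ambiguous_junction_bases=bases,
        )
        refs = {toy5.accession: toy5, toy3.accession: toy3}
        out = annotate_database(HarmonizedDatabase([rec]), refs)
        assert out[0].annotation.category == IN_FRAME
        assert out[0].annotation.phase5 == 0


def test_ambiguity_diagnostic_flags_convention_sensitive_records(toy5, toy3):
    # 3' coordinate just inside the UTR: assigning 2 junction bases to the 3'
    # partner instead would pull the entry back into the CDS
    sensitive = _sim_record(
        "s", toy5.cds_start + 10, toy3.cds_end + 1, toy5, toy3,
        ambiguous_junction_bases="AA",
    )
    robust = _sim_record(
        "r", toy5.cds_start + 10, toy3.cds_end + 30, toy5, toy3,
        ambiguous_junction_bases="AA",
    )
    refs = {toy5.accession: toy5, toy3.accession: toy3}
    db = HarmonizedDatabase([sensitive, robust])
    assert ambiguous_assignment_diagnostic(db, refs) == ["s"]
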