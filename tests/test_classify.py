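"""Decision-tree behaviour: rule firing, partition, recovery."""

import pytest

from agpkit.classify import (
    ClassifyParams,
    Subfamily,
    classify_protein,
    classify_proteome,
    summarize_subfamilies,
)
from agpkit.io_formats import AnnotationRecord, DomainCall, DomainName, ProteinRecord


def make(seq, *, signal=False, gpi=False, domains=(), pid="p1"):
    rec = ProteinRecord(id=pid, sequence=seq)
    ann = AnnotationRecord(
        protein_id=pid,
        has_signal_peptide=signal,
        has_gpi_anchor=gpi,
        domains=domains,
    )
    return rec, ann


GLYCO = "APP" + "W" * 8 + "APP" + "W" * 8 + "APP"       # 3 glycomodules
NEUTRAL = "WYFMLIVDENQRH"


def pad(n):
    return (NEUTRAL * (n // len(NEUTRAL) + 1))[:n]


class TestChimericPath:
    def test_fas_with_glycomodules_is_fla(self):
        seq = GLYCO + pad(120)
        rec, ann = make(seq, domains=(DomainCall(DomainName.FAS, 30, 120),))
        assert classify_protein(rec, ann).subfamily is Subfamily.FLA

    def test_fas_without_glycomodules_rejected(self):
        seq = pad(150)
        rec, ann = make(seq, domains=(DomainCall(DomainName.FAS, 30, 120),))
        assert classify_protein(rec, ann).subfamily is Subfamily.NOT_AGP

    def test_pcnl_routes_to_pla(self):
        seq = GLYCO + pad(120)
        rec, ann = make(seq, domains=(DomainCall(DomainName.PCNL, 30, 120),))
        assert classify_protein(rec, ann).subfamily is Subfamily.PLA

    def test_nsltp2_with_eight_cys_is_xylp(self):
        seq = GLYCO + "CACACCACLCACAC" + pad(80)
        rec, ann = make(seq, domains=(DomainCall(DomainName.NSLTP2, 30, 44),))
        assert classify_protein(rec, ann).subfamily is Subfamily.XYLP

    def test_nsltp2_without_eight_cys_is_other_cagp(self):
        seq = GLYCO + pad(100)
        rec, ann = make(seq, domains=(DomainCall(DomainName.NSLTP2, 30, 90),))
        cls = classify_protein(rec, ann)
        assert cls.subfamily is Subfamily.OTHER_CAGP
        assert any("eight-cysteine" in n for n in cls.notes)

    def test_other_domain_is_other_cagp(self):
        seq = GLYCO + pad(120)
        rec, ann = make(seq, domains=(DomainCall(DomainName.PKINASE, 30, 120),))
        assert classify_protein(rec, ann).subfamily is Subfamily.OTHER_CAGP

    def test_ext_repeats_override_to_chae(self):
        seq = GLYCO + "SPPP" + pad(20) + "SPPP" + pad(80)
        rec, ann = make(seq, domains=(DomainCall(DomainName.GH, 60, 110),))
        assert classify_protein(rec, ann).subfamily is Subfamily.CHAE

    def test_domain_end_beyond_sequence_rejected(self):
        rec, ann = make(GLYCO, domains=(DomainCall(DomainName.FAS, 1, 500),))
        with pytest.raises(ValueError):
            classify_protein(rec, ann)


class TestNonChimericRules:
    def test_hae_needs_high_past_glyco_and_repeats(self):
        seq = "SPPP" + "ATTA" * 10 + "SPPP" + GLYCO + pad(30)
        rec, ann = make(seq)
        assert classify_protein(rec, ann).subfamily is Subfamily.HAE

    def test_ag_peptide_window(self):
        # length 70, PAST ~0.41, signal, glycomodules
        seq = GLYCO + "AT" * 10 + pad(25)
        assert len(seq) == 70
        rec, ann = make(seq, signal=True)
        assert classify_protein(rec, ann).subfamily is Subfamily.AG_PEPTIDE

    def test_classical_above_threshold(self):
        seq = GLYCO + "AT" * 40 + pad(20)
        rec, ann = make(seq, signal=True)
        assert classify_protein(rec, ann).subfamily is Subfamily.CLASSICAL

    def test_lys_rich_refines_classical(self):
        seq = GLYCO + "K" * 15 + "AT" * 50 + pad(20)
        rec, ann = make(seq, signal=True)
        assert classify_protein(rec, ann).subfamily is Subfamily.LYS_RICH

    def test_missing_signal_makes_non_classical(self):
        seq = GLYCO + "AT" * 40 + pad(20)
        rec, ann = make(seq, signal=False)
        assert classify_protein(rec, ann).subfamily is Subfamily.NON_CLASSICAL

    def test_past_exactly_at_threshold_is_non_classical(self):
        # 23 PAST / 46 residues: exactly 0.50 with strict comparison
        seq = "APP" + "W" * 9 + "APP" + "W" * 9 + "APP" + "AT" * 7 + "W" * 5
        assert len(seq) == 46
        rec, ann = make(seq, signal=True)
        cls = classify_protein(rec, ann)
        assert cls.evidence.profile.past_fraction == pytest.approx(0.5)
        assert cls.subfamily is Subfamily.NON_CLASSICAL

    def test_threshold_tie_configurable(self):
        seq = "APP" + "W" * 9 + "APP" + "W" * 9 + "APP" + "AT" * 7 + "W" * 5
        rec, ann = make(seq, signal=True)
        params = ClassifyParams(classical_strict=False)
        assert classify_protein(rec, ann, params).subfamily is Subfamily.CLASSICAL

    def test_low_past_no_match(self):
        rec, ann = make(pad(150), signal=True)
        assert classify_protein(rec, ann).subfamily is Subfamily.NOT_AGP

    def test_gpi_recorded_as_evidence_not_filter(self):
        seq = GLYCO + "AT" * 40 + pad(20)
        rec, ann = make(seq, signal=True, gpi=False)
        no_gpi = classify_protein(rec, ann)
        rec2, ann2 = make(seq, signal=True, gpi=True)
        with_gpi = classify_protein(rec2, ann2)
        assert no_gpi.subfamily is with_gpi.subfamily is Subfamily.CLASSICAL
        assert any("GPI" in n for n in with_gpi.notes)


class TestProteomeDriver:
    def test_empty_input(self):
        assert classify_proteome([], []) == []

    def test_id_mismatch_rejected(self):
        rec, _ = make(GLYCO)
        with pytest.raises(ValueError):
            classify_protein(rec, AnnotationRecord(protein_id="other"))

    def test_missing_annotation_defaults_to_absent(self):
        rec = ProteinRecord(id="p9", sequence=GLYCO + "AT" * 40)
        (cls,) = classify_proteome([rec], [])
        # without a signal flag the high-PAST protein lands in NON_CLASSICAL
        assert cls.subfamily is Subfamily.NON_CLASSICAL

    def test_order_equivariance(self, small_proteome):
        fwd = classify_proteome(small_proteome.records, small_proteome.annotations)
        rev = classify_proteome(small_proteome.records[::-1], small_proteome.annotations)
        assert [c.subfamily for c in fwd] == [c.subfamily for c in rev[::-1]]

    def test_planted_labels_recovered(self, small_proteome):
        cls = classify_proteome(small_proteome.records, small_proteome.annotations)
        assert all(c.subfamily is small_proteome.truth[c.protein_id] for c in cls)

    def test_determinism(self, small_proteome):
        a = classify_proteome(small_proteome.records, small_proteome.annotations)
        b = classify_proteome(small_proteome.records, small_proteome.annotations)
        assert [c.subfamily for c in a] == [c.subfamily for c in b]


class TestSummary:
    def test_all_not_agp(self):
        counts, total = summarize_subfamilies([Subfamily.NOT_AGP] * 4)
        assert total == 0 and all(v == 0 for v in counts.values())

    def test_partition_identity(self, small_proteome):
        cls = classify_proteome(small_proteome.records, small_proteome.annotations)
        counts, total = summarize_subfamilies(cls)
        assert total == sum(counts.values())
        assert total == sum(1 for c in cls if c.subfamily is not Subfamily.NOT_AGP)

    def test_published_subfamily_inventory_sums(self):
        """The nine-subfamily inventory of the B. rapa AGP family totals 293."""
        inventory = {
            Subfamily.CLASSICAL: 25,
            Subfamily.LYS_RICH: 3,
            Subfamily.AG_PEPTIDE: 30,
            Subfamily.FLA: 36,
            Subfamily.PLA: 59,
            Subfamily.XYLP: 33,
            Subfamily.OTHER_CAGP: 102,
            Subfamily.NON_CLASSICAL: 2,
            Subfamily.HAE: 3,
        }
        labels = [s for s, n in inventory.items() for _ in range(n)]
        counts, total = summarize_subfamilies(labels)
        assert total == 293
        assert {k: v for k, v in counts.items() if v} == inventory
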