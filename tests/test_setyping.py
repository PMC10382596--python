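"""Tests of in-silico PCR, CDS translation and Se-type classification."""

import numpy as np
import pytest

from selocus.setyping import (
    Lineage,
    Orf3Status,
    Orf4Status,
    RuleTable,
    SeHaplotypeCall,
    SeType,
    allele_profile_for_type,
    assign_se_type,
    call_haplotype,
    insilico_pcr,
    panel_frequencies,
    predict_compatibility,
    translate_cds,
)
from selocus.synth import (
    DEFAULT_TYPE_VARIANTS,
    Orf3StopAt,
    Orf4PromoterDeletion,
    apply_variants,
    sequence_for_type,
)
from selocus.transmission import TransmissionParams


def _revcomp(seq):
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _call(pav=True, orf3=Orf3Status.TRUNCATED, orf4=Orf4Status.INTACT,
          lineage=Lineage.ASIAN_COMPLEX, accession="acc", taxon="tax"):
    if not pav:
        orf3, orf4 = Orf3Status.ABSENT, Orf4Status.ABSENT
    return SeHaplotypeCall(
        accession_id=accession, taxon=taxon, pav_present=pav,
        orf3_status=orf3, orf4_status=orf4, lineage=lineage,
    )


class TestInsilicoPcr:
    def test_known_amplicon_coordinates(self):
        """Primers planted at known offsets yield one amplicon by arithmetic."""
        rng = np.random.default_rng(0)
        backbone = "".join(rng.choice(list("ACGT"), size=2000))
        fwd = backbone[300:320]
        rev = _revcomp(backbone[900:920])
        hits = insilico_pcr(backbone, fwd, rev, max_product=1000)
        assert hits == [(300, 920)]

    def test_no_site_means_no_product(self, reference_locus):
        ann = reference_locus.annotation
        absent = sequence_for_type(reference_locus, SeType.NO_PAV)
        assert insilico_pcr(
            absent.seq, ann.pav_fwd_primer, ann.pav_rev_primer, ann.pav_max_product
        ) == []

    def test_strand_invariance(self, reference_locus):
        ann = reference_locus.annotation
        fw = insilico_pcr(
            reference_locus.seq, ann.pav_fwd_primer, ann.pav_rev_primer, ann.pav_max_product
        )
        rc = insilico_pcr(
            _revcomp(reference_locus.seq),
            ann.pav_fwd_primer,
            ann.pav_rev_primer,
            ann.pav_max_product,
        )
        assert sorted(b - a for a, b in fw) == sorted(b - a for a, b in rc)

    def test_position_covariance(self, reference_locus):
        ann = reference_locus.annotation
        shifted = "A" * 57 + reference_locus.seq
        base = insilico_pcr(
            reference_locus.seq, ann.pav_fwd_primer, ann.pav_rev_primer, ann.pav_max_product
        )
        moved = insilico_pcr(
            shifted, ann.pav_fwd_primer, ann.pav_rev_primer, ann.pav_max_product
        )
        assert moved == [(a + 57, b + 57) for a, b in base]

    def test_max_product_enforced(self):
        rng = np.random.default_rng(1)
        backbone = "".join(rng.choice(list("ACGT"), size=2000))
        fwd = backbone[100:120]
        rev = _revcomp(backbone[1500:1520])
        assert insilico_pcr(backbone, fwd, rev, max_product=500) == []

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError):
            insilico_pcr("ACGT" * 100, "ACGTACGTACGT", "ACGT" * 5, 100)


class TestTranslateCds:
    def test_minimal_cds(self):
        assert translate_cds("ATGTAA") == "M"

    def test_reference_orf_lengths(self, reference_locus):
        s3, e3 = reference_locus.features["orf3_cds"]
        s4, e4 = reference_locus.features["orf4_cds"]
        assert len(translate_cds(reference_locus.seq[s3:e3])) == 596
        assert len(translate_cds(reference_locus.seq[s4:e4])) == 523

    def test_engineered_stop_truncates(self, reference_locus):
        var = apply_variants(reference_locus, [Orf3StopAt(101)])
        # re-extract the killer CDS (same coordinates: substitution only)
        s, e = reference_locus.features["orf3_cds"]
        assert len(translate_cds(var.seq[s:e])) == 100

    def test_stop_terminated_length_identity(self, reference_locus):
        for name in ("orf1_cds", "orf2_cds", "orf3_cds", "orf4_cds"):
            s, e = reference_locus.features[name]
            cds = reference_locus.seq[s:e]
            assert len(translate_cds(cds)) * 3 + 3 == len(cds)

    def test_errors(self):
        with pytest.raises(ValueError):
            translate_cds("TTGTAA")  # no ATG start
        with pytest.raises(ValueError):
            translate_cds("AT")


class TestCallHaplotype:
    def test_reference_is_type1_profile(self, reference_locus):
        call = call_haplotype(
            reference_locus.seq, reference_locus.annotation, lineage=Lineage.ASIAN_COMPLEX
        )
        assert call.pav_present
        assert call.orf3_status is Orf3Status.FULL_LENGTH
        assert call.orf4_status is Orf4Status.INTACT

    def test_promoter_deletion_detected(self, reference_locus):
        var = apply_variants(reference_locus, [Orf4PromoterDeletion()])
        assert len(var.seq) == len(reference_locus.seq) - 369
        call = call_haplotype(var.seq, reference_locus.annotation)
        assert call.orf4_status is Orf4Status.PROMOTER_DELETED

    def test_pav_absent_locus(self, reference_locus):
        var = sequence_for_type(reference_locus, SeType.NO_PAV)
        call = call_haplotype(var.seq, reference_locus.annotation)
        assert not call.pav_present
        assert call.orf3_status is Orf3Status.ABSENT
        assert call.orf4_status is Orf4Status.ABSENT

    def test_truth_label_round_trip_all_types(self, reference_locus):
        for se_type, variants in DEFAULT_TYPE_VARIANTS.items():
            var = apply_variants(reference_locus, list(variants))
            call = call_haplotype(var.seq, reference_locus.annotation)
            assert call.orf3_status.value == var.truth["orf3_status"]
            assert call.orf4_status.value == var.truth["orf4_status"]
            assert call.pav_present == var.truth["pav_present"]

    def test_illegal_characters_rejected(self, reference_locus):
        with pytest.raises(ValueError):
            call_haplotype("ACGTX" * 100, reference_locus.annotation)

    def test_inconsistent_call_rejected(self):
        with pytest.raises(ValueError):
            SeHaplotypeCall(
                accession_id="a", taxon="t", pav_present=False,
                orf3_status=Orf3Status.FULL_LENGTH, orf4_status=Orf4Status.ABSENT,
            )


class TestAssignSeType:
    @pytest.mark.parametrize(
        "orf3, orf4, lineage, expected",
        [
            (Orf3Status.FULL_LENGTH, Orf4Status.INTACT, Lineage.ASIAN_COMPLEX, SeType.TYPE1),
            (Orf3Status.TRUNCATED, Orf4Status.PROMOTER_DELETED, Lineage.ASIAN_COMPLEX, SeType.TYPE2),
            (Orf3Status.TRUNCATED, Orf4Status.INTACT, Lineage.ASIAN_COMPLEX, SeType.TYPE3),
            (Orf3Status.TRUNCATED, Orf4Status.INTACT, Lineage.AFRICAN_COMPLEX, SeType.TYPE4),
            (Orf3Status.TRUNCATED, Orf4Status.INTACT, Lineage.MERIDIONALIS, SeType.TYPE5),
            # the rare truncated-protector haplotype falls through to Type 2
            (Orf3Status.TRUNCATED, Orf4Status.TRUNCATED, Lineage.ASIAN_COMPLEX, SeType.TYPE2),
        ],
    )
    def test_default_rules(self, orf3, orf4, lineage, expected):
        assert assign_se_type(_call(orf3=orf3, orf4=orf4, lineage=lineage)) is expected

    def test_no_pav_class(self):
        assert assign_se_type(_call(pav=False)) is SeType.NO_PAV

    def test_custom_rule_table_from_config(self):
        table = RuleTable.from_config(
            [
                {"name": "absent", "match": {"pav_present": False}, "type": "noPAV"},
                {"name": "rest", "match": {}, "type": "Type3"},
            ]
        )
        assert table.apply(_call(pav=False)) is SeType.NO_PAV
        assert table.apply(_call()) is SeType.TYPE3

    def test_non_total_table_raises(self):
        table = RuleTable.from_config(
            [{"name": "only", "match": {"pav_present": False}, "type": "noPAV"}]
        )
        with pytest.raises(ValueError):
            table.apply(_call())


class TestPanelFrequencies:
    def test_printed_japonica_fraction(self):
        calls = [
            _call(pav=False, accession=f"j{i}", taxon="japonica") for i in range(132)
        ] + [
            _call(orf3=Orf3Status.FULL_LENGTH, accession=f"j{132 + i}", taxon="japonica")
            for i in range(16)
        ]
        table = panel_frequencies(calls)
        row = table[(table.taxon == "japonica") & (table.se_type == "noPAV")]
        assert row.pct.iloc[0] == pytest.approx(100 * 132 / 148)
        assert round(row.pct.iloc[0], 2) == 89.19

    def test_single_accession(self):
        table = panel_frequencies([_call()])
        assert table.pct.iloc[0] == 100.0

    def test_per_taxon_percentages_sum_to_100(self):
        rng = np.random.default_rng(9)
        calls = []
        for i in range(200):
            taxon = f"tax{rng.integers(3)}"
            pav = bool(rng.integers(2))
            calls.append(_call(pav=pav, accession=f"a{i}", taxon=taxon))
        table = panel_frequencies(calls, include_overall=False)
        for _, sub in table.groupby("taxon"):
            assert sub.pct.sum() == pytest.approx(100.0)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            panel_frequencies([])


class TestPredictCompatibility:
    def _typed_call(self, se_type, accession):
        mapping = {
            SeType.TYPE1: dict(orf3=Orf3Status.FULL_LENGTH, orf4=Orf4Status.INTACT),
            SeType.TYPE3: dict(orf3=Orf3Status.TRUNCATED, orf4=Orf4Status.INTACT),
            SeType.NO_PAV: dict(pav=False),
        }
        return _call(accession=accession, **mapping[se_type])

    def test_killer_by_nopav_semisterile(self):
        v = predict_compatibility(
            self._typed_call(SeType.TYPE1, "a"), self._typed_call(SeType.NO_PAV, "b")
        )
        assert v == pytest.approx(0.50)

    def test_neutral_type3_fully_compatible(self):
        v = predict_compatibility(
            self._typed_call(SeType.TYPE3, "a"), self._typed_call(SeType.NO_PAV, "b")
        )
        assert v == pytest.approx(1.0)

    def test_like_by_like_fertile(self):
        v = predict_compatibility(
            self._typed_call(SeType.TYPE1, "a"), self._typed_call(SeType.TYPE1, "b")
        )
        assert v == pytest.approx(1.0)

    def test_type_profiles(self):
        p1 = allele_profile_for_type(SeType.TYPE1)
        assert p1.has_functional_killer and p1.has_functional_protector
        p2 = allele_profile_for_type(SeType.TYPE2)
        assert not p2.has_functional_killer and p2.has_functional_protector
        p0 = allele_profile_for_type(SeType.NO_PAV)
        assert not p0.has_functional_killer and not p0.has_functional_protector
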