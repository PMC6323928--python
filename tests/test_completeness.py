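import numpy as np
import pytest

from uvigkit.circularity import CircularityCall
from uvigkit.completeness import (
    CompletenessParams,
    GenusGroup,
    affiliate_by_markers,
    assign_quality_tier,
    estimate_completeness,
    flag_false_positive_circular,
    predicted_genome_size,
)
from uvigkit.records import MarkerHit, QualityTier, ViralContig


def _contig(length, circular=False, **kwargs):
    contig = ViralContig(id=kwargs.pop("id", "c"), sequence="A" * length, **kwargs)
    if circular:
        contig.circularity = CircularityCall(True, "DTR", 12, 0, length - 12)
    return contig


class TestMarkerAffiliation:
    def test_two_consistent_dsdna_markers_affiliate(self):
        hits = [MarkerHit("c", "m1", "G1", "dsDNA"), MarkerHit("c", "m2", "G1", "dsDNA")]
        aff = affiliate_by_markers(hits, "c")
        assert aff is not None and aff.taxon == "G1" and aff.n_supporting_markers == 2

    def test_single_dsdna_marker_insufficient(self):
        assert affiliate_by_markers([MarkerHit("c", "m1", "G1", "dsDNA")], "c") is None

    def test_single_ssdna_marker_sufficient(self):
        aff = affiliate_by_markers([MarkerHit("c", "m1", "F1", "ssDNA")], "c")
        assert aff is not None and aff.taxon_class == "ssDNA"

    def test_four_ncldv_markers_insufficient(self):
        hits = [MarkerHit("c", f"m{i}", "Giant1", "NCLDV") for i in range(4)]
        assert affiliate_by_markers(hits, "c") is None
        hits.append(MarkerHit("c", "m5", "Giant1", "NCLDV"))
        assert affiliate_by_markers(hits, "c") is not None

    def test_majority_taxon_wins_and_ties_give_none(self):
        hits = [
            MarkerHit("c", "m1", "G1", "dsDNA"),
            MarkerHit("c", "m2", "G1", "dsDNA"),
            MarkerHit("c", "m3", "G1", "dsDNA"),
            MarkerHit("c", "m4", "G2", "dsDNA"),
        ]
        assert affiliate_by_markers(hits, "c").taxon == "G1"
        hits.extend([MarkerHit("c", "m5", "G2", "dsDNA"), MarkerHit("c", "m6", "G2", "dsDNA")])
        assert affiliate_by_markers(hits, "c") is None

    def test_conflicting_class_for_same_taxon_rejected(self):
        hits = [MarkerHit("c", "m1", "G1", "dsDNA"), MarkerHit("c", "m2", "G1", "ssDNA")]
        with pytest.raises(ValueError, match="conflicting"):
            affiliate_by_markers(hits, "c")

    def test_mean_taxon_length_read_from_reference(self):
        hits = [MarkerHit("c", "m1", "G1", "dsDNA"), MarkerHit("c", "m2", "G1", "dsDNA")]
        aff = affiliate_by_markers(hits, "c", ref_lengths={"G1": 41000.0})
        assert aff.mean_taxon_genome_length == 41000.0


class TestFalsePositiveCircular:
    def test_below_80pct_of_min_isolate(self):
        group = GenusGroup("g", isolate_lengths=[40_000, 50_000])
        fp, reason = flag_false_positive_circular(_contig(30_000, circular=True), group, None)
        assert fp and "min_isolate" in reason

    def test_at_or_above_80pct_of_min_isolate_kept(self):
        group = GenusGroup("g", isolate_lengths=[40_000])
        fp, _ = flag_false_positive_circular(_contig(33_000, circular=True), group, None)
        assert not fp

    def test_isolate_free_group_uses_max_linear(self):
        group = GenusGroup("g", linear_lengths=[20_000, 50_000])
        fp, reason = flag_false_positive_circular(_contig(30_000, circular=True), group, None)
        assert fp and "max_linear" in reason

    def test_short_unaffiliated_circular_flagged(self):
        fp, reason = flag_false_positive_circular(_contig(8_000, circular=True), None, None)
        assert fp and "ssDNA" in reason

    def test_short_circular_with_ssdna_marker_exempt(self):
        from uvigkit.completeness import TaxonAffiliation

        aff = TaxonAffiliation("c", "F1", "ssDNA", 1)
        fp, _ = flag_false_positive_circular(_contig(8_000, circular=True), None, aff)
        assert not fp

    def test_requires_positive_circularity_call(self):
        with pytest.raises(ValueError, match="circularity"):
            flag_false_positive_circular(_contig(8_000), None, None)

    def test_monotone_in_length_per_rule(self):
        group = GenusGroup("g", isolate_lengths=[40_000])
        flags = [
            flag_false_positive_circular(_contig(length, circular=True), group, None)[0]
            for length in range(20_000, 60_001, 5_000)
        ]
        # once a length stops being flagged, no longer length is flagged
        assert flags == sorted(flags, reverse=True)


class TestPredictedGenomeSize:
    def test_tight_group_defines_size(self):
        group = GenusGroup("g", isolate_lengths=[40_000, 41_000, 39_000])
        assert predicted_genome_size(group) == pytest.approx(40_000)
        assert group.size_sd == pytest.approx(np.std([40_000, 41_000, 39_000]))

    def test_dispersed_group_undefined(self):
        group = GenusGroup("g", isolate_lengths=[10_000], circular_lengths=[40_000])
        assert predicted_genome_size(group) is None  # SD 15000 > 0.15 * 25000

    def test_single_member_defines_size(self):
        group = GenusGroup("g", circular_lengths=[40_000])
        assert predicted_genome_size(group) == 40_000

    def test_empty_group_undefined(self):
        assert predicted_genome_size(GenusGroup("g")) is None

    def test_invariant_to_member_order(self):
        lengths = [39_000, 41_000, 40_000, 40_500]
        forward = predicted_genome_size(GenusGroup("g", isolate_lengths=lengths))
        backward = predicted_genome_size(GenusGroup("g", isolate_lengths=lengths[::-1]))
        assert forward == backward


class TestCompleteness:
    def test_half_length_contig(self):
        assert estimate_completeness(_contig(20_000), 40_000) == pytest.approx(50.0)

    def test_oversize_capped_at_99(self):
        assert estimate_completeness(_contig(45_000), 40_000) == 99.0

    def test_undefined_without_size(self):
        assert estimate_completeness(_contig(20_000), None) is None

    def test_non_positive_size_rejected(self):
        with pytest.raises(ValueError):
            estimate_completeness(_contig(20_000), 0)


class TestQualityTier:
    def test_isolate_is_finished(self):
        contig = _contig(40_000, source_class="isolate")
        assert assign_quality_tier(contig) == QualityTier.FINISHED

    def test_non_fp_circular_is_complete(self):
        assert assign_quality_tier(_contig(40_000, circular=True)) == QualityTier.COMPLETE_CIRCULAR

    def test_fp_circular_is_tiered_as_linear(self):
        contig = _contig(8_000, circular=True)
        contig.false_positive_circular = True
        assert assign_quality_tier(contig) == QualityTier.GENOME_FRAGMENT

    def test_linear_at_92_percent_is_high_quality(self):
        contig = _contig(46_000)
        contig.completeness_pct = 92.0
        assert assign_quality_tier(contig) == QualityTier.HIGH_QUALITY_DRAFT

    def test_linear_without_completeness_is_fragment(self):
        assert assign_quality_tier(_contig(46_000)) == QualityTier.GENOME_FRAGMENT

    def test_transition_happens_exactly_once_at_90(self):
        size = 50_000
        tiers = []
        for pct in range(80, 101):
            contig = _contig(size * pct // 100)
            contig.completeness_pct = estimate_completeness(contig, size)
            tiers.append(assign_quality_tier(contig))
        switches = [
            (a, b) for a, b in zip(tiers, tiers[1:]) if a != b
        ]
        assert switches == [(QualityTier.GENOME_FRAGMENT, QualityTier.HIGH_QUALITY_DRAFT)]
        assert tiers[10] == QualityTier.HIGH_QUALITY_DRAFT  # 90% exactly
        assert tiers[9] == QualityTier.GENOME_FRAGMENT  # 89%
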