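"""Landmark windows: extents, precedence, distances."""

import pytest

from ssaso_triage import (
    CPos,
    DEFAULT_CONFIG,
    RegionClass,
    classify_region,
    distance_to_nearest_splice_site,
    encode_worked_examples,
    parse_hgvs_c,
)
from ssaso_triage.region_classifier import TAG_SPANS_JUNCTION

# bundle-model geometry used throughout: exon 2 ends at c.171, exon 3 starts
# at c.172; intron 2 is 3200 nt long, so one junction dominates each probe.


class TestDonorSideWindows:
    def test_partition_of_first_200_intronic_bases(self, model):
        for d in range(1, 201):
            r = classify_region(model, CPos(171, +d))
            if d <= 2:
                expected = RegionClass.CANONICAL_DONOR
            elif d <= DEFAULT_CONFIG.donor_region_intronic_nt:
                expected = RegionClass.DONOR_REGION
            elif d <= DEFAULT_CONFIG.deep_intronic_nt:
                expected = RegionClass.PROXIMAL_INTRONIC
            else:
                expected = RegionClass.DEEP_INTRONIC
            assert r.primary_class is expected, f"d={d}"
            assert r.distance_to_nearest_splice_site == d

    def test_donor_region_extent_is_exactly_six_intronic_bases(self, model):
        member = [
            d
            for d in range(1, 60)
            if classify_region(model, CPos(171, +d)).has_tag(RegionClass.DONOR_REGION)
        ]
        assert member == list(range(1, 7))


class TestAcceptorSideWindows:
    def test_partition_upstream_of_exon_three(self, model):
        for d in range(1, 201):
            r = classify_region(model, CPos(172, -d))
            if d <= 2:
                expected = RegionClass.CANONICAL_ACCEPTOR
            elif d <= DEFAULT_CONFIG.acceptor_region_intronic_nt:
                expected = RegionClass.ACCEPTOR_REGION
            elif d <= DEFAULT_CONFIG.branch_window_max_nt:
                expected = RegionClass.BRANCH_POINT_WINDOW
            elif d <= DEFAULT_CONFIG.deep_intronic_nt:
                expected = RegionClass.PROXIMAL_INTRONIC
            else:
                expected = RegionClass.DEEP_INTRONIC
            assert r.primary_class is expected, f"d={d}"

    def test_acceptor_region_extent_is_exactly_twenty_intronic_bases(self, model):
        member = [
            d
            for d in range(1, 60)
            if classify_region(model, CPos(172, -d)).has_tag(
                RegionClass.ACCEPTOR_REGION
            )
        ]
        assert member == list(range(1, 21))

    def test_branch_window_edges_are_18_and_40(self, model):
        member = [
            d
            for d in range(1, 80)
            if classify_region(model, CPos(172, -d)).has_tag(
                RegionClass.BRANCH_POINT_WINDOW
            )
        ]
        assert member == list(range(18, 41))

    def test_distance_to_branch_window(self, model):
        assert classify_region(model, CPos(172, -29)).distance_to_branch_window == 0
        assert classify_region(model, CPos(172, -10)).distance_to_branch_window == 8
        assert classify_region(model, CPos(172, -55)).distance_to_branch_window == 15


class TestDeepBoundary:
    def test_deep_intronic_starts_strictly_beyond_100(self, model):
        r100 = classify_region(model, CPos(171, +100))
        r101 = classify_region(model, CPos(171, +101))
        assert r100.primary_class is RegionClass.PROXIMAL_INTRONIC
        assert r101.primary_class is RegionClass.DEEP_INTRONIC


class TestExonicPositions:
    def test_terminal_base_is_distance_one(self, model):
        r = classify_region(model, CPos(255))  # last base of exon 3
        assert r.primary_class is RegionClass.EXONIC
        assert r.distance_to_nearest_splice_site == 1
        assert r.has_tag(RegionClass.DONOR_REGION)

    def test_exonic_donor_region_spans_three_bases(self, model):
        assert classify_region(model, CPos(253)).has_tag(RegionClass.DONOR_REGION)
        assert not classify_region(model, CPos(252)).has_tag(RegionClass.DONOR_REGION)

    def test_exonic_acceptor_region_spans_one_base(self, model):
        assert classify_region(model, CPos(172)).has_tag(RegionClass.ACCEPTOR_REGION)
        assert not classify_region(model, CPos(173)).has_tag(
            RegionClass.ACCEPTOR_REGION
        )

    def test_first_exon_has_no_acceptor_junction(self, model):
        # c.1 sits at transcript position 101 inside the 151-nt first exon
        r = classify_region(model, CPos(1))
        assert r.distance_to_nearest_splice_site == 51
        assert not r.has_tag(RegionClass.ACCEPTOR_REGION)

    def test_near_junction_flag_uses_recommended_cutoff(self, model):
        assert classify_region(model, CPos(241)).near_junction_exonic  # d=15
        assert not classify_region(model, CPos(240)).near_junction_exonic  # d=16

    def test_utr_position_classified_as_utr(self, model):
        r = classify_region(model, parse_hgvs_c("c.-12A>G"))
        assert r.primary_class is RegionClass.UTR
        assert not r.near_junction_exonic


class TestRangedVariants:
    def test_junction_spanning_deletion(self, model):
        v = parse_hgvs_c("c.171_171+2del")
        r = classify_region(model, v)
        assert r.primary_class is RegionClass.CANONICAL_DONOR
        assert r.has_tag(TAG_SPANS_JUNCTION)
        assert r.distance_to_nearest_splice_site == 1

    def test_fully_exonic_range_does_not_span(self, model):
        r = classify_region(model, parse_hgvs_c("c.200_210del"))
        assert not r.has_tag(TAG_SPANS_JUNCTION)
        assert r.primary_class is RegionClass.EXONIC


class TestDistanceProperties:
    def test_distance_is_one_lipschitz_across_an_intron(self, simple_plus_model):
        # intron 1 is 200 nt long; the distance profile must move by at most
        # one per base and be symmetric around the intron centre
        dists = [
            distance_to_nearest_splice_site(simple_plus_model, CPos(120, +k))
            for k in range(1, 201)
        ]
        assert dists[0] == 1 and dists[-1] == 1
        assert max(dists) == 100
        for a, b in zip(dists, dists[1:]):
            assert abs(a - b) <= 1
        assert dists == dists[::-1]

    def test_single_exon_transcript_has_no_splice_sites(self):
        from ssaso_triage import generate_random_transcript

        m = generate_random_transcript(3, n_exons=1)
        assert distance_to_nearest_splice_site(m, CPos(5)) is None


class TestWorkedExamples:
    @pytest.mark.parametrize("idx", range(4))
    def test_published_descriptors_classify_as_documented(self, idx):
        ex = encode_worked_examples()[idx]
        r = classify_region(ex.model, ex.variant)
        assert r.primary_class is ex.expected_class, ex.gene
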