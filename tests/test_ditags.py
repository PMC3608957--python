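from collections import Counter

import numpy as np
import pytest

from ditagdel.ditags import (
    AlignedPair,
    Ditag,
    MateAlignment,
    NickModel,
    assign_tag_id,
    cluster_ditags,
    extract_ditags,
    pair_to_ditag,
    pairs_from_sam,
    parse_ditag_id,
    summarize_ditags,
)
from ditagdel.restriction import SiteIndex, TagID, digest, ref_ditag_catalog
from ditagdel.simulate import write_sam


@pytest.fixture()
def site_index():
    # TaqI cut_offset 1: cuts fall after position p (the T stays left)
    return SiteIndex("chr3", np.asarray([1_000, 2_000, 3_000, 4_000, 5_000]))


@pytest.fixture()
def model():
    return NickModel()


class TestAssignTagID:
    def test_read_starting_at_cut_gets_side2(self, site_index, taqi, model):
        # cut of site 2 is at 2000; downstream region starts at 2001
        mate = MateAlignment("chr3", 2_001, 2_050)
        assert assign_tag_id(mate, site_index, taqi, model) == TagID("chr3", 2, 2)

    def test_read_ending_at_cut_gets_side1(self, site_index, taqi, model):
        mate = MateAlignment("chr3", 2_951, 3_000, "-")
        assert assign_tag_id(mate, site_index, taqi, model) == TagID("chr3", 3, 1)

    def test_tolerance_window(self, site_index, taqi, model):
        assert assign_tag_id(
            MateAlignment("chr3", 2_003, 2_052), site_index, taqi, model
        ) == TagID("chr3", 2, 2)
        assert (
            assign_tag_id(MateAlignment("chr3", 2_004, 2_053), site_index, taqi, model)
            is None
        )

    def test_read_far_from_all_sites_is_unanchored(self, site_index, taqi, model):
        assert assign_tag_id(
            MateAlignment("chr3", 2_500, 2_549), site_index, taqi, model
        ) is None

    def test_dense_sites_are_ambiguous(self, taqi, model):
        dense = SiteIndex("chr3", np.asarray([1_000, 1_002]))
        # read start 1001 is within tolerance of both cuts (1000 and 1002)
        assert assign_tag_id(
            MateAlignment("chr3", 1_001, 1_050), dense, taqi, model
        ) is None

    def test_distal_assignment_uses_partner_side(self, site_index, taqi, model):
        # partner anchored at (2, side 2); distal read's right end sits
        # 150 bp left of the cut of site 3
        distal = MateAlignment("chr3", 2_801, 2_850, "-")
        tag = assign_tag_id(
            distal, site_index, taqi, model, role="distal",
            partner=TagID("chr3", 2, 2),
        )
        assert tag == TagID("chr3", 3, 1)

    def test_distal_requires_partner(self, site_index, taqi, model):
        with pytest.raises(ValueError):
            assign_tag_id(
                MateAlignment("chr3", 2_801, 2_850), site_index, taqi, model,
                role="distal",
            )


class TestPairToDitag:
    def _pair(self, m1, m2):
        return AlignedPair("p", m1, m2)

    def test_reference_structure_pair(self, site_index, taqi, model):
        # anchor at cut of site 2, distal 150 bp inside the other end
        pair = self._pair(
            MateAlignment("chr3", 2_001, 2_050),
            MateAlignment("chr3", 2_801, 2_850, "-"),
        )
        ditag, reason = pair_to_ditag(pair, {"chr3": site_index}, taqi, model)
        assert reason == "ok"
        assert (ditag.left_serial, ditag.right_serial, ditag.skip) == (2, 3, 0)
        assert ditag.is_reference_type

    def test_skipping_pair_reports_skip(self, site_index, taqi, model):
        # anchor at site 1's cut, distal near site 5's cut: skips 2,3,4
        pair = self._pair(
            MateAlignment("chr3", 1_001, 1_050),
            MateAlignment("chr3", 4_801, 4_850, "-"),
        )
        ditag, reason = pair_to_ditag(pair, {"chr3": site_index}, taqi, model)
        assert reason == "ok"
        assert (ditag.left_serial, ditag.right_serial, ditag.skip) == (1, 5, 3)

    def test_anchor_may_sit_on_either_mate(self, site_index, taqi, model):
        pair = self._pair(
            MateAlignment("chr3", 2_151, 2_200),      # distal (150 into frag)
            MateAlignment("chr3", 2_951, 3_000, "-"),  # anchor at cut 3000
        )
        ditag, reason = pair_to_ditag(pair, {"chr3": site_index}, taqi, model)
        assert reason == "ok"
        assert (ditag.left_serial, ditag.right_serial) == (2, 3)

    def test_cross_chromosome_pair_is_discarded(self, site_index, taqi, model):
        pair = self._pair(
            MateAlignment("chr1", 2_001, 2_050),
            MateAlignment("chr3", 2_801, 2_850),
        )
        assert pair_to_ditag(pair, {"chr3": site_index}, taqi, model) == (
            None, "cross_chrom",
        )

    def test_unanchored_pair_is_discarded(self, site_index, taqi, model):
        pair = self._pair(
            MateAlignment("chr3", 2_400, 2_449),
            MateAlignment("chr3", 2_600, 2_649),
        )
        assert pair_to_ditag(pair, {"chr3": site_index}, taqi, model) == (
            None, "unanchored",
        )


class TestDitagIdentity:
    def test_worked_id_example(self):
        # #A-N-2 with #A-(N+4)-1 skips three consecutive sites
        ditag = Ditag("chr3", 25, 26)
        assert str(ditag.left_tag) == "3_25_2"
        assert str(ditag.right_tag) == "3_26_1"
        assert ditag.skip == 0
        assert Ditag("chrA", 7, 11).skip == 3

    def test_table_dialect_round_trip(self):
        ditag = parse_ditag_id("7_50712_2/7_50719_1")
        assert (ditag.chrom, ditag.left_serial, ditag.right_serial) == (
            "chr7", 50_712, 50_719,
        )
        assert ditag.skip == 6
        assert ditag.ditag_id == "7_50712_2/7_50719_1"

    def test_malformed_ids_rejected(self):
        with pytest.raises(ValueError):
            parse_ditag_id("7_1_2/8_5_1")  # cross-chromosome
        with pytest.raises(ValueError):
            parse_ditag_id("7_1_1/7_5_2")  # wrong sides
        with pytest.raises(ValueError):
            Ditag("chr1", 5, 5)  # zero serial difference


class TestClusterDitags:
    def test_identical_ditags_collapse(self):
        clusters = cluster_ditags(
            [Ditag("chr1", 3, 5), Ditag("chr1", 3, 5), Ditag("chr1", 1, 2)]
        )
        assert [(d.key, d.support) for d in clusters] == [
            (("chr1", 1, 2), 1), (("chr1", 3, 5), 2),
        ]

    def test_empty_stream(self):
        assert cluster_ditags([]) == []


class TestSimulatedExtraction:
    def test_round_trip_reproduces_planted_multiset(self, hom_sim, taqi, tmp_path):
        """Simulator -> SAM -> extraction returns exactly the emitted
        molecule multiset when noise is off."""
        sam = tmp_path / "pairs.sam"
        write_sam(hom_sim.pairsim.pairs, hom_sim.bundle.genome, str(sam))
        result = extract_ditags(
            pairs_from_sam(str(sam)), hom_sim.bundle.site_indexes, taqi, dedup=False
        )
        observed = Counter({d.key: d.support for d in result.clusters})
        assert observed == hom_sim.pairsim.expected_ditags
        assert result.counters["pairs_total"] == hom_sim.pairsim.counters["emitted"]

    def test_counters_reconcile_and_normalization(self, mixed_sim, taqi, tmp_path):
        sam = tmp_path / "pairs.sam"
        write_sam(mixed_sim.pairsim.pairs, mixed_sim.bundle.genome, str(sam))
        result = extract_ditags(
            pairs_from_sam(str(sam)), mixed_sim.bundle.site_indexes, taqi
        )
        assert result.reconciles()
        for d in result.clusters:
            assert d.left_tag.side == 2
            assert d.right_tag.side == 1
            assert d.right_serial > d.left_serial
            assert d.support >= 1


class TestSummarize:
    def _catalog(self, hom_sim, taqi):
        frags = [
            f
            for c, seq in sorted(hom_sim.bundle.genome.items())
            for f in digest(hom_sim.bundle.site_indexes[c], len(seq), taqi)
        ]
        return ref_ditag_catalog(frags)

    def test_all_observed_once(self, hom_sim, taqi):
        catalog = self._catalog(hom_sim, taqi)
        clusters = [
            Ditag(r.chrom, r.left_tag.serial, r.right_tag.serial) for r in catalog
        ]
        genome_size = sum(len(s) for s in hom_sim.bundle.genome.values())
        summary = summarize_ditags(clusters, catalog, genome_size)
        assert summary.fraction_observed == 1.0
        assert summary.mean_depth == 1.0

    def test_no_clusters_is_zeroed(self, hom_sim, taqi):
        catalog = self._catalog(hom_sim, taqi)
        summary = summarize_ditags([], catalog, 200_000)
        assert summary.refditags_observed == 0
        assert summary.mean_depth == 0.0
        assert summary.covered_fraction == 0.0

    def test_mean_depth_near_sampling_target(self, taqi, tmp_path):
        """At target depth 8 the observed mean Ref-Ditag depth stays within
        3 standard errors of 8."""
        from ditagdel.simulate import SimConfig, simulate

        sim = simulate(
            SimConfig(seed=31, chrom_length=150_000, n_deletions=0,
                      n_snp_sites=0, partial_digestion=0.0, depth=8.0,
                      size_bias=False)
        )
        sam = tmp_path / "pairs.sam"
        write_sam(sim.pairsim.pairs, sim.bundle.genome, str(sam))
        result = extract_ditags(
            pairs_from_sam(str(sam)), sim.bundle.site_indexes, taqi, dedup=False
        )
        catalog = self._catalog(sim, taqi)
        summary = summarize_ditags(
            result.clusters, catalog, sum(len(s) for s in sim.bundle.genome.values())
        )
        se = np.sqrt(8.0 / summary.refditags_observed)
        assert abs(summary.mean_depth - 8.0) <= 3 * se
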