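from fractions import Fraction

import numpy as np
import pytest

from ditagdel.caller import (
    CallerConfig,
    LocusIndex,
    SnpSet,
    call_deletions,
    deletion_size,
    estimate_true_positives,
    export_primers,
    extrapolate_genome_burden,
    filter_skip_and_snp,
    locus_fraction,
    round_half_away,
    zygosity_guess,
)
from ditagdel.ditags import Ditag, extract_ditags, pairs_from_sam
from ditagdel.epcr import epcr
from ditagdel.restriction import SiteIndex
from ditagdel.simulate import SimConfig, simulate, write_sam


@pytest.fixture()
def site_index():
    return SiteIndex("chr1", np.arange(1_000, 20_001, 1_000))


def extraction_for(sim, taqi, tmp_path, dedup=True):
    sam = tmp_path / "pairs.sam"
    write_sam(sim.pairsim.pairs, sim.bundle.genome, str(sam))
    return extract_ditags(
        pairs_from_sam(str(sam)), sim.bundle.site_indexes, taqi, dedup=dedup
    )


def known_snps(sim):
    return SnpSet([(s.chrom, s.position) for s in sim.truth.snps if s.known])


def truth_flanks(sim):
    return {
        (d.chrom, d.site_serials[0] - 1, d.site_serials[-1] + 1)
        for d in sim.truth.deletions
    }


class TestCriterion1:
    def test_single_site_skip_fails(self, site_index, taqi):
        ok, reason = filter_skip_and_snp(
            Ditag("chr1", 3, 5), site_index, SnpSet(), taqi
        )
        assert not ok and reason == "single-site skip"

    def test_all_skipped_sites_snp_fails(self, site_index, taqi):
        # skipped sites 4 and 5 sit at 4000/5000; SNPs inside both footprints
        snps = SnpSet([("chr1", 4_001), ("chr1", 5_003)])
        ok, reason = filter_skip_and_snp(Ditag("chr1", 3, 6), site_index, snps, taqi)
        assert not ok and reason == "all sites SNP"

    def test_one_non_snp_site_passes(self, site_index, taqi):
        snps = SnpSet([("chr1", 4_001)])
        ok, _ = filter_skip_and_snp(Ditag("chr1", 3, 6), site_index, snps, taqi)
        assert ok

    def test_snp_outside_footprint_does_not_mask(self, site_index, taqi):
        # footprint of site 4 is 4000-4003; a SNP at 4004 is beside it
        snps = SnpSet([("chr1", 4_004), ("chr1", 5_001)])
        ok, _ = filter_skip_and_snp(Ditag("chr1", 3, 6), site_index, snps, taqi)
        assert ok

    def test_empty_snp_set_passes_any_multi_skip(self, site_index, taqi):
        ok, _ = filter_skip_and_snp(Ditag("chr1", 2, 6), site_index, SnpSet(), taqi)
        assert ok


class TestLocusFraction:
    def test_lone_variant_has_fraction_one(self):
        variant = Ditag("chr1", 10, 14, support=5)
        _, total, fraction = locus_fraction(variant, LocusIndex([variant]))
        assert (total, fraction) == (5, 1.0)

    def test_reference_flanks_dilute_fraction(self):
        variant = Ditag("chr1", 10, 14, support=2)
        clusters = [
            variant,
            Ditag("chr1", 10, 11, support=6),  # shares left flank (10, side 2)
            Ditag("chr1", 13, 14, support=4),  # shares right flank (14, side 1)
            Ditag("chr1", 11, 12, support=9),  # inside, shares neither flank
        ]
        support, total, fraction = locus_fraction(variant, LocusIndex(clusters))
        assert (support, total) == (2, 12)
        assert fraction == pytest.approx(2 / 12)
        assert fraction < 0.33  # would be rejected by criterion 4

    def test_shared_both_flanks_counted_once(self):
        variant = Ditag("chr1", 10, 14, support=3)
        other = Ditag("chr1", 10, 14, support=3)  # same key, appears once
        _, total, _ = locus_fraction(variant, LocusIndex([variant]))
        assert total == 3
        del other


class TestZygosity:
    def test_no_internal_reference_signal_is_homozygous(self):
        variant = Ditag("chr1", 10, 14, support=6)
        assert zygosity_guess("chr1", 10, 14, 6, LocusIndex([variant])) == "homozygous"

    def test_balanced_alleles_are_heterozygous(self):
        clusters = [
            Ditag("chr1", 10, 14, support=3),
            Ditag("chr1", 10, 11, support=2),  # reference allele at the locus
            Ditag("chr1", 13, 14, support=1),
        ]
        assert zygosity_guess("chr1", 10, 14, 3, LocusIndex(clusters)) == "heterozygous"

    def test_internal_reference_ditag_forces_heterozygous(self):
        clusters = [
            Ditag("chr1", 10, 14, support=6),
            Ditag("chr1", 11, 12, support=1),  # reference fragment inside span
        ]
        assert zygosity_guess("chr1", 10, 14, 6, LocusIndex(clusters)) == "heterozygous"

    def test_flank_sharing_variant_noise_does_not_flip_zygosity(self):
        # partial-digestion skip-1 ditags share a flank but carry no
        # reference-allele information inside the span
        clusters = [
            Ditag("chr1", 10, 14, support=4),
            Ditag("chr1", 8, 10, support=3),   # noise left of the locus
            Ditag("chr1", 14, 16, support=3),  # noise right of the locus
        ]
        assert zygosity_guess("chr1", 10, 14, 4, LocusIndex(clusters)) == "homozygous"

    def test_simulated_concordance_at_depth_eight(self, taqi, tmp_path):
        """Zygosity guesses agree with planted truth for >= 90% of calls."""
        sim = simulate(
            SimConfig(seed=47, chrom_length=400_000, n_deletions=12,
                      hom_fraction=0.5, n_snp_sites=0, depth=8.0)
        )
        extraction = extraction_for(sim, taqi, tmp_path)
        calls, _ = call_deletions(
            extraction.clusters, sim.bundle.site_indexes, known_snps(sim),
            sim.bundle.genome, CallerConfig(), taqi,
        )
        truth = {
            (d.chrom, d.site_serials[0] - 1, d.site_serials[-1] + 1): d.zygosity
            for d in sim.truth.deletions
        }
        matched = [
            c for c in calls if (c.chrom, c.left_serial, c.right_serial) in truth
        ]
        # heterozygous deletions sampled at half depth under the size bias
        # legitimately drop below the support/fraction thresholds at times
        assert len(matched) >= 6
        agree = sum(
            c.zygosity == truth[(c.chrom, c.left_serial, c.right_serial)]
            for c in matched
        )
        assert agree / len(matched) >= 0.9


class TestCallDeletions:
    def test_exact_recovery_of_planted_homozygous_deletions(
        self, hom_sim, taqi, tmp_path
    ):
        extraction = extraction_for(hom_sim, taqi, tmp_path)
        calls, rejected = call_deletions(
            extraction.clusters, hom_sim.bundle.site_indexes, SnpSet(),
            hom_sim.bundle.genome, CallerConfig(), taqi,
        )
        assert {
            (c.chrom, c.left_serial, c.right_serial) for c in calls
        } == truth_flanks(hom_sim)
        # criterion completeness: every variant cluster lands in exactly one
        # of {called, rejected}
        variants = [d for d in extraction.clusters if d.skip >= 1]
        assert len(variants) == len(calls) + len(rejected)

    def test_bounds_nest_and_sizes_are_inclusive(self, hom_sim, taqi, tmp_path):
        extraction = extraction_for(hom_sim, taqi, tmp_path)
        calls, _ = call_deletions(
            extraction.clusters, hom_sim.bundle.site_indexes, SnpSet(),
            hom_sim.bundle.genome, CallerConfig(), taqi,
        )
        by_flanks = {(c.chrom, c.left_serial, c.right_serial): c for c in calls}
        for d in hom_sim.truth.deletions:
            call = by_flanks[(d.chrom, d.site_serials[0] - 1, d.site_serials[-1] + 1)]
            assert call.outer_start <= call.inner_start <= call.inner_end <= call.outer_end
            # the planted deletion lies inside the outer bounds
            assert call.outer_start <= d.start <= d.end <= call.outer_end
            # and covers the skipped-site footprints (inner bounds)
            assert d.start <= call.inner_start and call.inner_end <= d.end

    def test_support_one_candidate_rejected(self, site_index, taqi):
        clusters = [Ditag("chr1", 3, 6, support=1)]
        calls, rejected = call_deletions(
            clusters, {"chr1": site_index}, SnpSet(), None,
            CallerConfig(epcr_enabled=False), taqi,
        )
        assert calls == []
        assert rejected == [(clusters[0], "criterion2:support")]

    def test_epcr_requires_genome(self, site_index, taqi):
        with pytest.raises(ValueError):
            call_deletions([], {"chr1": site_index}, SnpSet(), None,
                           CallerConfig(epcr_enabled=True), taqi)

    def test_duplicated_locus_rejected_by_epcr(self, taqi, tmp_path):
        """A variant ditag whose tags sit in a two-copy repeat fails the
        single-product test (criterion 3)."""
        sim = simulate(
            SimConfig(seed=5, chrom_length=150_000, n_deletions=0,
                      n_snp_sites=0, n_duplications=1, partial_digestion=0.0)
        )
        dup = sim.bundle.duplications[0]
        s = dup.src_left_serial  # block spans fragments s..s+2 (3 fragments)
        clusters = [Ditag(dup.chrom, s, s + 3, support=5)]
        calls, rejected = call_deletions(
            clusters, sim.bundle.site_indexes, SnpSet(), sim.bundle.genome,
            CallerConfig(), taqi,
        )
        assert calls == []
        assert rejected[0][1] == "criterion3:epcr"

    def test_raising_thresholds_never_adds_calls(self, mixed_sim, taqi, tmp_path):
        extraction = extraction_for(mixed_sim, taqi, tmp_path)

        def call_set(**kw):
            calls, _ = call_deletions(
                extraction.clusters, mixed_sim.bundle.site_indexes,
                known_snps(mixed_sim), mixed_sim.bundle.genome,
                CallerConfig(epcr_enabled=False, **kw), taqi,
            )
            return {(c.chrom, c.left_serial, c.right_serial) for c in calls}

        base = call_set()
        assert call_set(min_support=3) <= base
        assert call_set(min_skip=3) <= base
        assert call_set(fraction_threshold=0.5) <= base


class TestConfounders:
    def test_adjacent_known_snp_pair_never_called(self, taqi, tmp_path):
        """Two adjacent point-mutated sites, both in the SNP set, mimic a
        skip-2 ditag but are rejected by criterion 1."""
        sim = simulate(
            SimConfig(seed=61, chrom_length=150_000, n_deletions=0,
                      n_snp_sites=0, adjacent_snp_pairs=2,
                      adjacent_pairs_known=True, partial_digestion=0.0,
                      depth=8.0, size_bias=False)
        )
        extraction = extraction_for(sim, taqi, tmp_path)
        assert any(d.skip == 2 for d in extraction.clusters)  # confounder seen
        calls, rejected = call_deletions(
            extraction.clusters, sim.bundle.site_indexes, known_snps(sim),
            sim.bundle.genome, CallerConfig(), taqi,
        )
        assert calls == []
        assert any(r == "criterion1:all sites SNP" for _, r in rejected)

    def test_novel_site_loss_is_the_known_failure_mode(self, taqi, tmp_path):
        """Destroying two adjacent sites *not* in the SNP set can yield a
        call: the published method's documented false-positive mode."""
        sim = simulate(
            SimConfig(seed=61, chrom_length=150_000, n_deletions=0,
                      n_snp_sites=0, adjacent_snp_pairs=2,
                      adjacent_pairs_known=False, partial_digestion=0.0,
                      depth=8.0, size_bias=False)
        )
        extraction = extraction_for(sim, taqi, tmp_path)
        calls, _ = call_deletions(
            extraction.clusters, sim.bundle.site_indexes, known_snps(sim),
            sim.bundle.genome, CallerConfig(), taqi,
        )
        assert len(calls) >= 1

    def test_forced_partial_digestion_rejected_as_single_skip(self, taqi, tmp_path):
        sim = simulate(
            SimConfig(seed=71, chrom_length=100_000, n_deletions=0,
                      n_snp_sites=0, partial_digestion=0.0,
                      partial_site_overrides={("chr1", 40): 1.0}, depth=8.0)
        )
        extraction = extraction_for(sim, taqi, tmp_path)
        assert any(
            d.left_serial < 40 < d.right_serial and d.skip >= 1
            for d in extraction.clusters
        )
        calls, rejected = call_deletions(
            extraction.clusters, sim.bundle.site_indexes, SnpSet(),
            sim.bundle.genome, CallerConfig(), taqi,
        )
        assert calls == []
        assert any(r.startswith("criterion1") for _, r in rejected)


class TestArithmetic:
    def test_table_breakpoint_sizes(self):
        assert deletion_size(193_768, 197_057) == 3_290
        assert deletion_size(96_313_845, 96_319_938) == 6_094
        assert deletion_size(5, 5) == 1
        with pytest.raises(ValueError):
            deletion_size(10, 9)

    def test_true_positive_scaling(self):
        est = estimate_true_positives(175, 18, 19)
        assert est == pytest.approx(165.789, abs=1e-3)
        assert round_half_away(est) == 166
        assert estimate_true_positives(42, 7, 7) == 42
        assert estimate_true_positives(100, 0, 10) == 0
        with pytest.raises(ValueError):
            estimate_true_positives(10, 5, 0)

    def test_burden_extrapolation_full_precision(self):
        est = estimate_true_positives(175, 18, 19)
        burden = extrapolate_genome_burden(est, 0.10, 0.45)
        # exact-fraction oracle: 175*18 / (19 * 0.10 * 0.45)
        oracle = Fraction(175 * 18, 19) / (Fraction(1, 10) * Fraction(45, 100))
        assert burden == pytest.approx(float(oracle))
        assert round_half_away(burden) == 3_684
        assert extrapolate_genome_burden(12.5, 1.0, 1.0) == 12.5
        with pytest.raises(ValueError):
            extrapolate_genome_burden(10, 0.0, 0.5)


class TestPrimerExport:
    def test_primers_match_planted_tag_sequences(self, hom_sim, taqi, tmp_path):
        extraction = extraction_for(hom_sim, taqi, tmp_path)
        calls, _ = call_deletions(
            extraction.clusters, hom_sim.bundle.site_indexes, SnpSet(),
            hom_sim.bundle.genome, CallerConfig(), taqi,
        )
        table = export_primers(
            calls, hom_sim.bundle.genome, hom_sim.bundle.site_indexes, taqi
        )
        assert len(table) == len(calls)
        for call, row in zip(calls, table.itertuples()):
            seq = hom_sim.bundle.genome[call.chrom]
            c_left = hom_sim.bundle.site_indexes[call.chrom].cut(
                call.left_serial, taqi
            )
            assert row.forward == seq[c_left : c_left + 30]
            assert len(row.reverse) == 30
            assert row.mutant_span_max < row.reference_span

    def test_primers_amplify_single_product_on_deleted_haplotype(
        self, hom_sim, taqi, tmp_path
    ):
        """Re-feeding exported primers to ePCR against the deleted haplotype
        yields exactly one (junction-spanning) product."""
        extraction = extraction_for(hom_sim, taqi, tmp_path)
        calls, _ = call_deletions(
            extraction.clusters, hom_sim.bundle.site_indexes, SnpSet(),
            hom_sim.bundle.genome, CallerConfig(), taqi,
        )
        table = export_primers(
            calls, hom_sim.bundle.genome, hom_sim.bundle.site_indexes, taqi
        )
        hap = hom_sim.haplotypes[0]  # all deletions are homozygous
        for row in table.itertuples():
            products = epcr(row.forward, row.reverse, hap)
            assert len(products) == 1
            assert products[0].size <= row.mutant_span_max

    def test_zero_tag_length_rejected(self, hom_sim, taqi):
        with pytest.raises(ValueError):
            export_primers([], hom_sim.bundle.genome,
                           hom_sim.bundle.site_indexes, taqi, tag_length=0)
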