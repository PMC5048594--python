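"""Meta-region classification, conservation, region overlap, regulatory potential."""

import math

import numpy as np
import pytest

from peakqc.core import GenomicInterval
from peakqc.annotation_layer import (
    GeneModel,
    classify_summits,
    conservation_profile,
    read_gene_table,
    region_overlap_ratio,
    regulatory_potential,
    summit_positions,
    top_peaks,
)

from conftest import make_peak


def _gene(gene_id="g1", chrom="chr1", strand="+", tx=(5000, 15000), exons=None):
    if exons is None:
        # first and last kilobase of the transcript are exonic
        exons = [(tx[0], tx[0] + 1000), (tx[1] - 1000, tx[1])]
    exon_ivs = tuple(GenomicInterval(chrom, s, e) for s, e in exons)
    return GeneModel(gene_id, chrom, strand, tx[0], tx[1], exon_ivs)


class TestSummits:
    def test_offset_and_midpoint_rules(self):
        peaks = [
            make_peak("chr1", 100, 200, offset=50),
            make_peak("chr1", 100, 200),  # broad: midpoint
        ]
        assert summit_positions(peaks) == [("chr1", 150), ("chr1", 150)]

    def test_tss_is_strand_aware(self):
        assert _gene(strand="+").tss == 5000
        assert _gene(strand="-").tss == 14999


class TestClassifySummits:
    def test_promoter_precedence_over_exon(self):
        # TSS 5000 sits inside the first exon; promoter must win
        g = _gene()
        dist = classify_summits([("chr1", 5000)], [g])
        assert dist.promoter == 1.0

    def test_chrom_without_genes_is_intergenic(self):
        dist = classify_summits([("chr9", 100)], [_gene()])
        assert dist.intergenic == 1.0

    def test_intron_between_exons(self):
        dist = classify_summits([("chr1", 10_000)], [_gene()])
        assert dist.intron == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            classify_summits([], [_gene()])

    def test_matches_linear_scan_oracle(self, rng):
        genes = [
            _gene("g1", tx=(5000, 15000), exons=[(5000, 6000), (9000, 9500)]),
            _gene("g2", strand="-", tx=(40_000, 52_000),
                  exons=[(40_000, 41_000), (51_000, 52_000)]),
        ]
        summits = [("chr1", int(p)) for p in rng.integers(0, 60_000, size=1000)]

        def oracle_label(pos):
            for g in genes:
                if abs(pos - g.tss) <= 2000:
                    return "promoter"
            for g in genes:
                if any(e.start <= pos < e.end for e in g.exons):
                    return "exon"
            for g in genes:
                if g.tx_start <= pos < g.tx_end:
                    return "intron"
            return "intergenic"

        from collections import Counter

        expected = Counter(oracle_label(p) for _, p in summits)
        dist = classify_summits(summits, genes)
        for label in ("promoter", "exon", "intron", "intergenic"):
            assert getattr(dist, label) == pytest.approx(
                expected[label] / 1000
            )
        assert sum(dist.as_dict().values()) == pytest.approx(1.0, abs=1e-9)

    def test_permutation_invariance(self, rng):
        genes = [_gene()]
        summits = [("chr1", int(p)) for p in rng.integers(0, 20_000, 200)]
        d1 = classify_summits(summits, genes)
        d2 = classify_summits(list(reversed(summits)), genes)
        assert d1.as_dict() == d2.as_dict()


class TestTopPeaks:
    def test_sorted_by_score_descending(self):
        peaks = [make_peak("chr1", i * 100, i * 100 + 10, score=s)
                 for i, s in enumerate([5, 9, 7])]
        assert [p.score for p in top_peaks(peaks, 2)] == [9, 7]

    def test_n_larger_than_set(self):
        peaks = [make_peak("chr1", 0, 10, score=1)]
        assert top_peaks(peaks, 5000) == peaks

    def test_ties_break_by_coordinate(self):
        peaks = [
            make_peak("chr2", 50, 60, score=7),
            make_peak("chr1", 90, 95, score=7),
            make_peak("chr1", 10, 20, score=7),
        ]
        out = top_peaks(peaks, 3)
        assert [(p.chrom, p.start) for p in out] == [
            ("chr1", 10), ("chr1", 90), ("chr2", 50)
        ]


class TestRegionOverlap:
    def test_all_inside(self):
        peaks = [make_peak("chr1", i * 10, i * 10 + 5) for i in range(10)]
        assert region_overlap_ratio(peaks, [GenomicInterval("chr1", 0, 200)]) == 1.0

    def test_constructed_sixty_percent(self):
        peaks = [make_peak("chr1", i * 100, i * 100 + 50) for i in range(100)]
        regions = [GenomicInterval("chr1", i * 100, i * 100 + 50)
                   for i in range(60)]
        assert region_overlap_ratio(peaks, regions) == pytest.approx(0.600)

    def test_abutting_region_excluded(self):
        peaks = [make_peak("chr1", 100, 200)]
        assert region_overlap_ratio(peaks, [GenomicInterval("chr1", 200, 300)]) == 0.0

    def test_monotone_under_growing_regions(self, rng):
        peaks = [make_peak("chr1", int(p), int(p) + 20)
                 for p in rng.integers(0, 5000, 50)]
        small = [GenomicInterval("chr1", 0, 1000)]
        big = small + [GenomicInterval("chr1", 3000, 4000)]
        assert region_overlap_ratio(peaks, big) >= region_overlap_ratio(peaks, small)

    def test_empty_peaks_error(self):
        with pytest.raises(ValueError):
            region_overlap_ratio([], [GenomicInterval("chr1", 0, 10)])


def _dense_track(chrom, lo, hi, fn):
    pos = np.arange(lo, hi)
    return {chrom: (pos, pos + 1, np.array([fn(p) for p in pos], dtype=float))}


class TestConservationProfile:
    def test_constant_track_gives_flat_profile(self):
        track = _dense_track("chr1", 0, 2000, lambda p: 0.7)
        prof = conservation_profile([("chr1", 1000)], track, flank=500, bin_size=50)
        assert np.allclose(prof.values, 0.7)

    def test_single_summit_reproduces_triangular_bump(self):
        center = 1000
        track = _dense_track(
            "chr1", 0, 2000, lambda p: max(0.0, 1.0 - abs(p - center) / 100)
        )
        prof = conservation_profile([("chr1", center)], track, flank=200, bin_size=1)
        expected = np.array(
            [max(0.0, 1.0 - abs(off) / 100) for off in range(-200, 200)]
        )
        assert np.allclose(prof.values, expected)

    def test_matches_direct_mean_oracle(self, rng):
        values = rng.random(5000)
        pos = np.arange(5000)
        track = {"chr1": (pos, pos + 1, values)}
        summits = [("chr1", int(p)) for p in rng.integers(400, 4600, size=100)]
        prof = conservation_profile(summits, track, flank=400, bin_size=40)
        width = 800
        windows = np.stack([values[p - 400 : p + 400] for _, p in summits])
        oracle = windows.mean(axis=0).reshape(-1, 40).mean(axis=1)
        assert np.allclose(prof.values, oracle, atol=1e-12)

    def test_symmetric_track_gives_symmetric_profile(self):
        # the window covers offsets [-flank, flank), so its discrete mirror
        # center is the half-integer between the two central bases
        track = _dense_track(
            "chr1", 0, 4000, lambda p: math.exp(-((p - 1999.5) ** 2) / 5000.0)
        )
        prof = conservation_profile([("chr1", 2000)], track, flank=400, bin_size=50)
        assert np.allclose(prof.values, prof.values[::-1], atol=1e-12)

    def test_edge_truncation_tallied_and_zero_padded(self):
        track = _dense_track("chr1", 0, 300, lambda p: 1.0)
        prof = conservation_profile(
            [("chr1", 100)], track, flank=200, bin_size=100,
            chrom_sizes={"chr1": 300},
        )
        assert prof.n_truncated == 1
        # first bin covers offsets [-200,-100): fully off-chromosome -> 0
        assert prof.values[0] == 0.0

    def test_no_summits_errors(self):
        with pytest.raises(ValueError):
            conservation_profile([], {}, flank=100, bin_size=10)


class TestRegulatoryPotential:
    def test_peak_at_tss_scores_exp_minus_half(self):
        g = _gene()
        pk = make_peak("chr1", 4900, 5100, offset=100)  # summit exactly at TSS
        rp = regulatory_potential([pk], [g])
        assert rp.scores["g1"] == pytest.approx(math.exp(-0.5))

    def test_hard_cutoff_beyond_max_dist(self):
        g = _gene()  # TSS 5000
        pk = make_peak("chr1", 105_000, 105_003, offset=1)  # d = 100_001
        rp = regulatory_potential([pk], [g])
        assert rp.scores["g1"] == 0.0

    def test_hand_summed_toy(self):
        genes = [
            _gene("gA", tx=(100_000, 110_000)),
            _gene("gB", strand="-", tx=(190_000, 200_001)),
        ]
        # summits at known distances from TSSs (gA: 100_000, gB: 200_000)
        summit_pos = [100_000, 110_000, 150_000, 199_000, 260_000]
        peaks = [make_peak("chr1", s - 10, s + 10, offset=10) for s in summit_pos]
        rp = regulatory_potential(peaks, genes)

        def w(d):
            return math.exp(-(0.5 + 4 * d / 100_000))

        # gA TSS 100_000: distances 0, 10k, 50k, 99k (160k beyond cutoff)
        assert rp.scores["gA"] == pytest.approx(w(0) + w(10_000) + w(50_000) + w(99_000))
        # gB TSS 200_000: distances 100k (inclusive cutoff), 90k, 50k, 1k, 60k
        assert rp.scores["gB"] == pytest.approx(
            w(100_000) + w(90_000) + w(50_000) + w(1_000) + w(60_000)
        )

    def test_additive_over_disjoint_peak_sets(self, rng):
        g = _gene("gX", tx=(50_000, 60_000))
        all_pos = rng.integers(0, 150_000, size=40)
        peaks = [make_peak("chr1", int(p), int(p) + 20, offset=10) for p in all_pos]
        p1, p2 = peaks[:25], peaks[25:]
        s_all = regulatory_potential(peaks, [g]).scores["gX"]
        s1 = regulatory_potential(p1, [g]).scores["gX"]
        s2 = regulatory_potential(p2, [g]).scores["gX"]
        assert s_all == pytest.approx(s1 + s2)

    def test_multi_transcript_gene_takes_max(self):
        t1 = _gene("g1", tx=(5000, 15000))
        t2 = _gene("g1", tx=(100_000, 120_000))
        pk = make_peak("chr1", 4900, 5100, offset=100)  # on t1's TSS only
        rp = regulatory_potential([pk], [t1, t2])
        assert rp.scores["g1"] == pytest.approx(math.exp(-0.5))

    def test_ranked_descending(self):
        genes = [_gene("near", tx=(5000, 9000)), _gene("far", tx=(500_000, 501_000))]
        pk = make_peak("chr1", 4950, 5050, offset=50)
        assert regulatory_potential([pk], genes).ranked()[0][0] == "near"


class TestGeneTable:
    def test_round_trip_parse(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text(
            "g1\tchr1\t+\t5000\t15000\t5000,14000\t6000,15000\n"
            "g2\tchr2\t-\t100\t900\t\t\n"
        )
        genes = read_gene_table(p)
        assert genes[0].tss == 5000 and len(genes[0].exons) == 2
        assert genes[1].tss == 899 and genes[1].exons == ()
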