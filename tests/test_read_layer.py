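"""Base quality, mapping ratio, subsampling, and library complexity."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from peakqc.core import AlignedRead, ReadTable
from peakqc.read_layer import (
    compute_nrf,
    compute_pbc,
    contamination_screen,
    location_counts,
    median_base_quality,
    subsample_reads,
    uniquely_mapped,
)
from peakqc.synthetic import SimulationSpec, exact_match_mapper, simulate_fastq, simulate_library

from conftest import make_reads, write_fastq


# ---------------------------------------------------------------------------
# median base quality
# ---------------------------------------------------------------------------

class TestMedianQuality:
    def test_constant_quality_read(self, tmp_path):
        p = write_fastq(tmp_path / "a.fastq", [("ACGT", "IIII")])  # Q40
        assert median_base_quality(p) == 40

    def test_lower_median_on_even_count(self, tmp_path):
        # qualities 10, 20, 30, 40 -> lower median 20
        p = write_fastq(tmp_path / "a.fastq", [("ACGT", "+5?I")])
        assert median_base_quality(p) == 20

    def test_large_constant_quality_sample(self, tmp_path):
        text = simulate_fastq(10_000, read_length=20, quality=25, seed=3)
        p = tmp_path / "c.fastq"
        p.write_text(text)
        assert median_base_quality(p, sample_n=2000, seed=7) == 25

    def test_per_read_median(self, tmp_path):
        p = write_fastq(
            tmp_path / "a.fastq", [("AC", "II"), ("AC", "++"), ("AC", "55")]
        )
        assert median_base_quality(p, per_read=True) == 20

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "e.fastq"
        p.write_text("")
        with pytest.raises(ValueError, match="empty"):
            median_base_quality(p)

    def test_non_phred33_quality_errors(self, tmp_path):
        p = write_fastq(tmp_path / "a.fastq", [("AC", "I ")])  # space < '!'
        with pytest.raises(ValueError, match="Phred"):
            median_base_quality(p)


# ---------------------------------------------------------------------------
# uniquely mapped ratio
# ---------------------------------------------------------------------------

class TestUniquelyMapped:
    def test_threshold_is_strictly_greater(self):
        reads = make_reads(
            [("chr1", i, "+", q) for i, q in enumerate([0, 1, 2, 30])],
            n_total=4,
        )
        assert uniquely_mapped(reads) == (2, 0.5)

    def test_all_high_quality(self):
        reads = make_reads([("chr1", i, "+", 60) for i in range(8)])
        assert uniquely_mapped(reads) == (8, 1.0)

    def test_mapq_255_means_unavailable_and_passes(self):
        reads = make_reads([("chr1", 1, "+", 255)], n_total=1)
        assert uniquely_mapped(reads) == (1, 1.0)

    def test_exact_ratio_on_constructed_mixture(self):
        reads = make_reads(
            [("chr1", i, "+", 30) for i in range(700)]
            + [("chr1", i, "+", 0) for i in range(300)]
        )
        count, ratio = uniquely_mapped(reads)
        assert (count, ratio) == (700, 0.700)

    def test_empty_library_errors(self):
        with pytest.raises(ValueError, match="empty"):
            uniquely_mapped(make_reads([]), total_reads=0)


# ---------------------------------------------------------------------------
# fixed-depth subsampling
# ---------------------------------------------------------------------------

class TestSubsample:
    def test_small_library_returned_whole_with_flag(self):
        reads = make_reads([("chr1", i) for i in range(10)])
        sample, below = subsample_reads(reads, n=4_000_000, seed=1)
        assert len(sample) == 10 and below is True

    def test_exact_size_is_identity(self):
        reads = make_reads([("chr1", i) for i in range(50)])
        sample, below = subsample_reads(reads, n=50, seed=1)
        assert below is False
        assert sorted(sample.pos5) == sorted(reads.pos5)

    def test_seed_stability_and_sampling_law(self):
        n_lib, n_sub = 100_000, 20_000
        reads = make_reads([("chr1", i) for i in range(n_lib)])
        s1, _ = subsample_reads(reads, n=n_sub, seed=5)
        s2, _ = subsample_reads(reads, n=n_sub, seed=5)
        assert np.array_equal(s1.pos5, s2.pos5)
        s3, _ = subsample_reads(reads, n=n_sub, seed=6)
        overlap = len(np.intersect1d(s1.pos5, s3.pos5))
        expected = n_sub * n_sub / n_lib
        sigma = math.sqrt(n_sub * (n_sub / n_lib) * (1 - n_sub / n_lib))
        assert abs(overlap - expected) < 3 * sigma


# ---------------------------------------------------------------------------
# location counts, NRF, PBC
# ---------------------------------------------------------------------------

class TestComplexity:
    def test_strand_separates_locations(self):
        reads = make_reads(
            [("chr1", 100, "+"), ("chr1", 100, "+"), ("chr1", 100, "-")]
        )
        lc = location_counts(reads)
        assert lc.n_locations == 2
        assert sorted(lc.counts) == [1, 2]

    def test_all_distinct_positions(self):
        lc = location_counts(make_reads([("chr1", i) for i in range(17)]))
        assert lc.n_locations == 17 and (lc.counts == 1).all()

    def test_nrf_pbc_on_constructed_counts(self):
        # location multiplicities {1, 1, 2, 3}: NRF = 4/7, PBC = 2/4
        reads = make_reads(
            [("chr1", 10)]
            + [("chr1", 20)]
            + [("chr1", 30)] * 2
            + [("chr1", 40)] * 3
        )
        lc = location_counts(reads)
        assert compute_nrf(lc) == pytest.approx(4 / 7)
        assert compute_pbc(lc) == 0.5

    def test_empty_errors(self):
        lc = location_counts(make_reads([]))
        with pytest.raises(ValueError):
            compute_nrf(lc)
        with pytest.raises(ValueError):
            compute_pbc(lc)

    def test_histogram_matches_generator_bookkeeping(self):
        sim = simulate_library(
            SimulationSpec(seed=21, n_reads=30_000, duplication_lambda=0.8)
        )
        lc = location_counts(sim.reads)
        measured = {}
        for c in lc.counts:
            measured[int(c)] = measured.get(int(c), 0) + 1
        assert measured == sim.truth["count_histogram"]

    def test_truncated_poisson_analytic_recovery(self):
        lam, n_loc = 0.5, 100_000
        sim = simulate_library(
            SimulationSpec(seed=8, n_locations=n_loc, duplication_lambda=lam)
        )
        lc = location_counts(sim.reads)
        p1 = lam * math.exp(-lam) / (1 - math.exp(-lam))  # P(count=1 | >=1)
        sigma_pbc = math.sqrt(p1 * (1 - p1) / n_loc)
        assert abs(compute_pbc(lc) - p1) < 3 * sigma_pbc
        # NRF -> 1/mean(count); delta-method sigma from truncated-Poisson var
        m1 = lam / (1 - math.exp(-lam))
        m2 = (lam + lam**2) / (1 - math.exp(-lam))
        sigma_nrf = math.sqrt(m2 - m1**2) / (m1**2 * math.sqrt(n_loc))
        assert abs(compute_nrf(lc) - 1 / m1) < 3 * sigma_nrf

    def test_order_and_chrom_renaming_invariance(self, rng):
        pos = rng.integers(0, 500, size=300)
        reads = make_reads([("chr1", int(p)) for p in pos])
        shuffled = reads.take(rng.permutation(len(reads)))
        renamed = ReadTable(
            np.array(["scaffold_9"] * len(reads), dtype=object),
            reads.pos5,
            reads.strand,
            reads.mapq,
        )
        base = (compute_nrf(location_counts(reads)), compute_pbc(location_counts(reads)))
        for other in (shuffled, renamed):
            lc = location_counts(other)
            assert (compute_nrf(lc), compute_pbc(lc)) == base


@given(
    st.lists(
        st.tuples(st.integers(0, 30), st.sampled_from("+-")),
        min_size=1,
        max_size=40,
    ),
    st.integers(0, 39),
)
def test_duplicating_a_read_never_increases_complexity(read_specs, which):
    reads = [AlignedRead("chr1", p, s, 30) for p, s in read_specs]
    dup = reads + [reads[which % len(reads)]]
    lc, lc_dup = (
        location_counts(ReadTable.from_records(r)) for r in (reads, dup)
    )
    assert compute_nrf(lc_dup) <= compute_nrf(lc)
    assert compute_pbc(lc_dup) <= compute_pbc(lc)
    # PBC = 1 iff NRF = 1 iff no duplicates
    assert (compute_pbc(lc) == 1.0) == (compute_nrf(lc) == 1.0)


# ---------------------------------------------------------------------------
# contamination screen
# ---------------------------------------------------------------------------

class TestContamination:
    def _genomes(self, rng):
        bases = np.array(list("ACGT"))
        return {
            sp: "".join(rng.choice(bases, size=5000))
            for sp in ("target", "contaminant")
        }

    def test_universal_mapper_maps_everything(self, tmp_path):
        p = tmp_path / "a.fastq"
        p.write_text(simulate_fastq(100, seed=1))
        out = contamination_screen(p, {"any": lambda s: True}, n=50, seed=2)
        assert out == {"any": 1.0}

    def test_exact_mixture_recovered_when_sample_covers_library(
        self, tmp_path, rng
    ):
        genomes = self._genomes(rng)
        text = simulate_fastq(
            1000, read_length=36, seed=5, genomes=genomes,
            mixture={"target": 0.9, "contaminant": 0.1},
        )
        p = tmp_path / "mix.fastq"
        p.write_text(text)
        mappers = {sp: exact_match_mapper(g) for sp, g in genomes.items()}
        # n exceeds the library: all reads used, fractions exact
        out = contamination_screen(p, mappers, n=5000, seed=0)
        assert out["target"] == pytest.approx(0.9)
        assert out["contaminant"] == pytest.approx(0.1)

    def test_empty_mapper_set_errors(self, tmp_path):
        p = tmp_path / "a.fastq"
        p.write_text(simulate_fastq(10, seed=1))
        with pytest.raises(ValueError):
            contamination_screen(p, {})
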