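"""Raw-read and mapping quality metrics.

The layer answers three questions about a sequencing library before any
peak-level analysis: were the base calls good (median Phred quality), did the
reads come from the right genome (uniquely-mapped ratio, contamination
screen), and was the library over-amplified by PCR (NRF and PBC).

Library complexity is measured on *read locations*: the stranded 5' position
of each uniquely mapped read.  With ``L`` distinct locations among ``n``
uniquely mapped reads, of which ``L1`` carry exactly one read,

    NRF = L / n          (non-redundant fraction)
    PBC = L1 / L         (PCR bottleneck coefficient)

Both shrink as sequencing depth grows — deeper libraries revisit locations —
so they are always computed on a fixed-depth subsample (default 4 million
uniquely mapped reads) to keep libraries of different depth comparable.  When
a library has fewer reads than the subsample depth the full library is used
and the result is flagged as below depth.
"""

from __future__ import annotations

from collections.abc import Callable
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ReadTable, as_read_table

__all__ = [
    "LocationCounts",
    "ReadLayerMetrics",
    "median_base_quality",
    "uniquely_mapped",
    "subsample_reads",
    "location_counts",
    "compute_nrf",
    "compute_pbc",
    "contamination_screen",
    "run_read_layer",
]

SUBSAMPLE_DEPTH = 4_000_000
CONTAM_SAMPLE = 100_000
MAPQ_GT = 1


@dataclass
class LocationCounts:
    """Multiset of reads per stranded genomic location.

    ``counts[i]`` is the number of reads at the i-th distinct
    (chrom, pos5, strand) location; ``n_reads`` is their sum.
    """

    counts: np.ndarray
    n_reads: int

    @property
    def n_locations(self) -> int:
        return len(self.counts)


@dataclass
class ReadLayerMetrics:
    median_quality: float | None = None
    total_reads: int = 0
    uniquely_mapped_reads: int = 0
    uniquely_mapped_ratio: float | None = None
    unique_locations: int = 0
    nrf: float | None = None
    pbc: float | None = None
    subsample_depth_used: int = 0
    below_subsample_depth: bool = False
    contamination: dict[str, float] = field(default_factory=dict)


def _read_fastq_sample(path: str | Path, sample_n: int, seed: int) -> list[bytes]:
    """Reservoir-sample up to ``sample_n`` quality strings from a FASTQ file.

    Classic Algorithm R with a seeded generator: seed-stable across runs and
    platforms, single pass, O(sample_n) memory.
    """
    if sample_n < 1:
        raise ValueError("sample_n must be >= 1")
    rng = np.random.default_rng(seed)
    reservoir: list[bytes] = []
    n_seen = 0
    with open(path, "rb") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            if not header.startswith(b"@"):
                raise ValueError(f"{path}: malformed FASTQ header {header[:20]!r}")
            fh.readline()  # sequence
            fh.readline()  # '+'
            qual = fh.readline().rstrip(b"\n")
            if not qual:
                raise ValueError(f"{path}: truncated FASTQ record")
            n_seen += 1
            if len(reservoir) < sample_n:
                reservoir.append(qual)
            else:
                j = rng.integers(0, n_seen)
                if j < sample_n:
                    reservoir[j] = qual
    if n_seen == 0:
        raise ValueError(f"{path}: empty FASTQ file")
    return reservoir


def median_base_quality(
    fastq_path: str | Path,
    sample_n: int = CONTAM_SAMPLE,
    seed: int = 0,
    per_read: bool = False,
) -> float:
    """Median Phred+33 base quality over a reservoir sample of reads.

    With ``per_read=True`` the median is taken over per-read mean qualities
    instead of over the pooled base calls.  Even-sized multisets use the
    lower median (the element at index ``(k-1)//2`` of the sorted values).
    """
    quals = _read_fastq_sample(fastq_path, sample_n, seed)
    arrays = []
    for q in quals:
        arr = np.frombuffer(q, dtype=np.uint8).astype(np.int32) - 33
        if arr.min() < 0:
            raise ValueError(
                f"{fastq_path}: quality character below Phred+33 range"
            )
        arrays.append(arr)
    if per_read:
        values = np.array([a.mean() for a in arrays])
    else:
        values = np.concatenate(arrays)
    values = np.sort(values)
    return float(values[(len(values) - 1) // 2])


def uniquely_mapped(
    reads, mapq_gt: int = MAPQ_GT, total_reads: int | None = None
) -> tuple[int, float]:
    """Count reads with mapping quality strictly above ``mapq_gt``.

    Returns ``(count, count / total_reads)``.  ``total_reads`` defaults to the
    record count of the SAM source (mapped + unmapped primaries).  mapq 255
    means "unavailable" in SAM and is treated as passing.
    """
    table = as_read_table(reads)
    if total_reads is None:
        total_reads = table.n_total
    if total_reads == 0:
        raise ValueError("empty library: total_reads is 0")
    count = len(table.filter_mapq_gt(mapq_gt))
    return count, count / total_reads


def subsample_reads(
    reads, n: int = SUBSAMPLE_DEPTH, seed: int = 0
) -> tuple[ReadTable, bool]:
    """Uniform sample of ``min(n, len(reads))`` reads without replacement.

    Returns ``(sample, below_depth)`` where ``below_depth`` is True when the
    library was smaller than the requested depth and was returned whole.
    Deterministic for a fixed seed: indices are drawn with a seeded
    generator, independent of any hash ordering.
    """
    if n < 1:
        raise ValueError("subsample size must be >= 1")
    table = as_read_table(reads)
    if len(table) <= n:
        return table, len(table) < n
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(table), size=n, replace=False)
    idx.sort()
    return table.take(idx), False


def location_counts(reads) -> LocationCounts:
    """Collapse reads to stranded 5'-position locations with multiplicities.

    The caller is expected to have already filtered to uniquely mapped reads
    and applied the fixed-depth subsample.
    """
    table = as_read_table(reads)
    if len(table) == 0:
        return LocationCounts(np.array([], dtype=np.int64), 0)
    # pack (chrom, pos5, strand) into one int64 key: chrom index in the high
    # bits, position shifted by one, strand in the low bit
    chrom_idx = pd.factorize(table.chrom)[0].astype(np.int64)
    if int(table.pos5.max(initial=0)) >= 1 << 41:
        raise ValueError("positions beyond 2^41 are not supported")
    key = (chrom_idx << 42) | (table.pos5 << 1) | table.strand.astype(np.int64)
    _, counts = np.unique(key, return_counts=True)
    return LocationCounts(counts, len(table))


def compute_nrf(lc: LocationCounts) -> float:
    """Non-redundant fraction: distinct locations over reads counted."""
    if lc.n_reads == 0:
        raise ValueError("cannot compute NRF of an empty read set")
    return lc.n_locations / lc.n_reads


def compute_pbc(lc: LocationCounts) -> float:
    """PCR bottleneck coefficient: single-read locations over all locations."""
    if lc.n_locations == 0:
        raise ValueError("cannot compute PBC with no locations")
    return int((lc.counts == 1).sum()) / lc.n_locations


def contamination_screen(
    fastq_path: str | Path,
    mappers: dict[str, Callable[[bytes], bool]],
    n: int = CONTAM_SAMPLE,
    seed: int = 0,
) -> dict[str, float]:
    """Mapped fraction of a read subsample against several species.

    ``mappers`` maps a species label to a predicate taking a read sequence
    and returning whether it maps to that species' genome.  The predicate is
    deliberately pluggable: a production deployment wires in a real aligner,
    tests wire in an exact-substring matcher.  The *same* subsample of up to
    ``n`` reads is scored against every species so the fractions are
    comparable.  A high fraction for an unexpected species signals a sample
    swap or culture contamination (mycoplasma being the classic offender).
    """
    if not mappers:
        raise ValueError("at least one species mapper is required")
    rng = np.random.default_rng(seed)
    reservoir: list[bytes] = []
    n_seen = 0
    with open(fastq_path, "rb") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip(b"\n")
            fh.readline()
            fh.readline()
            n_seen += 1
            if len(reservoir) < n:
                reservoir.append(seq)
            else:
                j = rng.integers(0, n_seen)
                if j < n:
                    reservoir[j] = seq
    if n_seen == 0:
        raise ValueError(f"{fastq_path}: empty FASTQ file")
    return {
        species: sum(1 for s in reservoir if mapper(s)) / len(reservoir)
        for species, mapper in mappers.items()
    }


def run_read_layer(
    reads,
    fastq_path: str | Path | None = None,
    mappers: dict[str, Callable[[bytes], bool]] | None = None,
    mapq_gt: int = MAPQ_GT,
    subsample_depth: int = SUBSAMPLE_DEPTH,
    contam_sample: int = CONTAM_SAMPLE,
    seed: int = 0,
) -> ReadLayerMetrics:
    """Compute the full read layer for one sample."""
    table = as_read_table(reads)
    m = ReadLayerMetrics(total_reads=table.n_total)
    count, ratio = uniquely_mapped(table, mapq_gt=mapq_gt)
    m.uniquely_mapped_reads = count
    m.uniquely_mapped_ratio = ratio
    unique = table.filter_mapq_gt(mapq_gt)
    if len(unique) > 0:
        sample, below = subsample_reads(unique, n=subsample_depth, seed=seed)
        lc = location_counts(sample)
        m.unique_locations = lc.n_locations
        m.nrf = compute_nrf(lc)
        m.pbc = compute_pbc(lc)
        m.subsample_depth_used = len(sample)
        m.below_subsample_depth = below
    if fastq_path is not None:
        m.median_quality = median_base_quality(
            fastq_path, sample_n=contam_sample, seed=seed
        )
        if mappers:
            m.contamination = contamination_screen(
                fastq_path, mappers, n=contam_sample, seed=seed
            )
    return m
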