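"""Enrichment and reproducibility metrics from peaks and aligned reads.

FRiP — the fraction of (non-mitochondrial) reads falling in peak regions —
is the workhorse signal-to-noise measure of an immunoprecipitation.  Like
library complexity it drifts with sequencing depth, so it is computed on a
fixed 4-million-read subsample; the peaks it is scored against are the calls
made from *all* reads, which keeps the statistic nearly depth-independent.
A read is "in a peak" when its 5' position lies inside the half-open peak
interval.

Replicate agreement is measured two ways: Pearson correlation of
reads-per-million-normalized binned coverage ("wiggle correlation"), and the
fraction of peaks of the larger replicate's set that overlap a peak of the
smaller set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from collections.abc import Sequence

import numpy as np

from .core import MergedIntervals, Peak, SignalTrack, as_read_table
from .read_layer import SUBSAMPLE_DEPTH, subsample_reads

__all__ = [
    "PeakStats",
    "ChipLayerMetrics",
    "MITO_NAMES",
    "peak_census",
    "compute_frip",
    "wiggle_correlation",
    "peak_overlap_consistency",
    "pairwise_consistency",
]

MITO_NAMES = frozenset({"chrM", "MT", "chrMT"})
CORR_BIN = 1000
FC_THRESHOLDS = (10.0, 20.0)


@dataclass
class PeakStats:
    """Peak census: totals and high-confidence counts at >=10x / >=20x fold
    enrichment."""

    n_peaks: int
    n_fc10: int
    n_fc20: int


@dataclass
class ReplicatePair:
    id_a: str
    id_b: str
    wig_correlation: float
    peak_overlap_ratio: float


@dataclass
class ChipLayerMetrics:
    peak_stats: PeakStats | None = None
    frip: float | None = None
    subsample_depth_used: int = 0
    below_subsample_depth: bool = False
    replicate_pairs: list[ReplicatePair] = field(default_factory=list)


def peak_census(
    peaks: Sequence[Peak], thresholds: tuple[float, float] = FC_THRESHOLDS
) -> PeakStats:
    """Count peaks, and peaks exceeding the two fold-enrichment cutoffs."""
    lo, hi = thresholds
    folds = np.array([p.fold_enrichment for p in peaks], dtype=float)
    return PeakStats(
        n_peaks=len(folds),
        n_fc10=int((folds >= lo).sum()),
        n_fc20=int((folds >= hi).sum()),
    )


def compute_frip(
    reads,
    peaks: Sequence[Peak],
    subsample: int = SUBSAMPLE_DEPTH,
    mito_names: frozenset[str] | set[str] = MITO_NAMES,
    seed: int = 0,
) -> tuple[float, int, bool]:
    """Fraction of non-mitochondrial subsampled reads whose 5' position lies
    inside a peak.

    Returns ``(frip, depth_used, below_depth)``.  The subsample is drawn
    before the mitochondrial filter so the depth contract refers to the
    library, matching how the subsample depth is defined for library
    complexity.  An all-mitochondrial subsample is an error; an empty peak
    set yields FRiP 0.0 with a warning (no peaks means no enrichment
    evidence, not a crash).
    """
    table = as_read_table(reads)
    sample, below = subsample_reads(table, n=subsample, seed=seed)
    mito = np.isin(sample.chrom, list(mito_names))
    sample = sample.take(np.flatnonzero(~mito))
    if len(sample) == 0:
        raise ValueError("no non-mitochondrial reads in the subsample")
    if len(peaks) == 0:
        warnings.warn("empty peak set: FRiP reported as 0.0", stacklevel=2)
        return 0.0, len(sample), below
    engine = MergedIntervals([p.interval for p in peaks])
    in_peak = engine.contains_points(sample.chrom, sample.pos5)
    return float(in_peak.mean()), len(sample), below


def wiggle_correlation(track_a: SignalTrack, track_b: SignalTrack) -> float:
    """Pearson correlation of two RPM-normalized binned coverage tracks.

    Each track is scaled to reads per million (1e6 / total signal), the bin
    vectors of all shared chromosomes are concatenated, and plain Pearson r
    is returned.  A flat (zero-variance) track has no defined correlation:
    NaN is returned with a warning rather than silently dropping the pair.
    """
    if track_a.bin_size != track_b.bin_size:
        raise ValueError(
            f"bin sizes differ: {track_a.bin_size} vs {track_b.bin_size}"
        )
    if set(track_a.data) != set(track_b.data):
        raise ValueError("tracks cover different chromosome sets")
    ta, tb = track_a.total_signal, track_b.total_signal
    a = np.concatenate([track_a.data[c] for c in sorted(track_a.data)])
    b = np.concatenate([track_b.data[c] for c in sorted(track_b.data)])
    if ta > 0:
        a = a * (1e6 / ta)
    if tb > 0:
        b = b * (1e6 / tb)
    if a.std() == 0 or b.std() == 0:
        warnings.warn(
            "flat signal track: wiggle correlation undefined (NaN)",
            stacklevel=2,
        )
        return math.nan
    return float(np.corrcoef(a, b)[0, 1])


def peak_overlap_consistency(
    peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]
) -> float:
    """Replicate peak agreement: overlapping peaks of the larger set divided
    by the larger set's size.

    Counting overlaps *of the larger set* keeps numerator and denominator on
    the same set, bounding the ratio in [0, 1].  Ties in set size are broken
    toward the first argument.
    """
    if not peaks_a or not peaks_b:
        raise ValueError("peak overlap consistency needs two non-empty sets")
    if len(peaks_b) > len(peaks_a):
        larger, smaller = peaks_b, peaks_a
    else:
        larger, smaller = peaks_a, peaks_b
    engine = MergedIntervals([p.interval for p in smaller])
    flags = engine.overlaps_intervals(
        [p.chrom for p in larger],
        np.array([p.start for p in larger], dtype=np.int64),
        np.array([p.end for p in larger], dtype=np.int64),
    )
    return float(flags.mean())


def pairwise_consistency(
    replicates: Sequence[tuple[SignalTrack, Sequence[Peak]]],
    ids: Sequence[str] | None = None,
) -> list[ReplicatePair]:
    """Both consistency metrics for every unordered replicate pair.

    ``replicates`` holds one (binned signal track, peak list) per replicate;
    k replicates yield C(k, 2) records.  Fewer than two replicates yield an
    empty list — single-replicate datasets simply have no consistency to
    report.
    """
    if ids is None:
        ids = [f"rep{i + 1}" for i in range(len(replicates))]
    if len(replicates) < 2:
        return []
    out = []
    for i, j in combinations(range(len(replicates)), 2):
        track_i, peaks_i = replicates[i]
        track_j, peaks_j = replicates[j]
        out.append(
            ReplicatePair(
                id_a=ids[i],
                id_b=ids[j],
                wig_correlation=wiggle_correlation(track_i, track_j),
                peak_overlap_ratio=peak_overlap_consistency(peaks_i, peaks_j),
            )
        )
    return out
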