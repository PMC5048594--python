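"""Genomic-context metrics on called peaks.

Where do the peaks sit relative to genes (meta-region distribution of
summits), how conserved is the sequence under them (average per-base
conservation in a ±2 kb window around summits), do the strongest peaks fall
in known regulatory territory (union-DHS overlap of the top peaks) or in
artifact-prone territory (blacklist overlap), and which genes are they most
likely to regulate (distance-weighted regulatory potential)?

Meta-region classification is by precedence: a summit inside a promoter
window is a promoter summit even if it also lies in an exon; promoter >
exon > intron > intergenic.  The promoter is TSS ± 2 kb by default.

The regulatory potential of a gene sums a decaying weight over every peak
whose summit lies within 100 kb of the transcription start site:

    RP(g) = sum over peaks p, d = |summit(p) − TSS(g)| <= D, of w(d/D)

with the default weight w(Δ) = exp(−(0.5 + 4Δ)) and D = 100 kb.  Genes
ranked by RP are the putative targets of the profiled factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from collections.abc import Callable, Sequence

import numpy as np

from .core import FormatError, GenomicInterval, MergedIntervals, Peak

__all__ = [
    "GeneModel",
    "MetaRegionDistribution",
    "ConservationProfile",
    "RegulatoryPotential",
    "read_gene_table",
    "summit_positions",
    "classify_summits",
    "top_peaks",
    "region_overlap_ratio",
    "conservation_profile",
    "regulatory_potential",
    "RP_WEIGHTS",
]

PROMOTER_WINDOW = 2000
CONSERVATION_FLANK = 2000
RP_MAX_DIST = 100_000
TOP_N = 5000


@dataclass(frozen=True)
class GeneModel:
    """One transcript of a gene: TSS, body extent and exon structure."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tx_start >= self.tx_end:
            raise ValueError("tx_start must be < tx_end")
        for ex in self.exons:
            if ex.start < self.tx_start or ex.end > self.tx_end:
                raise ValueError(
                    f"exon [{ex.start},{ex.end}) outside transcript "
                    f"[{self.tx_start},{self.tx_end})"
                )

    @property
    def tss(self) -> int:
        """Transcription start site: tx_start on +, tx_end−1 on −."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


@dataclass
class MetaRegionDistribution:
    promoter: float
    exon: float
    intron: float
    intergenic: float

    def as_dict(self) -> dict[str, float]:
        return {
            "promoter": self.promoter,
            "exon": self.exon,
            "intron": self.intron,
            "intergenic": self.intergenic,
        }


@dataclass
class ConservationProfile:
    """Mean conservation per offset bin in a window centered on summits."""

    flank: int
    bin_size: int
    values: np.ndarray
    n_summits: int
    n_truncated: int = 0
    n_missing_bases: int = 0

    @property
    def offsets(self) -> np.ndarray:
        """Center coordinate of each bin relative to the summit."""
        n = len(self.values)
        return (np.arange(n) * self.bin_size) - self.flank + self.bin_size / 2


@dataclass
class RegulatoryPotential:
    scores: dict[str, float]
    max_dist: int
    weight_id: str

    def ranked(self) -> list[tuple[str, float]]:
        """Genes sorted by descending score (ties by gene id)."""
        return sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a refGene-flat-style TSV: gene_id, chrom, strand, tx_start,
    tx_end, exon_starts, exon_ends (comma-separated, trailing comma allowed)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 5:
                raise FormatError(f"{path}:{lineno}: expected >=5 columns")
            gene_id, chrom, strand = cols[0], cols[1], cols[2]
            tx_start, tx_end = int(cols[3]), int(cols[4])
            exons: tuple[GenomicInterval, ...] = ()
            if len(cols) >= 7 and cols[5].strip(","):
                starts = [int(x) for x in cols[5].strip(",").split(",")]
                ends = [int(x) for x in cols[6].strip(",").split(",")]
                if len(starts) != len(ends):
                    raise FormatError(
                        f"{path}:{lineno}: exon start/end counts differ"
                    )
                exons = tuple(
                    GenomicInterval(chrom, s, e) for s, e in zip(starts, ends)
                )
            try:
                genes.append(
                    GeneModel(gene_id, chrom, strand, tx_start, tx_end, exons)
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return genes


def summit_positions(peaks: Sequence[Peak]) -> list[tuple[str, int]]:
    """Summit of each peak: recorded offset when present, midpoint otherwise."""
    return [(p.chrom, p.summit) for p in peaks]


def classify_summits(
    summits: Sequence[tuple[str, int]],
    genes: Sequence[GeneModel],
    promoter_window: int = PROMOTER_WINDOW,
) -> MetaRegionDistribution:
    """Assign each summit to exactly one meta-region and return fractions.

    Precedence promoter > exon > intron > intergenic; the promoter window is
    TSS ± ``promoter_window`` inclusive of both endpoints.
    """
    if len(summits) == 0:
        raise ValueError("no summits to classify")
    promoters = []
    for g in genes:
        promoters.append(
            GenomicInterval(g.chrom, max(0, g.tss - promoter_window), g.tss + promoter_window + 1)
        )
    exons = [ex for g in genes for ex in g.exons]
    bodies = [GenomicInterval(g.chrom, g.tx_start, g.tx_end) for g in genes]
    chroms = [c for c, _ in summits]
    pos = np.array([p for _, p in summits], dtype=np.int64)
    in_prom = (
        MergedIntervals(promoters).contains_points(chroms, pos)
        if promoters
        else np.zeros(len(pos), dtype=bool)
    )
    in_exon = (
        MergedIntervals(exons).contains_points(chroms, pos)
        if exons
        else np.zeros(len(pos), dtype=bool)
    )
    in_body = (
        MergedIntervals(bodies).contains_points(chroms, pos)
        if bodies
        else np.zeros(len(pos), dtype=bool)
    )
    n = len(pos)
    n_prom = int(in_prom.sum())
    n_exon = int((~in_prom & in_exon).sum())
    n_intron = int((~in_prom & ~in_exon & in_body).sum())
    n_inter = n - n_prom - n_exon - n_intron
    return MetaRegionDistribution(
        promoter=n_prom / n,
        exon=n_exon / n,
        intron=n_intron / n,
        intergenic=n_inter / n,
    )


def top_peaks(peaks: Sequence[Peak], n: int = TOP_N) -> list[Peak]:
    """The ``n`` strongest peaks by score, ties broken by (chrom, start)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(peaks, key=lambda p: (-p.score, p.chrom, p.start))
    return ordered[: min(n, len(ordered))]


def region_overlap_ratio(peaks: Sequence[Peak], regions: Sequence) -> float:
    """Fraction of peaks sharing >=1 bp with a region set.

    Used with the top-peak subset against union DHS (high is good: peaks sit
    in the regulatory repertoire) and against the blacklist (high is bad:
    peaks sit in artifact-prone regions).
    """
    if len(peaks) == 0:
        raise ValueError("region overlap ratio of an empty peak set")
    engine = MergedIntervals(regions)
    flags = engine.overlaps_intervals(
        [p.chrom for p in peaks],
        np.array([p.start for p in peaks], dtype=np.int64),
        np.array([p.end for p in peaks], dtype=np.int64),
    )
    return float(flags.mean())


def conservation_profile(
    summits: Sequence[tuple[str, int]],
    track: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    flank: int = CONSERVATION_FLANK,
    bin_size: int = 50,
    chrom_sizes=None,
) -> ConservationProfile:
    """Average per-base conservation in a ±``flank`` window around summits.

    ``track`` is the output of :func:`peakqc.core.read_bedgraph`.  The window
    covers base offsets ``[-flank, flank)`` relative to each summit (its
    discrete mirror center is the half-integer between the two central
    bases).  Window bases not covered by the track read as 0 and are
    tallied; summits closer
    than ``flank`` to a chromosome edge are zero-padded and counted as
    truncated.  The window is binned into ``2*flank // bin_size`` offset bins.
    """
    if len(summits) == 0:
        raise ValueError("no summits for conservation profile")
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of bin_size")
    width = 2 * flank
    acc = np.zeros(width, dtype=float)
    n_trunc = 0
    n_missing = 0
    for chrom, pos in summits:
        window = np.zeros(width, dtype=float)
        covered = np.zeros(width, dtype=bool)
        lo, hi = pos - flank, pos + flank
        if lo < 0 or (
            chrom_sizes is not None
            and chrom in chrom_sizes
            and hi > chrom_sizes[chrom]
        ):
            n_trunc += 1
        if chrom in track:
            starts, ends, values = track[chrom]
            # intervals intersecting [lo, hi)
            first = int(np.searchsorted(ends, lo, side="right"))
            last = int(np.searchsorted(starts, hi, side="left"))
            for i in range(first, last):
                a = max(int(starts[i]), lo) - lo
                b = min(int(ends[i]), hi) - lo
                if a < b:
                    window[a:b] = values[i]
                    covered[a:b] = True
        if lo < 0:
            covered[: -lo] = True  # off-chromosome padding, not "missing"
        n_missing += int((~covered).sum())
        acc += window
    mean_per_base = acc / len(summits)
    values = mean_per_base.reshape(-1, bin_size).mean(axis=1)
    if n_missing and chrom_sizes is None:
        warnings.warn(
            f"{n_missing} window bases had no conservation value (read as 0)",
            stacklevel=2,
        )
    return ConservationProfile(
        flank=flank,
        bin_size=bin_size,
        values=values,
        n_summits=len(summits),
        n_truncated=n_trunc,
        n_missing_bases=n_missing,
    )


def _cistrome_weight(delta: np.ndarray) -> np.ndarray:
    return np.exp(-(0.5 + 4.0 * delta))


def _exp2_weight(delta: np.ndarray) -> np.ndarray:
    # half-decay at 10% of the cutoff distance
    return np.power(2.0, -delta * 10.0)


def _uniform_weight(delta: np.ndarray) -> np.ndarray:
    return np.ones_like(delta)


RP_WEIGHTS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "cistrome": _cistrome_weight,
    "exp2": _exp2_weight,
    "uniform": _uniform_weight,
}


def regulatory_potential(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    max_dist: int = RP_MAX_DIST,
    weight: str | Callable[[np.ndarray], np.ndarray] = "cistrome",
) -> RegulatoryPotential:
    """Distance-weighted sum of peak summits within ``max_dist`` of each TSS.

    The weight is a non-increasing function of the scaled distance
    Δ = d / max_dist; the default decays as exp(−(0.5 + 4Δ)), so a peak
    sitting exactly on the TSS contributes e^−0.5 ≈ 0.6065.  A gene with
    several transcripts takes the maximum score over its transcript TSSs.
    Genes with no peak within range score 0.
    """
    if isinstance(weight, str):
        weight_id = weight
        weight_fn = RP_WEIGHTS[weight]
    else:
        weight_id = getattr(weight, "__name__", "custom")
        weight_fn = weight
    summits_by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in summit_positions(peaks):
        summits_by_chrom.setdefault(chrom, []).append(pos)  # type: ignore[union-attr]
    for c in summits_by_chrom:
        summits_by_chrom[c] = np.sort(np.asarray(summits_by_chrom[c], dtype=np.int64))
    scores: dict[str, float] = {}
    for g in genes:
        score = 0.0
        pos = summits_by_chrom.get(g.chrom)
        if pos is not None:
            lo = np.searchsorted(pos, g.tss - max_dist, side="left")
            hi = np.searchsorted(pos, g.tss + max_dist, side="right")
            if hi > lo:
                d = np.abs(pos[lo:hi] - g.tss)
                score = float(weight_fn(d / max_dist).sum())
        scores[g.gene_id] = max(scores.get(g.gene_id, 0.0), score)
    return RegulatoryPotential(scores=scores, max_dist=max_dist, weight_id=weight_id)
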