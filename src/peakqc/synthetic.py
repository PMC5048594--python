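"""Synthetic genomes, libraries, peaks, tracks and annotations with known truth.

Every QC metric in this package is testable against fixtures whose correct
value is either constructed exactly or known in closed form:

* Library complexity: reads are laid down location-by-location with
  per-location multiplicities drawn from a zero-truncated Poisson(λ).  The
  expected complexity metrics then have analytic values —
  E[NRF] → (1 − e^{−λ})/λ and E[PBC] → λ e^{−λ}/(1 − e^{−λ}) — while the
  *exact* NRF/PBC/FRiP of each emitted read set are recorded by bookkeeping
  during generation, never by calling the metric code under test.
* Enrichment: exactly ``round(q · n)`` uniquely mapped reads are placed
  inside the peak set and ``round(mito · n)`` on the mitochondrial
  chromosome, so the in-peak fraction of the emitted library is exact.
* Replicates: two read sets share a controlled fraction ρ of read positions
  (ρ = 1 gives byte-identical coverage), and two peak sets share a
  controlled fraction of peaks.
* Annotation: genes with known exon/intron layout, a conservation track made
  of Gaussian bumps at designated summits, and DHS/blacklist region sets
  built to contain an exact fraction of the top peaks.

All randomness flows from the spec seed; the same seed reproduces the same
bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np

from .core import GenomicInterval, Peak, ReadTable, complement_intervals
from .annotation_layer import GeneModel

__all__ = [
    "SimulationSpec",
    "LibrarySim",
    "ReplicateSim",
    "AnnotationSim",
    "simulate_library",
    "simulate_replicates",
    "simulate_annotation_and_tracks",
    "simulate_fastq",
    "exact_match_mapper",
    "sam_text",
]

DEFAULT_CHROM_SIZES = {"chr1": 1_000_000, "chr2": 800_000, "chrM": 20_000}
MITO_CHROM = "chrM"


@dataclass
class SimulationSpec:
    """Parameters of one simulated sequencing library.

    ``n_reads`` counts all reads (the FASTQ size); ``mapq_high_fraction`` of
    them are uniquely mapped (mapq 30), ``unmapped_fraction`` fail to map,
    and the remainder are multi-mappers (mapq 0).  ``in_peak_fraction`` and
    ``mito_fraction`` partition the *uniquely mapped* reads.  Setting
    ``n_locations`` switches the driver: exactly that many distinct locations
    are generated and ``n_reads`` is derived from their multiplicities.
    """

    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_SIZES)
    )
    n_reads: int = 100_000
    n_locations: int | None = None
    duplication_lambda: float = 0.5
    in_peak_fraction: float = 0.0
    mito_fraction: float = 0.0
    mapq_high_fraction: float = 1.0
    unmapped_fraction: float = 0.0
    n_peaks: int = 0
    peak_width: int = 400
    fold_mean: float = 8.0
    read_length: int = 50

    def __post_init__(self) -> None:
        for name in ("in_peak_fraction", "mito_fraction", "mapq_high_fraction",
                     "unmapped_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.duplication_lambda <= 0:
            raise ValueError("duplication_lambda must be > 0")
        if self.mapq_high_fraction + self.unmapped_fraction > 1.0 + 1e-12:
            raise ValueError("mapq_high_fraction + unmapped_fraction > 1")


@dataclass
class LibrarySim:
    reads: ReadTable
    peaks: list[Peak]
    truth: dict


@dataclass
class ReplicateSim:
    reads_a: ReadTable
    reads_b: ReadTable
    peaks_a: list[Peak]
    peaks_b: list[Peak]
    truth: dict


@dataclass
class AnnotationSim:
    genes: list[GeneModel]
    conservation: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    dhs: list[GenomicInterval]
    blacklist: list[GenomicInterval]
    peaks: list[Peak]
    truth: dict


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson(lam) by rejection of zeros, drawn in batches."""
    out: list[np.ndarray] = []
    need = size
    while need > 0:
        draw = rng.poisson(lam, size=max(need * 2, 100))
        draw = draw[draw > 0]
        out.append(draw[:need])
        need -= len(out[-1])
    return np.concatenate(out)


def _counts_for_total(rng: np.random.Generator, lam: float, total: int) -> np.ndarray:
    """Truncated-Poisson multiplicities whose sum is exactly ``total``.

    Counts are drawn until the running sum reaches the target; the last
    location is trimmed to fit (one location out of many — negligible
    distortion of the law)."""
    if total == 0:
        return np.array([], dtype=np.int64)
    mean = lam / (1.0 - np.exp(-lam))
    chunks: list[np.ndarray] = []
    remaining = total
    while remaining > 0:
        batch = _truncated_poisson(
            rng, lam, max(int(remaining / mean) + 16, 16)
        ).astype(np.int64)
        cum = np.cumsum(batch)
        if cum[-1] < remaining:
            chunks.append(batch)
            remaining -= int(cum[-1])
            continue
        k = int(np.searchsorted(cum, remaining, side="left"))
        take = batch[: k + 1].copy()
        take[-1] = remaining - (int(cum[k - 1]) if k > 0 else 0)
        chunks.append(take)
        remaining = 0
    return np.concatenate(chunks)


def _sample_unique_codes(
    rng: np.random.Generator, space: int, k: int
) -> np.ndarray:
    """k distinct integers from [0, space): rejection sampling with dedup,
    avoiding a full permutation of a possibly huge space."""
    if k > space:
        raise ValueError(f"cannot place {k} distinct locations in space {space}")
    chosen = np.unique(rng.integers(0, space, size=int(k * 1.2) + 16))
    while len(chosen) < k:
        more = rng.integers(0, space, size=k)
        chosen = np.unique(np.concatenate([chosen, more]))
    return rng.permutation(chosen)[:k]


class _PositionSpace:
    """Maps flat codes to (chrom, position, strand) over a set of intervals."""

    def __init__(self, intervals: Sequence[GenomicInterval]) -> None:
        self.chroms = np.array([iv.chrom for iv in intervals], dtype=object)
        self.starts = np.array([iv.start for iv in intervals], dtype=np.int64)
        lengths = np.array([iv.end - iv.start for iv in intervals], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(lengths)])
        self.size = int(self.offsets[-1]) * 2  # both strands

    def decode(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        strand = codes % 2 == 1
        base = codes // 2
        idx = np.searchsorted(self.offsets, base, side="right") - 1
        pos = self.starts[idx] + (base - self.offsets[idx])
        return self.chroms[idx], pos, strand


def _make_peaks(
    rng: np.random.Generator,
    chrom_sizes: dict[str, int],
    n_peaks: int,
    width: int,
    fold_mean: float,
    exclude_chroms: frozenset[str] = frozenset({MITO_CHROM}),
) -> list[Peak]:
    """Disjoint peaks on a jittered grid over the non-mitochondrial genome."""
    chroms = [c for c in chrom_sizes if c not in exclude_chroms]
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    per_chrom = np.maximum(1, np.round(n_peaks * lengths / lengths.sum())).astype(int)
    # fix rounding to hit n_peaks exactly
    while per_chrom.sum() > n_peaks:
        per_chrom[np.argmax(per_chrom)] -= 1
    while per_chrom.sum() < n_peaks:
        per_chrom[np.argmax(lengths / per_chrom)] += 1
    peaks: list[Peak] = []
    k = 0
    for chrom, n_c in zip(chroms, per_chrom):
        if n_c == 0:
            continue
        slot = chrom_sizes[chrom] // n_c
        if slot <= width + 2:
            raise ValueError("too many peaks for the genome size")
        for i in range(n_c):
            jitter = int(rng.integers(0, slot - width - 1))
            start = i * slot + jitter
            fe = float(rng.exponential(fold_mean))
            peaks.append(
                Peak(
                    GenomicInterval(chrom, start, start + width),
                    name=f"peak_{k}",
                    score=float(rng.uniform(20, 500)),
                    fold_enrichment=fe,
                    neglog10_q=float(rng.uniform(2, 50)),
                    summit_offset=width // 2,
                )
            )
            k += 1
    return peaks


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

def simulate_library(spec: SimulationSpec) -> LibrarySim:
    """Emit a read table plus exact bookkept truth for the read/ChIP layers.

    Truth fields: total_reads, uniquely_mapped_reads, uniquely_mapped_ratio,
    n_locations, nrf, pbc (over the uniquely mapped reads at full depth),
    frip (in-peak over non-mitochondrial uniquely mapped reads), and the
    location-count histogram.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.in_peak_fraction > 0 and spec.n_peaks == 0:
        raise ValueError("in_peak_fraction > 0 requires n_peaks > 0")
    peaks = (
        _make_peaks(rng, spec.chrom_sizes, spec.n_peaks, spec.peak_width,
                    spec.fold_mean)
        if spec.n_peaks > 0
        else []
    )

    # --- multiplicities per category -------------------------------------
    if spec.n_locations is not None:
        counts_all = _truncated_poisson(
            rng, spec.duplication_lambda, spec.n_locations
        )
        n_unique = int(counts_all.sum())
        n_total = n_unique if spec.mapq_high_fraction == 1.0 else int(
            round(n_unique / spec.mapq_high_fraction)
        )
        n_in_peak = int(round(spec.in_peak_fraction * n_unique))
        n_mito = int(round(spec.mito_fraction * n_unique))
        # partition the drawn locations by cumulative read count
        cum = np.cumsum(counts_all)
        k_peak = int(np.searchsorted(cum, n_in_peak, side="left"))
        k_mito = int(np.searchsorted(cum, n_in_peak + n_mito, side="left"))
        counts_peak = counts_all[:k_peak]
        counts_mito = counts_all[k_peak:k_mito]
        counts_bg = counts_all[k_mito:]
        n_in_peak = int(counts_peak.sum())
        n_mito = int(counts_mito.sum())
    else:
        n_total = spec.n_reads
        n_unique = int(round(spec.mapq_high_fraction * n_total))
        n_in_peak = int(round(spec.in_peak_fraction * n_unique))
        n_mito = int(round(spec.mito_fraction * n_unique))
        counts_peak = _counts_for_total(rng, spec.duplication_lambda, n_in_peak)
        counts_mito = _counts_for_total(rng, spec.duplication_lambda, n_mito)
        counts_bg = _counts_for_total(
            rng, spec.duplication_lambda, n_unique - n_in_peak - n_mito
        )

    # --- place locations ---------------------------------------------------
    non_mito = [
        GenomicInterval(c, 0, ln)
        for c, ln in spec.chrom_sizes.items()
        if c != MITO_CHROM
    ]
    chrom_col: list[np.ndarray] = []
    pos_col: list[np.ndarray] = []
    strand_col: list[np.ndarray] = []
    mapq_col: list[np.ndarray] = []

    def _place(counts: np.ndarray, space: _PositionSpace) -> None:
        k = len(counts)
        if k == 0:
            return
        codes = _sample_unique_codes(rng, space.size, k)
        chrom, pos, strand = space.decode(codes)
        chrom_col.append(np.repeat(chrom, counts))
        pos_col.append(np.repeat(pos, counts))
        strand_col.append(np.repeat(strand, counts))
        mapq_col.append(np.full(int(counts.sum()), 30, dtype=np.int32))

    if len(counts_peak):
        _place(counts_peak, _PositionSpace([p.interval for p in peaks]))
    if len(counts_mito):
        mito_iv = GenomicInterval(MITO_CHROM, 0, spec.chrom_sizes[MITO_CHROM])
        _place(counts_mito, _PositionSpace(mito_iv and [mito_iv]))
    if len(counts_bg):
        # background locations live strictly outside the peak set, so the
        # in-peak read count stays exact by construction
        non_mito_sizes = {
            c: ln for c, ln in spec.chrom_sizes.items() if c != MITO_CHROM
        }
        bg_space = (
            complement_intervals([p.interval for p in peaks], non_mito_sizes)
            if peaks
            else non_mito
        )
        _place(counts_bg, _PositionSpace(bg_space))

    # --- multi-mappers (mapq 0), placed anywhere non-mito ------------------
    n_unmapped = int(round(spec.unmapped_fraction * n_total))
    n_low = n_total - n_unique - n_unmapped
    if n_low > 0:
        space = _PositionSpace(non_mito)
        codes = rng.integers(0, space.size, size=n_low)  # duplicates fine
        chrom, pos, strand = space.decode(codes)
        chrom_col.append(chrom)
        pos_col.append(pos)
        strand_col.append(strand)
        mapq_col.append(np.zeros(n_low, dtype=np.int32))

    chrom_arr = (
        np.concatenate(chrom_col) if chrom_col else np.array([], dtype=object)
    )
    pos_arr = np.concatenate(pos_col) if pos_col else np.array([], dtype=np.int64)
    strand_arr = (
        np.concatenate(strand_col) if strand_col else np.array([], dtype=bool)
    )
    mapq_arr = np.concatenate(mapq_col) if mapq_col else np.array([], dtype=np.int32)
    order = rng.permutation(len(pos_arr))
    reads = ReadTable(
        chrom_arr[order], pos_arr[order], strand_arr[order], mapq_arr[order],
        n_total=n_total,
    )

    counts_unique = np.concatenate([counts_peak, counts_mito, counts_bg])
    n_locations = len(counts_unique)
    hist: dict[int, int] = {}
    for c in counts_unique:
        hist[int(c)] = hist.get(int(c), 0) + 1
    n_nonmito_unique = n_unique - n_mito
    truth = {
        "total_reads": n_total,
        "uniquely_mapped_reads": n_unique,
        "uniquely_mapped_ratio": n_unique / n_total if n_total else None,
        "n_locations": n_locations,
        "nrf": n_locations / n_unique if n_unique else None,
        "pbc": hist.get(1, 0) / n_locations if n_locations else None,
        "frip": (n_in_peak / n_nonmito_unique) if (peaks and n_nonmito_unique) else None,
        "n_in_peak": n_in_peak,
        "n_mito": n_mito,
        "count_histogram": hist,
    }
    return LibrarySim(reads=reads, peaks=peaks, truth=truth)


# ---------------------------------------------------------------------------
# replicate simulation
# ---------------------------------------------------------------------------

def simulate_replicates(
    spec: SimulationSpec,
    rho: float,
    peak_share_fraction: float = 0.6,
) -> ReplicateSim:
    """Two replicate libraries with tunable agreement.

    A fraction ρ of read positions is shared verbatim between the replicates
    and the rest drawn independently, so binned-coverage correlation
    increases monotonically with ρ and equals 1.0 exactly at ρ = 1.  The two
    equally sized peak sets share exactly
    ``round(peak_share_fraction · n_peaks)`` peaks; the remainder are
    disjoint, so the expected overlap ratio is ``peak_share_fraction``.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be in [0,1]")
    rng = np.random.default_rng(spec.seed)
    non_mito = [
        GenomicInterval(c, 0, ln)
        for c, ln in spec.chrom_sizes.items()
        if c != MITO_CHROM
    ]
    space = _PositionSpace(non_mito)
    n = spec.n_reads
    n_shared = int(round(rho * n))

    def _decode_table(codes: np.ndarray) -> ReadTable:
        chrom, pos, strand = space.decode(codes)
        return ReadTable(
            chrom, pos, strand, np.full(len(codes), 30, dtype=np.int32)
        )

    shared = rng.integers(0, space.size, size=n_shared)
    own_a = rng.integers(0, space.size, size=n - n_shared)
    own_b = rng.integers(0, space.size, size=n - n_shared)
    reads_a = _decode_table(np.concatenate([shared, own_a]))
    reads_b = _decode_table(np.concatenate([shared, own_b]))

    # peaks: shared block + per-replicate private blocks, all disjoint
    n_pk = spec.n_peaks
    n_shared_pk = int(round(peak_share_fraction * n_pk))
    all_peaks = _make_peaks(
        rng, spec.chrom_sizes, 2 * n_pk - n_shared_pk, spec.peak_width,
        spec.fold_mean,
    )
    shared_pk = all_peaks[:n_shared_pk]
    priv_a = all_peaks[n_shared_pk : n_pk]
    priv_b = all_peaks[n_pk : 2 * n_pk - n_shared_pk]
    peaks_a = shared_pk + priv_a
    peaks_b = shared_pk + priv_b
    truth = {
        "rho": rho,
        "peak_share_fraction": n_shared_pk / n_pk if n_pk else None,
        "identical_reads": rho == 1.0,
    }
    return ReplicateSim(reads_a, reads_b, peaks_a, peaks_b, truth)


# ---------------------------------------------------------------------------
# annotation simulation
# ---------------------------------------------------------------------------

def simulate_annotation_and_tracks(
    spec: SimulationSpec,
    n_genes: int = 20,
    gene_length: int = 10_000,
    dhs_fraction: float = 0.75,
    blacklist_fraction: float = 0.1,
    bump_amplitude: float = 1.0,
    bump_sigma: float = 50.0,
    bump_halfwidth: int = 200,
    baseline: float = 0.0,
    top_n: int | None = None,
) -> AnnotationSim:
    """Genes, conservation track, DHS and blacklist with known ground truth.

    Genes tile the first chromosome with three exons each (so promoter, exon
    and intron territory is known exactly).  The conservation track is
    ``baseline`` plus a Gaussian bump of the given amplitude and width at
    every peak summit.  DHS regions are built over exactly
    ``round(dhs_fraction · top_n)`` of the top peaks and the blacklist over
    ``round(blacklist_fraction · top_n)`` (disjoint choices), making the
    overlap ratios exact by construction.
    """
    rng = np.random.default_rng(spec.seed)
    peaks = _make_peaks(
        rng, spec.chrom_sizes, max(spec.n_peaks, 1), spec.peak_width,
        spec.fold_mean,
    )
    # genes on the first non-mito chromosome
    chrom = next(c for c in spec.chrom_sizes if c != MITO_CHROM)
    chrom_len = spec.chrom_sizes[chrom]
    slot = chrom_len // max(n_genes, 1)
    if slot <= gene_length:
        raise ValueError("genes do not fit the chromosome")
    genes: list[GeneModel] = []
    for i in range(n_genes):
        tx_start = i * slot + int(rng.integers(0, slot - gene_length))
        tx_end = tx_start + gene_length
        strand = "+" if i % 2 == 0 else "-"
        exon_len = gene_length // 10
        exons = tuple(
            GenomicInterval(chrom, s, s + exon_len)
            for s in (
                tx_start,
                tx_start + gene_length // 2,
                tx_end - exon_len,
            )
        )
        genes.append(
            GeneModel(f"gene_{i}", chrom, strand, tx_start, tx_end, exons)
        )

    # conservation bumps at summits
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for p in peaks:
        s = p.summit
        lo = max(0, s - bump_halfwidth)
        hi = min(spec.chrom_sizes[p.chrom], s + bump_halfwidth)
        x = np.arange(lo, hi)
        v = baseline + bump_amplitude * np.exp(
            -((x - s) ** 2) / (2.0 * bump_sigma**2)
        )
        rows = per_chrom.setdefault(p.chrom, [])
        rows.extend((int(xi), int(xi) + 1, float(vi)) for xi, vi in zip(x, v))
    conservation = {}
    for c, rows in per_chrom.items():
        rows.sort()
        arr = np.array(rows, dtype=float)
        conservation[c] = (
            arr[:, 0].astype(np.int64),
            arr[:, 1].astype(np.int64),
            arr[:, 2],
        )

    # DHS / blacklist built over disjoint subsets of the top peaks
    from .annotation_layer import top_peaks as _top

    n_top = min(top_n or len(peaks), len(peaks))
    tops = _top(peaks, n_top)
    n_dhs = int(round(dhs_fraction * n_top))
    n_bl = int(round(blacklist_fraction * n_top))
    if n_dhs + n_bl > n_top:
        raise ValueError("dhs_fraction + blacklist_fraction exceed 1")
    order = rng.permutation(n_top)
    dhs = [tops[i].interval for i in order[:n_dhs]]
    blacklist = [tops[i].interval for i in order[n_dhs : n_dhs + n_bl]]
    truth = {
        "dhs_overlap_ratio": n_dhs / n_top,
        "blacklist_overlap_ratio": n_bl / n_top,
        "bump_amplitude": bump_amplitude,
        "bump_sigma": bump_sigma,
        "baseline": baseline,
        "n_top": n_top,
    }
    return AnnotationSim(genes, conservation, dhs, blacklist, peaks, truth)


# ---------------------------------------------------------------------------
# sequence-level fixtures
# ---------------------------------------------------------------------------

def simulate_fastq(
    n_reads: int,
    read_length: int = 36,
    quality: int | Sequence[int] = 30,
    seed: int = 0,
    genomes: dict[str, str] | None = None,
    mixture: dict[str, float] | None = None,
) -> str:
    """FASTQ text with controlled base qualities and (optionally) sequences
    copied verbatim from supplied genome strings.

    With ``genomes``/``mixture`` each read is an exact substring of one
    genome, the genome chosen per read according to the mixture fractions —
    the fixture for the contamination screen's exact-match mapper.  Without
    them, sequences are random ACGT.  ``quality`` is one Phred score for all
    bases or a sequence to cycle through per read.
    """
    rng = np.random.default_rng(seed)
    quals = [quality] if isinstance(quality, int) else list(quality)
    species: list[str] = []
    fractions: list[float] = []
    if genomes:
        if mixture is None:
            mixture = {s: 1.0 / len(genomes) for s in genomes}
        species = list(mixture)
        fractions = [mixture[s] for s in species]
        counts = [int(round(f * n_reads)) for f in fractions]
        counts[-1] = n_reads - sum(counts[:-1])
        origins = np.repeat(np.arange(len(species)), counts)
    lines: list[str] = []
    alphabet = np.array(list("ACGT"))
    for i in range(n_reads):
        if genomes:
            g = genomes[species[origins[i]]]
            start = int(rng.integers(0, len(g) - read_length + 1))
            seq = g[start : start + read_length]
        else:
            seq = "".join(rng.choice(alphabet, size=read_length))
        q = quals[i % len(quals)]
        lines.append(f"@read_{i}")
        lines.append(seq)
        lines.append("+")
        lines.append(chr(q + 33) * read_length)
    return "\n".join(lines) + "\n"


def exact_match_mapper(genome: str):
    """A pluggable 'aligner' for the contamination screen: a read maps iff it
    is an exact substring of the genome string."""

    def _maps(seq: bytes | str) -> bool:
        if isinstance(seq, bytes):
            seq = seq.decode()
        return seq in genome

    return _maps


def sam_text(
    reads: ReadTable,
    chrom_sizes: dict[str, int],
    read_length: int = 50,
) -> str:
    """Serialize a read table as minimal plain-text SAM.

    SEQ/QUAL are '*' placeholders (the downstream metrics never read them);
    unmapped records (to make ``n_total`` round-trip) are emitted as FLAG 4.
    """
    out = ["@HD\tVN:1.6\tSO:unsorted"]
    for c, ln in chrom_sizes.items():
        out.append(f"@SQ\tSN:{c}\tLN:{ln}")
    for i, (c, p, s, q) in enumerate(
        zip(reads.chrom, reads.pos5, reads.strand, reads.mapq)
    ):
        p = int(p)
        if s:  # minus strand: pos5 is the 3' reference end
            flag = 16
            rl = min(read_length, p + 1)  # clamp at chromosome start
            pos = p - rl + 2  # 1-based leftmost
        else:
            flag = 0
            rl = min(read_length, chrom_sizes[str(c)] - p)  # clamp at end
            pos = p + 1
        out.append(
            f"r{i}\t{flag}\t{c}\t{pos}\t{int(q)}\t{rl}M\t*\t0\t0\t*\t*"
        )
    for j in range(reads.n_total - len(reads)):
        out.append(f"u{j}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*")
    return "\n".join(out) + "\n"
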