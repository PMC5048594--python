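"""Coordinate conventions, standard-format I/O, and the interval engine.

Everything downstream of this module speaks 0-based half-open coordinates
(BED convention).  SAM's 1-based POS is converted on ingest and never seen
again.  Two overlap conventions coexist deliberately:

* ``overlaps_any`` — two intervals overlap iff they share at least one base;
  half-open abutting intervals ([a,b) and [b,c)) do *not* overlap.
* ``merge_intervals`` — abutting intervals *do* merge, so a merged set is the
  maximal covered blocks (needed when building a union region set such as
  merged DNase hypersensitive sites).
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GenomicInterval",
    "ChromSizes",
    "Peak",
    "AlignedRead",
    "ReadTable",
    "SignalTrack",
    "MergedIntervals",
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_sam_min",
    "read_bedgraph",
    "merge_intervals",
    "overlaps_any",
    "bin_reads",
]


class FormatError(ValueError):
    """A standard-format file violated its dialect (message names the line)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


class ChromSizes(dict):
    """Mapping chrom name -> length in bp; validates on insertion."""

    def __setitem__(self, chrom: str, length: int) -> None:
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        super().__setitem__(chrom, int(length))

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "ChromSizes":
        cs = cls()
        for k, v in d.items():
            cs[k] = v
        return cs


@dataclass(frozen=True)
class Peak:
    """One called peak.

    ``score`` follows the MACS narrowPeak column-5 convention; ``summit_offset``
    is the offset of the summit from ``start`` (−1 = unknown, as in broadPeak).
    For a peak without a recorded summit the interval midpoint
    ``floor((start+end)/2)`` stands in as the summit.
    """

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0
    fold_enrichment: float = 0.0
    neglog10_q: float = 0.0
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if self.summit_offset >= 0 and not (
            self.interval.start + self.summit_offset < self.interval.end
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak "
                f"[{self.interval.start}, {self.interval.end})"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def summit(self) -> int:
        """Absolute summit position (midpoint when the offset is unknown)."""
        if self.summit_offset >= 0:
            return self.interval.start + self.summit_offset
        return (self.interval.start + self.interval.end) // 2


@dataclass(frozen=True)
class AlignedRead:
    """One mapped read reduced to its 5'-most reference coordinate.

    ``pos5`` is 0-based; for minus-strand reads it is the 3' reference end of
    the alignment (the 5' end of the read as sequenced), computed from the
    reference-consuming CIGAR operations.
    """

    chrom: str
    pos5: int
    strand: str  # '+' or '-'
    mapq: int


class ReadTable:
    """Column-oriented store of aligned reads for vectorized metrics.

    Bulk metrics (library complexity, FRiP, binning) operate on millions of
    reads; a list of record objects would dominate both memory and time, so
    reads are held as parallel numpy arrays.  ``n_total`` is the number of
    primary records seen in the source including unmapped ones — the
    denominator of the uniquely-mapped ratio.
    """

    def __init__(
        self,
        chrom: np.ndarray,
        pos5: np.ndarray,
        strand: np.ndarray,
        mapq: np.ndarray,
        n_total: int | None = None,
    ) -> None:
        n = len(pos5)
        if not (len(chrom) == len(strand) == len(mapq) == n):
            raise ValueError("column lengths differ")
        self.chrom = np.asarray(chrom)
        self.pos5 = np.asarray(pos5, dtype=np.int64)
        self.strand = np.asarray(strand)  # bool: True = '-'
        self.mapq = np.asarray(mapq, dtype=np.int32)
        self.n_total = n if n_total is None else int(n_total)

    def __len__(self) -> int:
        return len(self.pos5)

    def take(self, idx: np.ndarray) -> "ReadTable":
        return ReadTable(
            self.chrom[idx], self.pos5[idx], self.strand[idx], self.mapq[idx]
        )

    def filter_mapq_gt(self, threshold: int) -> "ReadTable":
        """Keep reads with mapq strictly above ``threshold``; mapq 255 (the
        SAM 'unavailable' sentinel) always passes."""
        keep = (self.mapq > threshold) | (self.mapq == 255)
        return self.take(np.flatnonzero(keep))

    @classmethod
    def from_records(
        cls, reads: Iterable[AlignedRead], n_total: int | None = None
    ) -> "ReadTable":
        reads = list(reads)
        return cls(
            np.array([r.chrom for r in reads], dtype=object),
            np.array([r.pos5 for r in reads], dtype=np.int64),
            np.array([r.strand == "-" for r in reads], dtype=bool),
            np.array([r.mapq for r in reads], dtype=np.int32),
            n_total=n_total,
        )

    @classmethod
    def from_sam(cls, path: str | Path, chrom_sizes: ChromSizes) -> "ReadTable":
        chroms: list[str] = []
        pos5: list[int] = []
        strand: list[bool] = []
        mapq: list[int] = []
        n_total = 0
        for rec in _iter_sam(path, chrom_sizes):
            n_total += 1
            if rec is None:  # unmapped primary record
                continue
            chroms.append(rec.chrom)
            pos5.append(rec.pos5)
            strand.append(rec.strand == "-")
            mapq.append(rec.mapq)
        return cls(
            np.array(chroms, dtype=object),
            np.array(pos5, dtype=np.int64),
            np.array(strand, dtype=bool),
            np.array(mapq, dtype=np.int32),
            n_total=n_total,
        )

    def records(self) -> Iterator[AlignedRead]:
        for c, p, s, q in zip(self.chrom, self.pos5, self.strand, self.mapq):
            yield AlignedRead(str(c), int(p), "-" if s else "+", int(q))


def as_read_table(reads) -> ReadTable:
    """Accept a ReadTable or any iterable of AlignedRead."""
    if isinstance(reads, ReadTable):
        return reads
    return ReadTable.from_records(reads)


@dataclass
class SignalTrack:
    """Fixed-bin genome-wide coverage: one non-negative vector per chromosome."""

    bin_size: int
    data: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total_signal(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def scaled(self, factor: float) -> "SignalTrack":
        return SignalTrack(
            self.bin_size, {c: v * factor for c, v in self.data.items()}
        )


# ---------------------------------------------------------------------------
# Format readers / writers
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Read a 2-column ``chrom.sizes`` TSV."""
    cs = ChromSizes()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            if parts[0] in cs:
                raise FormatError(f"{path}:{lineno}: duplicate chrom {parts[0]!r}")
            cs[parts[0]] = int(parts[1])
    return cs


_SKIP_PREFIXES = ("track", "browser", "#")


def read_bed(path: str | Path) -> list[Peak]:
    """Read BED / narrowPeak / broadPeak into :class:`Peak` objects.

    Dialect is decided per line by column count: 10 columns = narrowPeak
    (score, fold enrichment, −log10 q, summit offset populated), 9 columns =
    broadPeak (no summit), fewer = plain BED with neutral defaults.
    ``track``/``browser``/``#`` lines are skipped.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            try:
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinates: {exc}") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = cols[3] if len(cols) > 3 else "."
            score = float(cols[4]) if len(cols) > 4 else 0.0
            fe = float(cols[6]) if len(cols) > 6 else 0.0
            nlq = float(cols[8]) if len(cols) > 8 else 0.0
            offset = int(cols[9]) if len(cols) > 9 else -1
            try:
                peaks.append(
                    Peak(
                        GenomicInterval(chrom, start, end),
                        name=name,
                        score=score,
                        fold_enrichment=fe,
                        neglog10_q=nlq,
                        summit_offset=offset,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_bed(peaks: Sequence[Peak], path: str | Path, dialect: str = "narrowPeak") -> None:
    """Write peaks in narrowPeak (10-col), broadPeak (9-col) or BED3 dialect."""
    with open(path, "w") as fh:
        for p in peaks:
            base = f"{p.chrom}\t{p.start}\t{p.end}"
            if dialect == "bed3":
                fh.write(base + "\n")
                continue
            cols = [
                base,
                p.name,
                _fmt_num(p.score),
                ".",
                _fmt_num(p.fold_enrichment),
                "-1",
                _fmt_num(p.neglog10_q),
            ]
            if dialect == "narrowPeak":
                cols.append(str(p.summit_offset))
            fh.write("\t".join(cols) + "\n")


def _fmt_num(x: float) -> str:
    return f"{x:g}"


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = frozenset("MDN=X")


def cigar_reference_span(cigar: str) -> int:
    """Number of reference bases consumed by a CIGAR string."""
    span = 0
    for n, op in _CIGAR_RE.findall(cigar):
        if op in _REF_CONSUMING:
            span += int(n)
    return span


def _iter_sam(
    path: str | Path, chrom_sizes: ChromSizes
) -> Iterator[AlignedRead | None]:
    """Yield one item per primary SAM record: an AlignedRead, or None when the
    record is unmapped.  Secondary (0x100) and supplementary (0x800)
    alignments are dropped entirely (they do not count toward totals)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("@") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 6:
                raise FormatError(f"{path}:{lineno}: truncated SAM record")
            try:
                flag = int(cols[1])
                pos = int(cols[3])
                mapq = int(cols[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad SAM field: {exc}") from exc
            if flag & (0x100 | 0x800):
                continue
            if flag & 0x4:
                yield None
                continue
            rname, cigar = cols[2], cols[5]
            if rname not in chrom_sizes:
                raise FormatError(
                    f"{path}:{lineno}: reference {rname!r} absent from chrom sizes "
                    "(genome mismatch?)"
                )
            if flag & 0x10:
                pos5 = pos - 1 + cigar_reference_span(cigar) - 1
                strand = "-"
            else:
                pos5 = pos - 1
                strand = "+"
            if not (0 <= pos5 < chrom_sizes[rname]):
                raise FormatError(
                    f"{path}:{lineno}: position {pos5} outside {rname} "
                    f"(length {chrom_sizes[rname]})"
                )
            yield AlignedRead(rname, pos5, strand, mapq)


def read_sam_min(path: str | Path, chrom_sizes: ChromSizes) -> Iterator[AlignedRead]:
    """Stream mapped primary reads from a plain-text SAM file.

    Only FLAG, RNAME, POS, MAPQ and CIGAR are consulted.  Unmapped,
    secondary and supplementary records are skipped.  An RNAME missing from
    ``chrom_sizes`` raises :class:`FormatError` naming the offending
    reference — the symptom of a genome-build mismatch.
    """
    for rec in _iter_sam(path, chrom_sizes):
        if rec is not None:
            yield rec


def read_bedgraph(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Read a 4-column bedGraph into per-chrom (starts, ends, values) arrays,
    sorted by start."""
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            cols = line.split()
            if len(cols) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            per_chrom.setdefault(cols[0], []).append(
                (int(cols[1]), int(cols[2]), float(cols[3]))
            )
    out = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        arr = np.array(rows, dtype=float)
        out[chrom] = (
            arr[:, 0].astype(np.int64),
            arr[:, 1].astype(np.int64),
            arr[:, 2],
        )
    return out


# ---------------------------------------------------------------------------
# Interval engine
# ---------------------------------------------------------------------------

def _as_interval(x) -> GenomicInterval:
    if isinstance(x, GenomicInterval):
        return x
    return GenomicInterval(x.chrom, x.start, x.end)


def merge_intervals(intervals: Iterable) -> list[GenomicInterval]:
    """Merge possibly unsorted, overlapping intervals into maximal blocks.

    Abutting half-open intervals merge ([a,b)+[b,c) -> [a,c)); total covered
    bases are preserved.  Output is sorted by (chrom, start).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        iv = _as_interval(iv)
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:  # overlap or abut
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def complement_intervals(
    intervals: Iterable, chrom_sizes: "ChromSizes | dict[str, int]"
) -> list[GenomicInterval]:
    """The gaps: every base of the genome not covered by ``intervals``."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merge_intervals(intervals):
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom, length in chrom_sizes.items():
        prev = 0
        for iv in by_chrom.get(chrom, []):
            if iv.start > prev:
                out.append(GenomicInterval(chrom, prev, iv.start))
            prev = iv.end
        if prev < length:
            out.append(GenomicInterval(chrom, prev, length))
    return out


class MergedIntervals:
    """A merged, per-chromosome sorted interval set supporting O(log n)
    interval-overlap and point-membership queries.

    Because merged intervals on one chromosome are disjoint and sorted, both
    their starts and their ends are strictly increasing, so a single
    ``searchsorted`` locates the only candidate that could overlap a query.
    """

    def __init__(self, intervals: Iterable) -> None:
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for iv in merge_intervals(intervals):
            self._starts.setdefault(iv.chrom, []).append(iv.start)  # type: ignore[union-attr]
            self._ends.setdefault(iv.chrom, []).append(iv.end)  # type: ignore[union-attr]
        for c in self._starts:
            self._starts[c] = np.asarray(self._starts[c], dtype=np.int64)
            self._ends[c] = np.asarray(self._ends[c], dtype=np.int64)

    def overlaps_intervals(
        self, chroms: Sequence[str], starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """True per query interval iff it shares >=1 bp with the set."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        out = np.zeros(len(starts), dtype=bool)
        chroms = np.asarray(chroms, dtype=object)
        for chrom in np.unique(chroms):
            if chrom not in self._starts:
                continue
            sel = np.flatnonzero(chroms == chrom)
            s, e = starts[sel], ends[sel]
            # last merged interval with start < query end
            idx = np.searchsorted(self._starts[chrom], e, side="left") - 1
            ok = idx >= 0
            hit = np.zeros(len(sel), dtype=bool)
            hit[ok] = self._ends[chrom][idx[ok]] > s[ok]
            out[sel] = hit
        return out

    def contains_points(
        self, chroms: Sequence[str], positions: np.ndarray
    ) -> np.ndarray:
        """True per (chrom, position) iff the base lies inside the set."""
        positions = np.asarray(positions, dtype=np.int64)
        return self.overlaps_intervals(chroms, positions, positions + 1)

    @property
    def n_blocks(self) -> int:
        return sum(len(v) for v in self._starts.values())


def overlaps_any(query: Sequence, subject: Sequence) -> list[bool]:
    """For each query interval, does it share >=1 bp with any subject interval?

    Half-open convention: touching intervals ([0,10) vs [10,20)) do not
    overlap.
    """
    query = [_as_interval(q) for q in query]
    engine = MergedIntervals(subject)
    flags = engine.overlaps_intervals(
        [q.chrom for q in query],
        np.array([q.start for q in query], dtype=np.int64),
        np.array([q.end for q in query], dtype=np.int64),
    )
    return [bool(f) for f in flags]


def bin_reads(reads, chrom_sizes: ChromSizes, bin_size: int) -> SignalTrack:
    """Count read 5' positions into fixed-size genomic bins.

    Every chromosome in ``chrom_sizes`` gets a vector of
    ``ceil(length / bin_size)`` bins, so two libraries binned against the same
    genome are directly comparable.  ``total_signal`` equals the number of
    reads counted.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    table = as_read_table(reads)
    track = SignalTrack(bin_size)
    for chrom, length in chrom_sizes.items():
        n_bins = -(-length // bin_size)  # ceil
        sel = table.chrom == chrom
        idx = table.pos5[sel] // bin_size
        track.data[chrom] = np.bincount(idx, minlength=n_bins).astype(np.float64)
    return track
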