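# Methods

## Coordinate and overlap conventions

All coordinates are 0-based half-open (`[start, end)`, BED convention);
SAM's 1-based `POS` is converted on ingest.  A read's location is its
stranded 5′-most reference coordinate: for minus-strand alignments this is
the 3′ reference end, computed from the reference-consuming CIGAR
operations (M, D, N, =, X), matching how alignment tools define duplicate
locations.  Reads with mapping quality 255 ("unavailable" in the SAM
specification) pass any mapq threshold.

Two overlap notions coexist on purpose.  *Overlap* means sharing at least
one base, so abutting half-open intervals (`[a,b)` and `[b,c)`) do not
overlap; *merging* joins abutting intervals, because a union region set
(e.g. merged DNase hypersensitive sites) is the set of maximal covered
blocks.  The interval engine merges the subject set once and answers each
query with a single binary search — on a merged, per-chromosome sorted set
both starts and ends are strictly increasing, so the interval with the
largest start below the query end is the only overlap candidate.  The
engine is validated against brute-force all-pairs and per-base bitmap
oracles in the test suite.

## Read layer

**Median base quality.**  Phred+33 qualities from a reservoir sample of
reads (Algorithm R with a seeded generator, platform-stable); the median
is taken over the pooled base calls, with the lower median on even counts.
A per-read-mean variant is available (`per_read=True`); the pooled per-base
median is the default reported value.

**Uniquely mapped.**  Reads with mapping quality strictly greater than 1,
over all primary records (mapped plus unmapped).  The threshold is
configurable; secondary and supplementary alignments never count.

**Library complexity.**  NRF = distinct locations / uniquely mapped reads;
PBC = single-read locations / distinct locations.  A location is a
(chromosome, 5′ position, strand) triple — including strand follows common
ENCODE-style practice.  Because both statistics fall as depth grows, they
are computed on a uniform random subsample of 4 000 000 uniquely mapped
reads (index sampling without replacement from a seeded generator, then
re-sorted, so results are independent of read order and hash ordering).
Smaller libraries are used whole and flagged `below_subsample_depth`.

**Contamination screen.**  The same subsample of up to 100 000 reads is
scored against every configured species; the "aligner" is an injected
predicate (sequence → maps?), so production use can wire in a real mapper
while the package stays self-contained.  The test fixture is an
exact-substring matcher against synthetic genomes.

## ChIP layer

**FRiP** is the fraction of non-mitochondrial reads whose 5′ position lies
inside a peak (membership by the read point, not the read span — consistent
with the location-based complexity metrics).  It is computed on the same
fixed 4 M subsample, drawn before the mitochondrial filter, against the
peak set called from *all* reads; with all-reads peaks the statistic is
nearly depth-independent, which the suite checks by comparing the 4 M
subsample FRiP of an 8 M-read library against the library's exact in-peak
fraction.  Mitochondrial names default to {chrM, MT, chrMT}.  An empty
peak set yields FRiP 0.0 with a warning rather than an error.

**Peak census** applies the fold-enrichment cutoffs inclusively (≥10,
≥20); both cutoffs are configurable.

**Replicate consistency.**  Coverage is binned (default 1 kb), scaled to
reads per million, concatenated across shared chromosomes, and compared by
Pearson correlation; a flat track makes the correlation undefined and is
reported as NaN with a warning rather than dropped.  Peak agreement is the
fraction of the *larger* set's peaks that overlap the smaller set — the
numerator and denominator then refer to the same set, bounding the ratio
in [0, 1] and making the unordered pair well-defined (ties broken toward
the first argument).  With k replicates, both metrics are reported for all
C(k, 2) pairs.

## Annotation layer

A peak's summit is its recorded summit offset when present (narrowPeak
column 10) and the interval midpoint `⌊(start+end)/2⌋` otherwise, so every
peak has a summit.

**Meta-regions.**  Each summit gets exactly one label with precedence
promoter > exon > intron > intergenic.  The promoter is TSS ± 2 kb
inclusive (the window size is configurable and deliberately matches the
conservation flank); intron is inside the transcript but in neither a
promoter window nor an exon.  The denominator is all summits, not only the
top peaks.

**Conservation profile.**  Per-base track values in the window of offsets
`[-flank, flank)` around each summit, averaged per summit and then per
offset bin.  Uncovered bases read as 0 and are tallied; windows crossing a
chromosome edge are zero-padded and counted as truncated.  The window is
half-open, so its discrete mirror center is the half-integer between the
two central bases; profiles of symmetric tracks are exactly symmetric
about that center.

**Region overlap.**  Fraction of the top-N peaks (default 5000, sorted by
MACS score descending with coordinate tie-break) sharing ≥1 bp with a
pre-merged region set; used for both union-DHS (high is good) and
blacklist (high is bad).  Blacklisted peaks are reported, never removed.

**Regulatory potential.**  For gene g,
`RP(g) = Σ w(d/D)` over peaks whose summit lies within D = 100 kb of the
TSS (inclusive), with default weight `w(Δ) = exp(−(0.5 + 4Δ))` — a
Cistrome-style exponential decay under which a summit on the TSS scores
e^{−0.5} ≈ 0.6065 and the weight falls ~55-fold across the window.  The
exact historical weight is not standardized, so the function is pluggable
(`exp2`: half-decay at D/10; `uniform`: plain count) and the choice is
recorded in the output.  A gene with several transcripts takes the maximum
over its transcript TSSs; distance is summit-to-TSS.

## QC atlas

One flattened record per sample (nullable metrics), stratified by an
assay-category label.  The default eight categories — transcription
factor, narrow histone mark, broad histone mark, chromatin regulator,
chromatin accessibility, RNA polymerase, CTCF/insulator, other — are a
configurable label set, not a fixed taxonomy.  Percentiles use the
mid-rank definition `100·(#{x<v} + ½·#{x=v})/N`, which is monotone,
symmetric and stable under ties.  Input controls are stored but excluded
from enrichment-metric pools (FRiP, peak counts) by default, since their
distributions are background.  Thresholds — quality > 25, uniquely-mapped
ratio > 0.5, PBC > 0.8, FRiP ≥ 0.01 (ChIP samples only), both replicate
consistency metrics > 0.6 — are strict except FRiP's, and overridable.

## Synthetic data

The generator's purpose is fixtures with *known* answers; truth values are
recorded by bookkeeping during generation and never computed by the metric
code under test.

* **Duplication** is modeled per location: multiplicities are
  zero-truncated Poisson(λ), giving closed forms
  E[NRF] → (1−e^{−λ})/λ and E[PBC] → λe^{−λ}/(1−e^{−λ}).  Default
  λ = 0.5 (PBC ≈ 0.771, NRF ≈ 0.787), a moderately duplicated library.
  Counts are drawn until the target read total is reached and the last
  location trimmed to fit — one location in ~10⁵, negligible distortion.
* **Composition** is exact: of n reads, `round(mapq_high·n)` are uniquely
  mapped (mapq 30), `round(unmapped·n)` unmapped, the rest multi-mappers
  (mapq 0); of the uniquely mapped, exactly `round(q·n)` sit inside the
  peak set and `round(mito·n)` on chrM.  Background locations are sampled
  from the complement of the peak set, so the in-peak count cannot drift.
* **Replicates** share a fraction ρ of read positions verbatim (ρ = 1
  gives identical coverage, correlation exactly 1.0) and a fraction of
  peaks exactly (equal set sizes make the expected overlap ratio the
  shared fraction).
* **Annotation** fixtures are constructed, not sampled: genes tile a
  chromosome with fixed exon layout, the conservation track is a Gaussian
  bump at each summit, and DHS/blacklist sets cover exact disjoint
  fractions of the top peaks.

What the generator does *not* emulate: base-call errors, GC and
mappability bias, fragment-length structure, chromatin-driven peak shape,
or correlated duplication hot-spots.  Passing tests therefore demonstrate
that the metric computations are correct under their definitions, not
that the thresholds are well calibrated for any particular real assay.

Default simulated genomes are small (two chromosomes of 1 Mb / 0.8 Mb plus
a 20 kb mitochondrion); the depth-stability check uses a 120 Mb genome and
8 million reads so that the fixed 4 M subsample is a genuine subsample.
These sizes keep every expected value analytically checkable while
exercising the same code paths as genome-scale data.

## Orchestration and reproducibility

`run_qc` executes the layers in dependency order; metrics whose inputs are
absent are null, and flags on null metrics are `not_applicable` — a run
with bad QC still exits 0, because a verdict is information.  The metrics
JSON has a stamped schema version, fixed key order and floats rounded to
1e−6, so identical configurations produce byte-identical output; NaN
(undefined correlation) serializes as null.  All randomness — subsampling,
reservoir sampling, simulation — flows from explicit seeds through
`numpy.random.default_rng`; nothing depends on hash ordering.

Known limitations: no BAM/BigWig binary ingestion (plain SAM, BED-family,
bedGraph and TSV only); paired-end mates are treated as independent reads;
fragment-size estimation, peak calling and motif analysis are upstream
tools' responsibilities, consumed here only through their outputs.
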