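import numpy as np
import pytest
from hypothesis import settings

from peakqc.core import AlignedRead, ChromSizes, GenomicInterval, Peak, ReadTable

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def chrom_sizes():
    return ChromSizes.from_dict({"chr1": 10_000, "chr2": 8_000, "chrM": 2_000})


def make_reads(specs, n_total=None):
    """ReadTable from (chrom, pos5, strand, mapq) tuples; mapq defaults 30."""
    records = []
    for s in specs:
        chrom, pos5 = s[0], s[1]
        strand = s[2] if len(s) > 2 else "+"
        mapq = s[3] if len(s) > 3 else 30
        records.append(AlignedRead(chrom, pos5, strand, mapq))
    return ReadTable.from_records(records, n_total=n_total)


def make_peak(chrom, start, end, score=0.0, fe=0.0, q=0.0, offset=-1, name="."):
    return Peak(
        GenomicInterval(chrom, start, end),
        name=name,
        score=score,
        fold_enrichment=fe,
        neglog10_q=q,
        summit_offset=offset,
    )


def write_fastq(path, records):
    """records: list of (sequence, quality-string)."""
    with open(path, "w") as fh:
        for i, (seq, qual) in enumerate(records):
            fh.write(f"@r{i}\n{seq}\n+\n{qual}\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
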