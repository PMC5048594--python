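"""The historical QC atlas: a reference table of metric records.

A single sample's FRiP of 0.02 is hard to judge in isolation; against the
distribution of FRiP values from thousands of comparable experiments it
becomes a percentile.  The atlas stores one flattened metric record per
sample, stratified by assay category (transcription-factor ChIP behaves very
differently from a broad histone mark), answers mid-rank percentile queries,
and applies the headline good/bad thresholds:

    median base quality > 25, uniquely-mapped ratio > 0.5, PBC > 0.8,
    FRiP >= 1% (ChIP samples, not input controls), replicate consistency
    (both wiggle correlation and peak overlap ratio) > 0.6.

Input controls are kept in the table but excluded from enrichment percentile
pools by default, since their FRiP distribution is background, not signal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QCRecord",
    "AtlasTable",
    "DEFAULT_CATEGORIES",
    "DEFAULT_THRESHOLDS",
    "compile_atlas",
    "percentile",
    "flag_metrics",
]

# The atlas stratifies by eight assay categories; the set is configurable
# because category taxonomies differ between labs.
DEFAULT_CATEGORIES = (
    "transcription factor",
    "narrow histone mark",
    "broad histone mark",
    "chromatin regulator",
    "chromatin accessibility",
    "RNA polymerase",
    "CTCF/insulator",
    "other",
)

METRIC_FIELDS = (
    "median_quality",
    "total_reads",
    "uniquely_mapped_reads",
    "uniquely_mapped_ratio",
    "unique_locations",
    "nrf",
    "pbc",
    "frip",
    "n_peaks",
    "n_fc10",
    "n_fc20",
    "wig_correlation",
    "peak_overlap_ratio",
    "promoter_fraction",
    "exon_fraction",
    "intron_fraction",
    "intergenic_fraction",
    "dhs_overlap_ratio",
    "blacklist_overlap_ratio",
)

# ChIP-enrichment metrics: input controls are excluded from these percentile
# pools (their distribution is background).
ENRICHMENT_METRICS = frozenset({"frip", "n_peaks", "n_fc10", "n_fc20"})


@dataclass
class QCRecord:
    """Flattened per-sample metric record — the row type of the atlas."""

    sample_id: str
    dataset_id: str = ""
    species: str = ""
    assay_category: str = "other"
    is_input_control: bool = False
    median_quality: float | None = None
    total_reads: float | None = None
    uniquely_mapped_reads: float | None = None
    uniquely_mapped_ratio: float | None = None
    unique_locations: float | None = None
    nrf: float | None = None
    pbc: float | None = None
    frip: float | None = None
    n_peaks: float | None = None
    n_fc10: float | None = None
    n_fc20: float | None = None
    wig_correlation: float | None = None
    peak_overlap_ratio: float | None = None
    promoter_fraction: float | None = None
    exon_fraction: float | None = None
    intron_fraction: float | None = None
    intergenic_fraction: float | None = None
    dhs_overlap_ratio: float | None = None
    blacklist_overlap_ratio: float | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")


_RECORD_FIELDS = tuple(f.name for f in dc_fields(QCRecord))


class AtlasTable:
    """Historical QC records indexed by (assay category, metric)."""

    def __init__(self, records: Sequence[QCRecord]) -> None:
        seen: set[str] = set()
        for r in records:
            if r.sample_id in seen:
                raise ValueError(f"duplicate sample_id {r.sample_id!r}")
            seen.add(r.sample_id)
        self.records = list(records)
        self.frame = pd.DataFrame(
            [{f: getattr(r, f) for f in _RECORD_FIELDS} for r in records],
            columns=list(_RECORD_FIELDS),
        )

    def __len__(self) -> int:
        return len(self.records)

    def values_for(
        self, metric: str, category: str | None = None, include_input: bool = False
    ) -> np.ndarray:
        """Non-null historical values of one metric, optionally restricted to
        a category; input controls excluded from enrichment metrics unless
        asked for."""
        if metric not in METRIC_FIELDS:
            raise KeyError(f"unknown metric {metric!r}")
        df = self.frame
        if category is not None:
            df = df[df["assay_category"] == category]
        if metric in ENRICHMENT_METRICS and not include_input:
            df = df[~df["is_input_control"].astype(bool)]
        vals = pd.to_numeric(df[metric], errors="coerce").dropna()
        return vals.to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AtlasTable":
        df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
        records = []
        for _, row in df.iterrows():
            kwargs = {}
            for f in _RECORD_FIELDS:
                if f not in row:
                    raise ValueError(f"atlas TSV missing field {f!r}")
                v = row[f]
                if f in ("sample_id", "dataset_id", "species", "assay_category"):
                    kwargs[f] = "" if pd.isna(v) else str(v)
                elif f == "is_input_control":
                    kwargs[f] = bool(v)
                else:
                    kwargs[f] = None if pd.isna(v) else float(v)
            records.append(QCRecord(**kwargs))
        return cls(records)


def record_from_metrics_json(data: dict) -> QCRecord:
    """Build a QCRecord from one metrics JSON document (the report output).

    Unknown metric keys inside the layer sections are rejected so schema
    drift is caught at compile time, not at query time.
    """
    kwargs: dict = {}
    for key in ("sample_id", "dataset_id", "species", "assay_category"):
        if key in data:
            kwargs[key] = data[key]
    kwargs["is_input_control"] = bool(data.get("is_input_control", False))
    if "sample_id" not in kwargs:
        raise ValueError("metrics JSON lacks required field 'sample_id'")
    for layer in ("read_layer", "chip_layer", "annotation_layer"):
        section = data.get(layer) or {}
        for k, v in section.items():
            if k in ("below_subsample_depth", "subsample_depth_used",
                     "contamination", "replicate_pairs", "conservation"):
                continue  # bookkeeping fields, not atlas metrics
            if k not in METRIC_FIELDS:
                raise ValueError(f"unknown metric field {k!r} in {layer}")
            kwargs[k] = None if v is None else float(v)
    return QCRecord(**kwargs)


def compile_atlas(inputs: Iterable) -> AtlasTable:
    """Compile QC records into an atlas table.

    ``inputs`` may mix paths to metrics JSON files and ready QCRecord
    objects.  Duplicate sample ids and schema mismatches are errors.
    """
    records: list[QCRecord] = []
    for item in inputs:
        if isinstance(item, QCRecord):
            records.append(item)
        else:
            with open(item) as fh:
                data = json.load(fh)
            records.append(record_from_metrics_json(data))
    return AtlasTable(records)


def percentile(
    value: float,
    metric: str,
    table: AtlasTable,
    category: str | None = None,
    include_input: bool = False,
) -> float:
    """Mid-rank percentile of ``value`` in the historical pool.

    percentile = 100 · (#{x < v} + 0.5 · #{x = v}) / N — symmetric under
    reflection and stable under ties.
    """
    pool = table.values_for(metric, category=category, include_input=include_input)
    if len(pool) == 0:
        raise ValueError(
            f"no historical values for metric {metric!r}"
            + (f" in category {category!r}" if category else "")
        )
    below = int((pool < value).sum())
    ties = int((pool == value).sum())
    return 100.0 * (below + 0.5 * ties) / len(pool)


# (threshold value, comparison) per metric; "ge" = value >= threshold is good,
# "gt" = strictly greater is good.
DEFAULT_THRESHOLDS: dict[str, tuple[float, str]] = {
    "median_quality": (25.0, "gt"),
    "uniquely_mapped_ratio": (0.5, "gt"),
    "pbc": (0.8, "gt"),
    "frip": (0.01, "ge"),
    "wig_correlation": (0.6, "gt"),
    "peak_overlap_ratio": (0.6, "gt"),
}


def flag_metrics(
    record: QCRecord, thresholds: dict[str, tuple[float, str]] | None = None
) -> dict[str, str]:
    """Judge each thresholded metric of one record: good / bad / not_applicable.

    A null metric is not applicable (the layer did not run).  FRiP is not
    judged on input controls — background samples are expected to have low
    enrichment.
    """
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    out: dict[str, str] = {}
    for metric, (cut, op) in thresholds.items():
        value = getattr(record, metric, None)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            out[metric] = "not_applicable"
            continue
        if metric == "frip" and record.is_input_control:
            out[metric] = "not_applicable"
            continue
        good = value >= cut if op == "ge" else value > cut
        out[metric] = "good" if good else "bad"
    return out
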