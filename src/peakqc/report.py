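"""Orchestrate a full QC run over one dataset and emit JSON + report.

A run takes one dataset — one or more replicate samples (aligned reads and,
optionally, called peaks and a FASTQ) plus genome resources — executes the
read, ChIP and annotation layers in dependency order, and writes:

* ``metrics.json`` — every metric, nested by layer, with stable key order
  and fixed float precision so reruns diff cleanly;
* ``report.md`` — a human-readable three-section report with good/bad flags
  and, when a historical atlas is configured, percentile annotations.

Metrics whose inputs are missing (no peaks, no gene table, ...) are null and
the report notes the skipped layer.  A "bad" QC verdict is information, not
a failure: the run still exits cleanly.
"""

from __future__ import annotations

import difflib
import json
import math
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import annotation_layer as ann
from . import atlas as atlas_mod
from . import chip_layer as chip
from . import read_layer as rl
from .core import ReadTable, bin_reads, read_bed, read_bedgraph, read_chrom_sizes

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_qc"]

SCHEMA_VERSION = "1.0"


class ConfigError(ValueError):
    """One or more configuration problems; message aggregates all of them."""


@dataclass
class ReplicateInput:
    reads: str | None = None
    peaks: str | None = None
    fastq: str | None = None


@dataclass
class Parameters:
    subsample_depth: int = rl.SUBSAMPLE_DEPTH
    contam_sample: int = rl.CONTAM_SAMPLE
    mapq_gt: int = rl.MAPQ_GT
    corr_bin: int = chip.CORR_BIN
    fc_thresholds: tuple[float, float] = chip.FC_THRESHOLDS
    mito_names: tuple[str, ...] = tuple(sorted(chip.MITO_NAMES))
    top_n: int = ann.TOP_N
    promoter_flank: int = ann.PROMOTER_WINDOW
    rp_dist: int = ann.RP_MAX_DIST
    rp_weight: str = "cistrome"
    conservation_flank: int = ann.CONSERVATION_FLANK
    conservation_bin: int = 50


@dataclass
class GenomeFiles:
    chrom_sizes: str | None = None
    genes: str | None = None
    dhs: str | None = None
    blacklist: str | None = None
    conservation: str | None = None


@dataclass
class RunConfig:
    sample_id: str
    dataset_id: str = ""
    species: str = ""
    assay_category: str = "other"
    is_input_control: bool = False
    seed: int = 0
    output_dir: str | None = None
    atlas: str | None = None
    control_reads: str | None = None
    genome: GenomeFiles = field(default_factory=GenomeFiles)
    replicates: list[ReplicateInput] = field(default_factory=list)
    parameters: Parameters = field(default_factory=Parameters)


_TOP_KEYS = {
    "sample_id", "dataset_id", "species", "assay_category", "is_input_control",
    "seed", "output_dir", "atlas", "control_reads", "genome", "replicates",
    "parameters",
}
_GENOME_KEYS = {f.strip() for f in GenomeFiles.__dataclass_fields__}
_PARAM_KEYS = set(Parameters.__dataclass_fields__)
_REP_KEYS = set(ReplicateInput.__dataclass_fields__)


def _check_keys(section: dict, allowed: set[str], where: str, errors: list[str]) -> None:
    for key in section:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            suggestion = f" (did you mean {hint[0]!r}?)" if hint else ""
            errors.append(f"unknown key {key!r} in {where}{suggestion}")


def validate_config(source: str | Path | dict) -> RunConfig:
    """Parse and validate a TOML or JSON run configuration.

    All problems — unknown keys (with a nearest-match suggestion), missing
    required keys, out-of-range parameters, nonexistent files — are
    collected and raised together as one :class:`ConfigError`.
    """
    if isinstance(source, dict):
        data = dict(source)
    else:
        path = Path(source)
        text = path.read_text()
        if path.suffix == ".json":
            data = json.loads(text)
        else:
            data = tomllib.loads(text)
    errors: list[str] = []
    _check_keys(data, _TOP_KEYS, "config", errors)
    if not data.get("sample_id"):
        errors.append("required key 'sample_id' is missing or empty")
    genome_raw = data.get("genome", {}) or {}
    _check_keys(genome_raw, _GENOME_KEYS, "genome", errors)
    params_raw = data.get("parameters", {}) or {}
    _check_keys(params_raw, _PARAM_KEYS, "parameters", errors)
    reps_raw = data.get("replicates", []) or []
    for i, rep in enumerate(reps_raw):
        _check_keys(rep, _REP_KEYS, f"replicates[{i}]", errors)
    if not reps_raw:
        errors.append("at least one replicate with reads or peaks is required")

    params = Parameters()
    for k, v in params_raw.items():
        if k not in _PARAM_KEYS:
            continue  # already recorded as an unknown-key error
        if k in ("fc_thresholds", "mito_names"):
            setattr(params, k, tuple(v))
        else:
            setattr(params, k, type(getattr(params, k))(v))
    for name in ("subsample_depth", "contam_sample", "corr_bin", "top_n",
                 "promoter_flank", "rp_dist", "conservation_flank",
                 "conservation_bin"):
        if getattr(params, name) < 1:
            errors.append(f"parameter {name} must be >= 1")
    if params.rp_weight not in ann.RP_WEIGHTS:
        errors.append(
            f"parameter rp_weight must be one of {sorted(ann.RP_WEIGHTS)}"
        )

    cfg = RunConfig(
        sample_id=str(data.get("sample_id", "")),
        dataset_id=str(data.get("dataset_id", "")),
        species=str(data.get("species", "")),
        assay_category=str(data.get("assay_category", "other")),
        is_input_control=bool(data.get("is_input_control", False)),
        seed=int(data.get("seed", 0)),
        output_dir=data.get("output_dir"),
        atlas=data.get("atlas"),
        control_reads=data.get("control_reads"),
        genome=GenomeFiles(**{k: genome_raw.get(k) for k in _GENOME_KEYS}),
        replicates=[
            ReplicateInput(**{k: rep.get(k) for k in _REP_KEYS})
            for rep in reps_raw
        ],
        parameters=params,
    )
    # every referenced path must exist at validation time
    referenced = [cfg.atlas, cfg.control_reads] + [
        getattr(cfg.genome, k) for k in _GENOME_KEYS
    ]
    for rep in cfg.replicates:
        referenced += [rep.reads, rep.peaks, rep.fastq]
    for p in referenced:
        if p is not None and not Path(p).exists():
            errors.append(f"referenced path does not exist: {p}")
    has_input = any(r.reads or r.peaks for r in cfg.replicates)
    if cfg.replicates and not has_input:
        errors.append("replicates provide neither reads nor peaks")
    if any(r.reads for r in cfg.replicates) and not cfg.genome.chrom_sizes:
        errors.append("genome.chrom_sizes is required when reads are given")
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


def _round_floats(obj, ndigits: int = 6):
    """Fixed float precision throughout the JSON document (reproducible
    diffs); NaN becomes null."""
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_qc(config: RunConfig) -> tuple[atlas_mod.QCRecord, str]:
    """Execute all QC layers for one dataset.

    Returns the flattened :class:`QCRecord` (replicate 1 carries the
    read-layer fields; replicate-pair metrics are summarized as medians) and
    the markdown report.  When ``config.output_dir`` is set, ``metrics.json``,
    ``report.md`` and — if a gene table was supplied — the ranked
    regulatory-potential TSV are written there.
    """
    p = config.parameters
    warnings_log: list[str] = []
    chrom_sizes = (
        read_chrom_sizes(config.genome.chrom_sizes)
        if config.genome.chrom_sizes
        else None
    )

    # --- per-replicate inputs ---------------------------------------------
    rep_reads: list[ReadTable | None] = []
    rep_peaks: list[list] = []
    for rep in config.replicates:
        rep_reads.append(
            ReadTable.from_sam(rep.reads, chrom_sizes) if rep.reads else None
        )
        rep_peaks.append(read_bed(rep.peaks) if rep.peaks else [])

    # --- read layer (per replicate) ---------------------------------------
    read_layers = []
    for rep, table in zip(config.replicates, rep_reads):
        if table is None:
            read_layers.append(None)
            continue
        m = rl.run_read_layer(
            table,
            fastq_path=rep.fastq,
            mapq_gt=p.mapq_gt,
            subsample_depth=p.subsample_depth,
            contam_sample=p.contam_sample,
            seed=config.seed,
        )
        if m.below_subsample_depth:
            warnings_log.append(
                f"library smaller than the {p.subsample_depth}-read subsample "
                "depth; complexity metrics computed on all reads"
            )
        read_layers.append(m)

    # --- ChIP layer --------------------------------------------------------
    primary_reads = rep_reads[0]
    primary_peaks = rep_peaks[0]
    chip_metrics = chip.ChipLayerMetrics()
    if primary_peaks:
        chip_metrics.peak_stats = chip.peak_census(
            primary_peaks, thresholds=p.fc_thresholds
        )
    if primary_reads is not None and primary_peaks:
        unique = primary_reads.filter_mapq_gt(p.mapq_gt)
        frip, depth, below = chip.compute_frip(
            unique,
            primary_peaks,
            subsample=p.subsample_depth,
            mito_names=set(p.mito_names),
            seed=config.seed,
        )
        chip_metrics.frip = frip
        chip_metrics.subsample_depth_used = depth
        chip_metrics.below_subsample_depth = below
    usable = [
        (r, pk) for r, pk in zip(rep_reads, rep_peaks) if r is not None and pk
    ]
    if len(usable) >= 2 and chrom_sizes is not None:
        tracks = [
            (bin_reads(r.filter_mapq_gt(p.mapq_gt), chrom_sizes, p.corr_bin), pk)
            for r, pk in usable
        ]
        chip_metrics.replicate_pairs = chip.pairwise_consistency(tracks)
        for pair in chip_metrics.replicate_pairs:
            if math.isnan(pair.wig_correlation):
                warnings_log.append(
                    f"flat signal in pair {pair.id_a}/{pair.id_b}: "
                    "wiggle correlation undefined"
                )

    # --- annotation layer ---------------------------------------------------
    ann_section: dict = {
        "promoter_fraction": None,
        "exon_fraction": None,
        "intron_fraction": None,
        "intergenic_fraction": None,
        "dhs_overlap_ratio": None,
        "blacklist_overlap_ratio": None,
    }
    conservation_values = None
    rp_result = None
    if primary_peaks:
        summits = ann.summit_positions(primary_peaks)
        tops = ann.top_peaks(primary_peaks, p.top_n)
        genes = (
            ann.read_gene_table(config.genome.genes)
            if config.genome.genes
            else None
        )
        if genes:
            dist = ann.classify_summits(
                summits, genes, promoter_window=p.promoter_flank
            )
            ann_section.update(
                promoter_fraction=dist.promoter,
                exon_fraction=dist.exon,
                intron_fraction=dist.intron,
                intergenic_fraction=dist.intergenic,
            )
            rp_result = ann.regulatory_potential(
                primary_peaks, genes, max_dist=p.rp_dist, weight=p.rp_weight
            )
        if config.genome.dhs:
            ann_section["dhs_overlap_ratio"] = ann.region_overlap_ratio(
                tops, read_bed(config.genome.dhs)
            )
        if config.genome.blacklist:
            ann_section["blacklist_overlap_ratio"] = ann.region_overlap_ratio(
                tops, read_bed(config.genome.blacklist)
            )
        if config.genome.conservation:
            profile = ann.conservation_profile(
                summits,
                read_bedgraph(config.genome.conservation),
                flank=p.conservation_flank,
                bin_size=p.conservation_bin,
                chrom_sizes=chrom_sizes,
            )
            conservation_values = profile.values
            if profile.n_truncated:
                warnings_log.append(
                    f"{profile.n_truncated} summit windows truncated at a "
                    "chromosome edge (zero-padded)"
                )

    # --- control sample (read layer only) ----------------------------------
    control_section = None
    if config.control_reads and chrom_sizes is not None:
        ctrl = ReadTable.from_sam(config.control_reads, chrom_sizes)
        cm = rl.run_read_layer(
            ctrl, mapq_gt=p.mapq_gt, subsample_depth=p.subsample_depth,
            seed=config.seed,
        )
        control_section = _read_layer_dict(cm)

    # --- assemble record and JSON ------------------------------------------
    rl0 = read_layers[0] if read_layers else None
    pairs = chip_metrics.replicate_pairs
    corr_values = [q.wig_correlation for q in pairs
                   if not math.isnan(q.wig_correlation)]
    overlap_values = [q.peak_overlap_ratio for q in pairs]
    record = atlas_mod.QCRecord(
        sample_id=config.sample_id,
        dataset_id=config.dataset_id,
        species=config.species,
        assay_category=config.assay_category,
        is_input_control=config.is_input_control,
        median_quality=None if rl0 is None else rl0.median_quality,
        total_reads=None if rl0 is None else float(rl0.total_reads),
        uniquely_mapped_reads=(
            None if rl0 is None else float(rl0.uniquely_mapped_reads)
        ),
        uniquely_mapped_ratio=(
            None if rl0 is None else rl0.uniquely_mapped_ratio
        ),
        unique_locations=None if rl0 is None else float(rl0.unique_locations),
        nrf=None if rl0 is None else rl0.nrf,
        pbc=None if rl0 is None else rl0.pbc,
        frip=chip_metrics.frip,
        n_peaks=(
            None if chip_metrics.peak_stats is None
            else float(chip_metrics.peak_stats.n_peaks)
        ),
        n_fc10=(
            None if chip_metrics.peak_stats is None
            else float(chip_metrics.peak_stats.n_fc10)
        ),
        n_fc20=(
            None if chip_metrics.peak_stats is None
            else float(chip_metrics.peak_stats.n_fc20)
        ),
        wig_correlation=float(np.median(corr_values)) if corr_values else None,
        peak_overlap_ratio=(
            float(np.median(overlap_values)) if overlap_values else None
        ),
        **ann_section,
    )
    flags = atlas_mod.flag_metrics(record)

    percentiles: dict[str, float] = {}
    if config.atlas:
        table = atlas_mod.AtlasTable.from_tsv(config.atlas)
        for metric in ("median_quality", "uniquely_mapped_ratio", "pbc", "frip"):
            value = getattr(record, metric)
            if value is None:
                continue
            try:
                percentiles[metric] = atlas_mod.percentile(
                    value, metric, table, category=config.assay_category
                )
            except ValueError:
                pass  # category absent from this atlas

    doc = {
        "schema_version": SCHEMA_VERSION,
        "sample_id": record.sample_id,
        "dataset_id": record.dataset_id,
        "species": record.species,
        "assay_category": record.assay_category,
        "is_input_control": record.is_input_control,
        "seed": config.seed,
        "read_layer": None if rl0 is None else _read_layer_dict(rl0),
        "replicate_read_layers": [
            None if m is None else _read_layer_dict(m) for m in read_layers
        ],
        "control_read_layer": control_section,
        "chip_layer": {
            "n_peaks": None if chip_metrics.peak_stats is None
            else chip_metrics.peak_stats.n_peaks,
            "n_fc10": None if chip_metrics.peak_stats is None
            else chip_metrics.peak_stats.n_fc10,
            "n_fc20": None if chip_metrics.peak_stats is None
            else chip_metrics.peak_stats.n_fc20,
            "frip": chip_metrics.frip,
            "subsample_depth_used": chip_metrics.subsample_depth_used,
            "below_subsample_depth": chip_metrics.below_subsample_depth,
            "replicate_pairs": [asdict(q) for q in pairs],
            "wig_correlation": record.wig_correlation,
            "peak_overlap_ratio": record.peak_overlap_ratio,
        },
        "annotation_layer": {
            **ann_section,
            "conservation": (
                None if conservation_values is None
                else list(conservation_values)
            ),
        },
        "flags": flags,
        "percentiles": percentiles,
        "warnings": warnings_log,
    }
    doc = _round_floats(doc)
    report = _render_report(doc)

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "metrics.json", "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=False)
            fh.write("\n")
        (out / "report.md").write_text(report)
        if rp_result is not None:
            with open(out / "regulatory_potential.tsv", "w") as fh:
                for gene_id, score in rp_result.ranked():
                    fh.write(f"{gene_id}\t{score:.6f}\n")
    return record, report


def _read_layer_dict(m: rl.ReadLayerMetrics) -> dict:
    return {
        "median_quality": m.median_quality,
        "total_reads": m.total_reads,
        "uniquely_mapped_reads": m.uniquely_mapped_reads,
        "uniquely_mapped_ratio": m.uniquely_mapped_ratio,
        "unique_locations": m.unique_locations,
        "nrf": m.nrf,
        "pbc": m.pbc,
        "subsample_depth_used": m.subsample_depth_used,
        "below_subsample_depth": m.below_subsample_depth,
        "contamination": dict(m.contamination),
    }


_FLAG_BADGE = {"good": "good (blue)", "bad": "bad (red)", "not_applicable": "n/a"}


def _render_report(doc: dict) -> str:
    """Markdown report: three layer sections, flags, percentiles, warnings."""
    lines = [
        f"# QC report — {doc['sample_id']}",
        "",
        f"- dataset: {doc['dataset_id'] or '—'}",
        f"- assay category: {doc['assay_category']}",
        f"- input control: {'yes' if doc['is_input_control'] else 'no'}",
        "",
        "## Read layer",
    ]
    rd = doc.get("read_layer")
    if rd is None:
        lines.append("_skipped: no aligned reads supplied_")
    else:
        lines += [
            f"- total reads: {rd['total_reads']}",
            f"- uniquely mapped: {rd['uniquely_mapped_reads']} "
            f"(ratio {rd['uniquely_mapped_ratio']})",
            f"- median base quality: {rd['median_quality']}",
            f"- unique locations: {rd['unique_locations']}",
            f"- NRF: {rd['nrf']}  PBC: {rd['pbc']} "
            f"(at depth {rd['subsample_depth_used']})",
        ]
        for sp, frac in rd["contamination"].items():
            lines.append(f"- contamination {sp}: {frac}")
    lines += ["", "## ChIP layer"]
    ch = doc["chip_layer"]
    if ch["n_peaks"] is None and ch["frip"] is None:
        lines.append("_skipped: no peaks supplied_")
    else:
        lines += [
            f"- peaks: {ch['n_peaks']} "
            f"(>=10x: {ch['n_fc10']}, >=20x: {ch['n_fc20']})",
            f"- FRiP: {ch['frip']} (at depth {ch['subsample_depth_used']})",
        ]
        for pair in ch["replicate_pairs"]:
            lines.append(
                f"- {pair['id_a']} vs {pair['id_b']}: wiggle correlation "
                f"{pair['wig_correlation']}, peak overlap "
                f"{pair['peak_overlap_ratio']}"
            )
    lines += ["", "## Annotation layer"]
    an = doc["annotation_layer"]
    if all(v is None for k, v in an.items() if k != "conservation"):
        lines.append("_skipped: no annotation resources supplied_")
    else:
        if an["promoter_fraction"] is not None:
            lines.append(
                "- summit distribution: "
                f"promoter {an['promoter_fraction']}, "
                f"exon {an['exon_fraction']}, intron {an['intron_fraction']}, "
                f"intergenic {an['intergenic_fraction']}"
            )
        if an["dhs_overlap_ratio"] is not None:
            lines.append(f"- union DHS overlap (top peaks): {an['dhs_overlap_ratio']}")
        if an["blacklist_overlap_ratio"] is not None:
            lines.append(f"- blacklist overlap (top peaks): {an['blacklist_overlap_ratio']}")
    lines += ["", "## Flags"]
    for metric, verdict in doc["flags"].items():
        pct = doc["percentiles"].get(metric)
        pct_note = f" — atlas percentile {pct:.1f}" if pct is not None else ""
        lines.append(f"- {metric}: {_FLAG_BADGE[verdict]}{pct_note}")
    if doc["warnings"]:
        lines += ["", "## Warnings"]
        lines += [f"- {w}" for w in doc["warnings"]]
    return "\n".join(lines) + "\n"
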