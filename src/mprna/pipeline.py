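"""End-to-end pipeline: design/map/qc/normalize/model/call in one call.

Every run serializes its configuration next to its outputs so a result
directory is self-describing; identical configs and seeds give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from mprna import io
from mprna.pool_design import DesignParams, assemble_pool
from mprna.read_mapping import MappingPolicy, build_index, count_reads, qc_recovery
from mprna.region_caller import CallerParams, call_drs, regions_to_frame
from mprna.signal_model import CountsMatrix, model_nucleotide_counts, normalize_counts

import pandas as pd

logger = logging.getLogger("mprna")


@dataclass
class RunConfig:
    """Inputs, parameters and seeds for one pipeline run."""

    out_dir: str
    transcripts_fasta: str | None = None
    manifest: str | None = None  # skip design when given
    sample_sheet: str | None = None  # sample_id, condition, replicate, fastq
    counts: str | None = None  # skip mapping when given
    design: DesignParams = field(default_factory=DesignParams)
    mapping: MappingPolicy = field(default_factory=MappingPolicy)
    caller: CallerParams = field(default_factory=CallerParams)
    qc_threshold: float = 0.70
    ignore_qc: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _dump_config(config: RunConfig, out: Path) -> None:
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute design -> map -> qc -> normalize -> model -> call.

    Stages with precomputed inputs (an existing manifest or counts table)
    are skipped.  A failed recovery QC aborts the run unless
    ``ignore_qc`` is set.  Returns a run summary (also written as JSON).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _dump_config(config, out)
    summary: dict = {"stages": []}

    # design
    if config.manifest:
        manifest = io.read_manifest(config.manifest, config.design.fwd_primer, config.design.rev_primer)
        summary["stages"].append({"stage": "design", "skipped": True, "manifest": config.manifest})
    else:
        if not config.transcripts_fasta:
            raise ValueError("stage design: need transcripts_fasta or an existing manifest")
        transcripts = io.read_fasta(config.transcripts_fasta)
        manifest = assemble_pool(transcripts, config.design)
        io.write_manifest(manifest, out / "manifest.tsv")
        io.write_pool_fasta(manifest, out / "pool.fasta")
        summary["stages"].append({"stage": "design", "n_oligos": len(manifest)})
    logger.info("design: %d oligos", len(manifest))

    if not config.sample_sheet:
        raise ValueError("stage map: sample_sheet is required")
    samples = io.read_sample_sheet(config.sample_sheet)

    # map
    if config.counts:
        counts = io.read_counts(config.counts, samples.drop(columns=[c for c in ("fastq",) if c in samples]))
        summary["stages"].append({"stage": "map", "skipped": True, "counts": config.counts})
    else:
        if "fastq" not in samples.columns:
            raise ValueError("stage map: sample sheet needs a 'fastq' column when counts are not given")
        index = build_index(manifest, config.mapping)
        cols = {}
        reports = []
        for sid, row in samples.iterrows():
            path = Path(row["fastq"])
            if not path.exists():
                raise FileNotFoundError(f"stage map: {path}")
            col, report = count_reads(io.read_fastq_stream(path), index, config.mapping, sid)
            cols[sid] = col
            reports.append(report)
            logger.info("map %s: %.3f mapped", sid, report["mapping_fraction"])
        values = pd.DataFrame(cols)
        counts = CountsMatrix(values=values, samples=samples.drop(columns=["fastq"]))
        io.write_counts(counts, out / "counts.tsv")
        io.write_tsv(pd.json_normalize(reports), out / "mapping_report.tsv")
        summary["stages"].append(
            {"stage": "map", "mapping_fractions": {r["sample_id"]: r["mapping_fraction"] for r in reports}}
        )

    # qc
    qc = qc_recovery(counts.values, config.qc_threshold)
    io.write_tsv(qc.rename_axis("sample_id").reset_index(), out / "qc_recovery.tsv")
    summary["stages"].append({"stage": "qc", "pass": bool(qc["pass"].all())})
    if not qc["pass"].all() and not config.ignore_qc:
        failed = qc.index[~qc["pass"]].tolist()
        raise RuntimeError(f"stage qc: sample(s) below {config.qc_threshold:.0%} oligo recovery: {failed}")

    # normalize + model
    norm = normalize_counts(counts)
    io.write_counts(norm, out / "norm_counts.tsv")
    tracks = model_nucleotide_counts(norm, manifest, step=config.design.step)
    tracks_dir = out / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    for tid, track in tracks.items():
        io.write_track(track, tracks_dir / f"{tid}.tsv")
    summary["stages"].append({"stage": "model", "n_transcripts": len(tracks)})

    # call
    result = call_drs(tracks, counts.samples, config.caller, norm=norm, manifest=manifest)
    io.write_tsv(regions_to_frame(result.regions), out / "drs.tsv")
    io.write_tsv(regions_to_frame(result.candidates), out / "candidates.tsv")
    io.write_dr_bed(result.regions, out / "drs.bed")
    io.write_tsv(pd.DataFrame({"null_stat": result.null_stats}), out / "null_stats.tsv")
    summary["stages"].append(
        {"stage": "call", "threshold": result.threshold, "n_candidates": len(result.candidates), "n_drs": len(result.regions)}
    )
    logger.info("call: %d DRs of %d candidates (threshold %.4g)", len(result.regions), len(result.candidates), result.threshold)

    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
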