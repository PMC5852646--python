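"""Readers and writers for the formats the pipeline touches.

All intervals on disk are 0-based half-open (BED convention), everywhere.
TSVs carry headers; the counts table keeps manifest row order so outputs
diff cleanly between runs.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from mprna.pool_design import OligoRecord
from mprna.region_caller import DifferentialRegion
from mprna.signal_model import CountsMatrix, NucleotideTrack


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# --- FASTA / FASTQ -------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> ordered dict of id -> uppercase sequence."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with _open_text(path) as fh:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        SeqIO.write(
            (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records.items()),
            fh,
            "fasta",
        )


def read_fastq_stream(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Stream (id, sequence, quality) from FASTQ or FASTQ.gz."""
    with _open_text(path) as fh:
        it = FastqGeneralIterator(fh)
        i = 0
        while True:
            i += 1
            try:
                rid, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as e:
                raise ValueError(f"{path}: malformed FASTQ record {i}: {e}") from None
            yield rid, seq.upper(), qual


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> int:
    n = 0
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


# --- TSV / BED -----------------------------------------------------------

def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3-6 (0-based half-open) with validation; returns up to BED6 columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from None
            if start < 0 or end < start:
                raise ValueError(f"{path}:{ln}: invalid interval [{start}, {end})")
            row = dict(zip(BED_COLUMNS, parts[:6]))
            row["start"], row["end"] = start, end
            rows.append(row)
    return pd.DataFrame(rows)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


# --- package-specific tables --------------------------------------------

MANIFEST_COLUMNS = ["oligo_id", "transcript_id", "start", "end", "window_index", "barcode", "variable_seq"]


def write_manifest(manifest: Iterable[OligoRecord], path: str | Path) -> None:
    rows = []
    widx: dict[str, int] = {}
    for o in manifest:
        i = widx.get(o.transcript_id, 0)
        widx[o.transcript_id] = i + 1
        rows.append(
            {
                "oligo_id": o.oligo_id,
                "transcript_id": o.transcript_id,
                "start": o.start,
                "end": o.end,
                "window_index": i,
                "barcode": o.barcode,
                "variable_seq": o.variable_seq,
            }
        )
    write_tsv(pd.DataFrame(rows, columns=MANIFEST_COLUMNS), path)


def read_manifest(
    path: str | Path,
    fwd_primer: str | None = None,
    rev_primer: str | None = None,
) -> list[OligoRecord]:
    from mprna.pool_design import FWD_PRIMER, REV_PRIMER

    fwd = fwd_primer or FWD_PRIMER
    rev = rev_primer or REV_PRIMER
    df = read_tsv(path, dtype={"barcode": str, "variable_seq": str})
    missing = set(MANIFEST_COLUMNS) - {"window_index"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    return [
        OligoRecord(
            oligo_id=r.oligo_id,
            transcript_id=r.transcript_id,
            start=int(r.start),
            end=int(r.end),
            variable_seq=r.variable_seq,
            barcode=r.barcode,
            full_seq=fwd + r.variable_seq + r.barcode + rev,
        )
        for r in df.itertuples()
    ]


def write_pool_fasta(manifest: Iterable[OligoRecord], path: str | Path) -> None:
    write_fasta({o.oligo_id: o.full_seq for o in manifest}, path)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet TSV: sample_id, condition (nuclear|total), replicate [, fastq]."""
    df = read_tsv(path, dtype={"sample_id": str})
    required = {"sample_id", "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    df["replicate"] = df["replicate"].astype(int)
    return df.set_index("sample_id")


def write_counts(counts: CountsMatrix, path: str | Path) -> None:
    counts.values.rename_axis("oligo_id").to_csv(path, sep="\t")


def read_counts(path: str | Path, samples: pd.DataFrame) -> CountsMatrix:
    values = pd.read_csv(path, sep="\t", index_col="oligo_id")
    return CountsMatrix(values=values, samples=samples)


def write_track(track: NucleotideTrack, path: str | Path) -> None:
    df = track.values.copy()
    df.insert(0, "coverage", track.coverage)
    df.rename_axis("position").to_csv(path, sep="\t")


def write_dr_bed(regions: Iterable[DifferentialRegion], path: str | Path) -> None:
    """BED6 export; score = min(1000, round(-10*log10(p_emp)))."""
    import numpy as np

    rows = []
    for i, r in enumerate(regions):
        score = int(min(1000, round(-10 * np.log10(r.p_emp)))) if r.p_emp > 0 else 1000
        rows.append(
            {
                "chrom": r.transcript_id,
                "start": r.start,
                "end": r.end,
                "name": f"DR{i + 1:03d}",
                "score": score,
                "strand": "+",
            }
        )
    write_bed(pd.DataFrame(rows, columns=BED_COLUMNS), path)
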