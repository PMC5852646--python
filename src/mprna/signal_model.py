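"""Library-size normalization and per-nucleotide signal modeling.

Counts are normalized to counts per million (CPM): each sample column is
scaled by 1e6 / its total read count, so samples of different depth are
comparable.  A transcript position's signal is then modeled as the median
of the normalized counts of every oligo whose window covers it; with
110-nt windows at a 10-nt step, interior positions are covered by 11
oligos and tracks come out on a 10-nt grid (one value per step interval,
indexed by the interval's left endpoint).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from mprna.pool_design import OligoRecord

CONDITIONS = ("nuclear", "total")


@dataclass
class CountsMatrix:
    """Oligo x sample counts plus sample metadata.

    ``values``: DataFrame indexed by oligo_id, one column per sample.
    ``samples``: DataFrame indexed by sample_id with columns
    ``condition`` (nuclear|total) and ``replicate`` (int).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples metadata missing for columns: {sorted(missing)}")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)} (expected {CONDITIONS})")

    def sample_ids(self, condition: str | None = None) -> list[str]:
        if condition is None:
            return list(self.values.columns)
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        keep = self.samples.index[self.samples["condition"] == condition]
        return [s for s in self.values.columns if s in set(keep)]

    def replicate_pairs(self) -> list[tuple[str, str]]:
        """(nuclear, total) sample pairs matched by replicate index."""
        nuc = {int(self.samples.loc[s, "replicate"]): s for s in self.sample_ids("nuclear")}
        tot = {int(self.samples.loc[s, "replicate"]): s for s in self.sample_ids("total")}
        if set(nuc) != set(tot):
            raise ValueError(
                f"unbalanced replicate structure: nuclear {sorted(nuc)} vs total {sorted(tot)}"
            )
        return [(nuc[r], tot[r]) for r in sorted(nuc)]


@dataclass
class NucleotideTrack:
    """Per-transcript modeled signal on the tiling grid.

    ``positions`` are 0-based transcript offsets at design-step spacing;
    ``values`` is a positions x samples DataFrame of modeled (median)
    normalized counts; ``coverage`` counts the oligos overlapping each
    position.
    """

    transcript_id: str
    positions: np.ndarray
    values: pd.DataFrame
    coverage: np.ndarray = field(repr=False, default=None)


def normalize_counts(raw: CountsMatrix, scale: float = 1e6) -> CountsMatrix:
    """Library-size (CPM) normalization: column * scale / column-sum."""
    sums = raw.values.sum(axis=0)
    zero = sums.index[sums == 0].tolist()
    if zero:
        raise ValueError(f"all-zero sample(s): {zero}")
    norm = raw.values * (scale / sums)
    return CountsMatrix(values=norm, samples=raw.samples)


def model_nucleotide_counts(
    norm: CountsMatrix,
    manifest: Iterable[OligoRecord],
    step: int | None = None,
    warn_missing: bool = True,
) -> dict[str, NucleotideTrack]:
    """Model per-nucleotide counts as the median over covering oligos.

    For each grid position p (multiples of the step from 0 to the last
    covered position) and each sample, the modeled value is the median of
    the normalized counts of all oligos whose window [start, end) contains
    p.  Even-cardinality medians are the mean of the two middle values.
    Oligos absent from ``norm`` raise; transcripts without oligos simply do
    not appear.
    """
    manifest = list(manifest)
    missing = [o.oligo_id for o in manifest if o.oligo_id not in norm.values.index]
    if missing:
        raise ValueError(f"manifest oligos absent from counts: {missing[:5]} (+{max(0, len(missing) - 5)} more)")

    by_tid: dict[str, list[OligoRecord]] = {}
    for o in manifest:
        by_tid.setdefault(o.transcript_id, []).append(o)

    if step is None:
        starts_all = sorted({o.start for o in manifest})
        diffs = {b - a for a, b in zip(starts_all, starts_all[1:])}
        step = min(diffs) if diffs else (manifest[0].end - manifest[0].start)

    sample_cols = list(norm.values.columns)
    tracks: dict[str, NucleotideTrack] = {}
    for tid, oligos in by_tid.items():
        oligos = sorted(oligos, key=lambda o: o.start)
        starts = np.array([o.start for o in oligos])
        ends = np.array([o.end for o in oligos])
        vals = norm.values.loc[[o.oligo_id for o in oligos], sample_cols].to_numpy(dtype=float)
        last = int(ends.max())
        positions = np.arange(0, last, step)
        modeled = np.empty((len(positions), len(sample_cols)))
        coverage = np.empty(len(positions), dtype=int)
        for i, p in enumerate(positions):
            mask = (starts <= p) & (p < ends)
            cov = int(mask.sum())
            coverage[i] = cov
            modeled[i] = np.median(vals[mask], axis=0) if cov else np.nan
        keep = coverage >= 1
        tracks[tid] = NucleotideTrack(
            transcript_id=tid,
            positions=positions[keep],
            values=pd.DataFrame(modeled[keep], index=positions[keep], columns=sample_cols),
            coverage=coverage[keep],
        )
    return tracks


def summarize_track(track: NucleotideTrack, samples: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Per-position median and sample SD (n-1) across a condition's replicates."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    cols = [s for s in track.values.columns if samples.loc[s, "condition"] == condition]
    if len(cols) < 2:
        raise ValueError(f"need >= 2 replicates for condition {condition!r}, found {len(cols)}")
    sub = track.values[cols]
    return pd.DataFrame(
        {"median": sub.median(axis=1), "sd": sub.std(axis=1, ddof=1)}, index=track.positions
    )
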