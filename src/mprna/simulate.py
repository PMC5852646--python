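"""Synthetic MPRNA experiments with ground truth.

The generator emulates the assay end to end: random transcripts are tiled
into a barcoded pool; each transcript carries planted nuclear-enrichment
regions of known location and fold effect; per-oligo baseline abundances
are log-normal (synthesis/amplification spread); counts are negative
binomial (gamma-Poisson) around depth-scaled means, with an optional
dropout fraction of oligos lost from the pool entirely; and reads are the
barcode-first expected reads with i.i.d. substitution errors.

An oligo overlapping a planted region by a fraction w of its window gets
a nuclear mean multiplier 1 + (effect - 1) * w — the simulator's linear
dilution assumption for partial overlaps.  Every draw flows from a single
seed, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from mprna.pool_design import DesignParams, OligoRecord, assemble_pool
from mprna.read_mapping import expected_read
from mprna.signal_model import CountsMatrix

_ALPH = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic experiment.

    Defaults emulate a full-scale assay: ~38 transcripts tiled into an
    oligo pool of order 10^4, six nuclear and six total replicates at
    10^6 reads each, 3-fold planted nuclear enrichment over 300-nt
    regions, log-normal baseline spread (sigma = 0.5 on the natural log,
    i.e. a ~4-fold 10-90% abundance range), negative binomial dispersion
    0.2 and 5% oligo dropout.  Tests scale ``n_transcripts`` and lengths
    down; the statistical knobs stay at these values.
    """

    n_transcripts: int = 38
    transcript_length: tuple[int, int] = (1200, 4000)
    regions_per_transcript: int = 1
    region_length: int = 300
    effect: float = 3.0
    baseline_sigma: float = 0.5
    dispersion: float = 0.2
    reads_per_sample: float = 1e6
    n_replicates: int = 6
    read_length: int = 100
    error_rate: float = 0.005
    dropout: float = 0.05
    design: DesignParams = field(default_factory=DesignParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect < 1:
            raise ValueError("planted effect must be >= 1 (nuclear fold-enrichment)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.transcript_length[0] < self.design.window:
            raise ValueError("transcripts must be at least one design window long")
        if self.regions_per_transcript and self.region_length > self.transcript_length[0]:
            raise ValueError("planted region longer than the shortest transcript")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth: planted regions, per-oligo expected enrichment, seed."""

    regions: pd.DataFrame  # transcript_id, start, end, effect
    oligo_truth: pd.DataFrame  # oligo_id, overlap_w, multiplier, expected_ratio, dropped
    seed: int


def _random_transcripts(cfg: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    out = {}
    lo, hi = cfg.transcript_length
    for i in range(cfg.n_transcripts):
        L = int(rng.integers(lo, hi + 1))
        out[f"tx{i:03d}"] = "".join("ACGT"[b] for b in rng.integers(0, 4, size=L))
    return out


def _plant_regions(cfg: SimConfig, lengths: dict[str, int], rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    step = cfg.design.step
    for tid, L in lengths.items():
        for _ in range(cfg.regions_per_transcript):
            if cfg.region_length > L:
                raise ValueError(f"planted region longer than transcript {tid}")
            # snapped to the tiling grid so truth and calls share a coordinate lattice
            start = int(rng.integers(0, (L - cfg.region_length) // step + 1)) * step
            rows.append({"transcript_id": tid, "start": start, "end": start + cfg.region_length, "effect": cfg.effect})
    return pd.DataFrame(rows, columns=["transcript_id", "start", "end", "effect"])


def _overlap_fraction(o: OligoRecord, regions: pd.DataFrame) -> float:
    sub = regions[regions["transcript_id"] == o.transcript_id]
    w = 0.0
    for _, r in sub.iterrows():
        ov = max(0, min(o.end, r["end"]) - max(o.start, r["start"]))
        w = max(w, ov / (o.end - o.start))
    return w


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    config: SimConfig | None = None,
    transcripts: dict[str, str] | None = None,
) -> tuple[list[OligoRecord], CountsMatrix, SimTruth]:
    """Simulate a designed pool and its oligo x sample counts table.

    Returns the manifest, raw counts with sample metadata (6+6 replicate
    design by default) and the ground truth.  Supplying ``transcripts``
    bypasses random sequence generation but keeps everything else.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    if transcripts is None:
        transcripts = _random_transcripts(cfg, rng)
    design = cfg.design if cfg.design.seed != 0 else replace(
        cfg.design, seed=int(rng.integers(1, 2**31 - 1))
    )
    manifest = assemble_pool(transcripts, design)
    regions = _plant_regions(cfg, {t: len(s) for t, s in transcripts.items()}, rng)

    n = len(manifest)
    lam = rng.lognormal(mean=0.0, sigma=cfg.baseline_sigma, size=n)
    dropped = rng.random(n) < cfg.dropout
    lam[dropped] = 0.0
    w = np.array([_overlap_fraction(o, regions) for o in manifest])
    mult = 1.0 + (cfg.effect - 1.0) * w

    depth = float(cfg.reads_per_sample)
    mean_total = depth * lam / lam.sum()
    mean_nuc = depth * (lam * mult) / (lam * mult).sum()

    cols = {}
    meta = []
    for r in range(1, cfg.n_replicates + 1):
        sid = f"nuclear_{r}"
        cols[sid] = _nb_draw(rng, mean_nuc, cfg.dispersion)
        meta.append({"sample_id": sid, "condition": "nuclear", "replicate": r})
    for r in range(1, cfg.n_replicates + 1):
        sid = f"total_{r}"
        cols[sid] = _nb_draw(rng, mean_total, cfg.dispersion)
        meta.append({"sample_id": sid, "condition": "total", "replicate": r})

    values = pd.DataFrame(cols, index=[o.oligo_id for o in manifest])
    samples = pd.DataFrame(meta).set_index("sample_id")
    counts = CountsMatrix(values=values, samples=samples)

    expected_ratio = np.where(lam > 0, mult * lam.sum() / (lam * mult).sum(), np.nan)
    truth = SimTruth(
        regions=regions,
        oligo_truth=pd.DataFrame(
            {
                "oligo_id": [o.oligo_id for o in manifest],
                "overlap_w": w,
                "multiplier": mult,
                "expected_ratio": expected_ratio,
                "dropped": dropped,
            }
        ).set_index("oligo_id"),
        seed=cfg.seed,
    )
    return manifest, counts, truth


def simulate_reads(
    manifest: Sequence[OligoRecord],
    counts_column: pd.Series,
    config: SimConfig | None = None,
    seed: int | None = None,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Emit error-bearing reads for one sample's count column.

    Exactly ``counts_column[oligo]`` reads per oligo, each the oligo's
    barcode-first expected read truncated to the configured read length,
    with i.i.d. substitutions at ``error_rate`` and constant quality.
    Returns FASTQ-ready ``(read_id, sequence, quality)`` tuples plus the
    read -> source-oligo truth table.
    """
    cfg = config or SimConfig()
    if cfg.read_length < cfg.design.barcode_len:
        raise ValueError("read length shorter than the barcode")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    by_id = {o.oligo_id: o for o in manifest}

    templates = []
    reps = []
    oligo_order = []
    for oid, c in counts_column.items():
        c = int(c)
        if c < 0:
            raise ValueError(f"negative count for {oid}")
        if c == 0:
            continue
        er = expected_read(by_id[oid])[: cfg.read_length]
        templates.append(np.frombuffer(er.encode(), dtype=np.uint8))
        reps.append(c)
        oligo_order.append(oid)
    if not templates:
        return [], pd.DataFrame(columns=["read_id", "oligo_id"]).set_index("read_id")

    L = len(templates[0])
    mat = np.repeat(np.stack(templates), reps, axis=0).copy()
    # map base bytes to 0..3, substitute, map back
    code = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(_ALPH):
        code[b] = i
    codes = code[mat]
    err = rng.random(mat.shape) < cfg.error_rate
    n_err = int(err.sum())
    if n_err:
        codes[err] = (codes[err] + rng.integers(1, 4, size=n_err)) % 4
    seqs = _ALPH[codes]

    src = np.repeat(np.array(oligo_order, dtype=object), reps)
    qual = "I" * L
    reads = []
    ids = []
    for i in range(seqs.shape[0]):
        rid = f"r{i:08d}"
        ids.append(rid)
        reads.append((rid, seqs[i].tobytes().decode(), qual))
    truth = pd.DataFrame({"read_id": ids, "oligo_id": src}).set_index("read_id")
    return reads, truth
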