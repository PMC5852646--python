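"""Tiled, barcoded oligo-pool design.

Each transcript is scanned in fixed-length windows (default 110 nt) at a
fixed step (default 10 nt) so that, with the default geometry, every
interior base is covered by window/step = 11 oligos.  Each window becomes a
153-nt oligo: 16-nt forward universal primer site + 110-nt variable
sequence + 10-nt unique barcode + 17-nt reverse universal primer site.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np

FWD_PRIMER = "ACTGGCCGCTTCACTG"
REV_PRIMER = "AGATCGGAAGAGCGTCG"

_ALPHABET = "ACGT"
_VALID_SEQ = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class DesignParams:
    """Pool-design geometry and barcode constraints.

    ``barcode_min_hamming=3`` guarantees that a single substitution inside
    the barcode prefix of a read can never convert one pool barcode into
    another, keeping the mapper's exact-prefix lookup unambiguous.
    """

    window: int = 110
    step: int = 10
    barcode_len: int = 10
    fwd_primer: str = FWD_PRIMER
    rev_primer: str = REV_PRIMER
    barcode_min_hamming: int = 3
    max_homopolymer: int = 4
    primer_kmer_exclusion: int = 8
    anchor_last: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.window >= self.step >= 1):
            raise ValueError(f"require window >= step >= 1, got {self.window}, {self.step}")
        if self.barcode_len < 1:
            raise ValueError("barcode_len must be >= 1")


@dataclass(frozen=True)
class OligoRecord:
    """One designed oligo with its transcript coordinates (0-based, half-open)."""

    oligo_id: str
    transcript_id: str
    start: int
    end: int
    variable_seq: str
    barcode: str
    full_seq: str


def clean_sequence(seq: str, name: str = "sequence") -> str:
    """Uppercase, convert U->T (with a warning), reject other ambiguity codes."""
    s = seq.upper()
    if "U" in s:
        warnings.warn(f"{name}: converting U to T (RNA input)", stacklevel=2)
        s = s.replace("U", "T")
    if not s:
        raise ValueError(f"{name}: empty sequence")
    if not _VALID_SEQ.match(s):
        bad = sorted(set(s) - set(_ALPHABET))
        raise ValueError(f"{name}: non-ACGT characters {bad}")
    return s


def tile_transcript(seq: str, params: DesignParams | None = None, *, name: str = "transcript") -> list[tuple[int, int]]:
    """Tile a sequence into (start, end) windows of ``params.window`` at ``params.step``.

    With ``anchor_last`` an extra window ending exactly at the sequence end is
    appended when the regular grid leaves a trailing remainder; by default the
    incomplete tail is dropped so per-base coverage stays predictable.
    """
    params = params or DesignParams()
    L = len(seq)
    if L < params.window:
        raise ValueError(f"{name}: length {L} < window {params.window}")
    n = (L - params.window) // params.step + 1
    windows = [(i * params.step, i * params.step + params.window) for i in range(n)]
    if params.anchor_last and windows[-1][1] < L:
        windows.append((L - params.window, L))
    return windows


def _hamming_ok(mat: np.ndarray, cand: np.ndarray, min_d: int) -> bool:
    if mat.shape[0] == 0:
        return True
    return int((mat != cand).sum(axis=1).min()) >= min_d


def _max_homopolymer(s: str) -> int:
    best = run = 1
    for a, b in zip(s, s[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _primer_kmers(params: DesignParams) -> set[str]:
    k = params.primer_kmer_exclusion
    kmers: set[str] = set()
    for p in (params.fwd_primer, params.rev_primer):
        for s in (p, reverse_complement(p)):
            kmers.update(s[i : i + k] for i in range(len(s) - k + 1))
    return kmers


def assign_barcodes(n: int, params: DesignParams | None = None) -> list[str]:
    """Sample ``n`` distinct barcodes by seeded rejection.

    Constraints: pairwise Hamming distance >= ``barcode_min_hamming``, no
    homopolymer run longer than ``max_homopolymer``, and no 8-mer shared with
    either universal primer (in either orientation).  Deterministic for a
    fixed ``params.seed``.
    """
    params = params or DesignParams()
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    space = 4 ** params.barcode_len
    if n > space:
        raise ValueError(f"cannot draw {n} distinct barcodes of length {params.barcode_len}")
    rng = np.random.default_rng(params.seed)
    forbidden = _primer_kmers(params) if params.barcode_len >= params.primer_kmer_exclusion else set()
    k = params.primer_kmer_exclusion

    accepted = np.empty((n, params.barcode_len), dtype=np.uint8)
    count = 0
    # Rejection cap scales with n so infeasible constraint sets fail loudly.
    max_tries = 2000 + 2000 * n
    tries = 0
    while count < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"barcode sampling did not reach n={n} after {max_tries} draws; "
                "constraints too tight for this length"
            )
        cand = rng.integers(0, 4, size=params.barcode_len).astype(np.uint8)
        s = "".join(_ALPHABET[c] for c in cand)
        if _max_homopolymer(s) > params.max_homopolymer:
            continue
        if forbidden and any(s[i : i + k] in forbidden for i in range(len(s) - k + 1)):
            continue
        if not _hamming_ok(accepted[:count], cand, params.barcode_min_hamming):
            continue
        accepted[count] = cand
        count += 1
    return ["".join(_ALPHABET[c] for c in row) for row in accepted]


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def assemble_pool(
    transcripts: dict[str, str],
    params: DesignParams | None = None,
) -> list[OligoRecord]:
    """Design the full oligo pool over a set of transcripts.

    ``transcripts`` maps transcript_id -> sequence (ACGT; U accepted with a
    warning).  Returns one :class:`OligoRecord` per tiling window, with
    pool-wide unique barcodes; ``full_seq`` is always
    ``fwd_primer + variable_seq + barcode + rev_primer``.
    """
    params = params or DesignParams()
    ids = list(transcripts)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate transcript ids")
    clean = {tid: clean_sequence(seq, name=tid) for tid, seq in transcripts.items()}
    windows = {tid: tile_transcript(seq, params, name=tid) for tid, seq in clean.items()}
    total = sum(len(w) for w in windows.values())
    barcodes = assign_barcodes(total, params)
    records: list[OligoRecord] = []
    i = 0
    for tid in ids:
        seq = clean[tid]
        for widx, (start, end) in enumerate(windows[tid]):
            var = seq[start:end]
            bc = barcodes[i]
            records.append(
                OligoRecord(
                    oligo_id=f"{tid}|w{widx:04d}|s{start}",
                    transcript_id=tid,
                    start=start,
                    end=end,
                    variable_seq=var,
                    barcode=bc,
                    full_seq=params.fwd_primer + var + bc + params.rev_primer,
                )
            )
            i += 1
    return records
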