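"""PWM containers, MEME minimal-format reading, and log-odds scanning.

The scanner reports every position whose summed log2(p/background) score
reaches a threshold.  It is an occurrence scanner, not a p-value scanner:
for motif discovery or calibrated occurrence p-values, dedicated motif
suites remain the reference tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TextIO

import numpy as np
from Bio import motifs as bio_motifs

_BASES = "ACGT"
PSEUDO = 1e-4


@dataclass
class PWM:
    """Column-stochastic base-probability matrix plus background frequencies."""

    motif_id: str
    matrix: np.ndarray  # width x 4, columns (here: rows) sum to 1 over ACGT
    background: dict[str, float] = field(default_factory=lambda: {b: 0.25 for b in _BASES})

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValueError("PWM matrix must be width x 4 with width >= 1")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM positions must each sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """log2((p + pseudocount on zeros) / background), width x 4."""
        m = self.matrix.copy()
        m[m == 0] = PSEUDO
        bg = np.array([self.background[b] for b in _BASES])
        return np.log2(m / bg)


def read_meme(handle: TextIO | str) -> list[PWM]:
    """Read PWMs from MEME minimal text format."""
    if isinstance(handle, str):
        with open(handle) as fh:
            return read_meme(fh)
    parsed = bio_motifs.parse(handle, "minimal")
    out = []
    for m in parsed:
        mat = np.array([[m.pwm[b][i] for b in _BASES] for i in range(m.length)])
        mat = mat / mat.sum(axis=1, keepdims=True)
        bg = {b: float(m.background[b]) for b in _BASES}
        out.append(PWM(motif_id=m.name or "motif", matrix=mat, background=bg))
    return out


def write_meme(pwms: list[PWM], handle: TextIO | str) -> None:
    if isinstance(handle, str):
        with open(handle, "w") as fh:
            write_meme(pwms, fh)
            return
    handle.write("MEME version 4\n\nALPHABET= ACGT\n\n")
    bg = pwms[0].background if pwms else {b: 0.25 for b in _BASES}
    handle.write("Background letter frequencies\n")
    handle.write(" ".join(f"{b} {bg[b]:.5f}" for b in _BASES) + "\n\n")
    for p in pwms:
        handle.write(f"MOTIF {p.motif_id}\n")
        handle.write(f"letter-probability matrix: alength= 4 w= {p.width} nsites= 20 E= 0\n")
        for row in p.matrix:
            handle.write(" ".join(f"{x:.6f}" for x in row) + "\n")
        handle.write("\n")


def pwm_scan(seq: str, pwm: PWM, score_threshold: float) -> list[tuple[int, float]]:
    """Positions (0-based) where the log-odds score >= threshold.

    Scans the given strand only; U is treated as T.  A sequence shorter
    than the motif yields an empty list.
    """
    s = seq.upper().replace("U", "T")
    w = pwm.width
    if len(s) < w:
        return []
    lods = pwm.log_odds()
    idx = {b: i for i, b in enumerate(_BASES)}
    try:
        codes = np.array([idx[c] for c in s])
    except KeyError as e:
        raise ValueError(f"non-ACGTU character {e} in sequence") from None
    hits = []
    for p in range(len(s) - w + 1):
        score = float(lods[np.arange(w), codes[p : p + w]].sum())
        if score >= score_threshold:
            hits.append((p, score))
    return hits
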