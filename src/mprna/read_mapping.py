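"""Barcode-based read-to-oligo assignment.

Reads start at the oligo barcode and extend into the adjacent oligo
sequence in read orientation (the reverse complement of the sense strand,
so a 100-nt read sees the 10-nt barcode followed by up to 90 nt of the
variable sequence read back from its 3' end).  A read is assigned to an
oligo iff its first ``barcode_len`` nucleotides exactly match that oligo's
barcode (in read orientation) and the continuation has at most
``max_mismatches`` substitutions against the expected sequence within the
first ``check_len`` checked nucleotides.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd

from mprna.pool_design import OligoRecord, reverse_complement

NO_BARCODE = "no_barcode"
TOO_MANY_MISMATCHES = "too_many_mismatches"
TOO_SHORT = "too_short"

_READ_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class MappingPolicy:
    """Mismatch budget for the sequence adjacent to the barcode.

    ``check_len`` is the number of nucleotides verified after the exact
    barcode match; 90 matches a 100-nt read (10-nt barcode + 90 checked),
    while 65 reproduces a shorter verification window some protocols use.
    """

    barcode_len: int = 10
    check_len: int = 90
    max_mismatches: int = 2

    def __post_init__(self) -> None:
        if self.max_mismatches < 0 or self.check_len < 0 or self.barcode_len < 1:
            raise ValueError("invalid mapping policy")


def expected_read(oligo: OligoRecord, fwd_primer: str | None = None) -> str:
    """The error-free read for an oligo: revcomp of (fwd primer + variable seq + barcode).

    Its prefix of ``len(barcode)`` nt is the read-orientation barcode.
    """
    if fwd_primer is None:
        core = oligo.variable_seq + oligo.barcode
        fwd_primer = oligo.full_seq[: oligo.full_seq.index(core)]
    return reverse_complement(fwd_primer + oligo.variable_seq + oligo.barcode)


class MappingIndex:
    """Exact-lookup barcode index plus the per-oligo expected read table."""

    def __init__(self, barcode_to_oligo: dict[str, str], expected: dict[str, str], policy: MappingPolicy):
        self.barcode_to_oligo = barcode_to_oligo
        self.expected = expected
        self.policy = policy
        self.oligo_ids = list(expected)

    def __len__(self) -> int:
        return len(self.barcode_to_oligo)


def build_index(manifest: Iterable[OligoRecord], policy: MappingPolicy | None = None) -> MappingIndex:
    """Build the exact barcode lookup and expected-read table for a manifest."""
    policy = policy or MappingPolicy()
    manifest = list(manifest)
    dupes = [bc for bc, k in Counter(o.barcode for o in manifest).items() if k > 1]
    if dupes:
        raise ValueError(f"duplicate barcodes in manifest: {dupes[:10]}")
    barcode_to_oligo: dict[str, str] = {}
    expected: dict[str, str] = {}
    for o in manifest:
        er = expected_read(o)
        barcode_to_oligo[er[: policy.barcode_len]] = o.oligo_id
        expected[o.oligo_id] = er
    return MappingIndex(barcode_to_oligo, expected, policy)


def map_read(read: str, index: MappingIndex, policy: MappingPolicy | None = None) -> tuple[str | None, str | None]:
    """Assign one read to an oligo.

    Returns ``(oligo_id, None)`` on success or ``(None, reason)`` with reason
    in {no_barcode, too_many_mismatches, too_short}.  ``N`` counts as a
    mismatch; other non-ACGTN characters raise.
    """
    policy = policy or index.policy
    if not _READ_ALPHABET.issuperset(read):
        bad = sorted(set(read) - _READ_ALPHABET)
        raise ValueError(f"read contains invalid characters {bad}")
    if len(read) < policy.barcode_len:
        return None, TOO_SHORT
    oligo_id = index.barcode_to_oligo.get(read[: policy.barcode_len])
    if oligo_id is None:
        return None, NO_BARCODE
    exp = index.expected[oligo_id]
    b = policy.barcode_len
    w = min(policy.check_len, len(read) - b, len(exp) - b)
    mism = sum(a != c for a, c in zip(read[b : b + w], exp[b : b + w]))
    if mism <= policy.max_mismatches:
        return oligo_id, None
    return None, TOO_MANY_MISMATCHES


def count_reads(
    reads: Iterable[str] | Iterator[tuple[str, str, str]],
    index: MappingIndex,
    policy: MappingPolicy | None = None,
    sample_id: str = "sample",
) -> tuple[pd.Series, dict]:
    """Count reads per oligo for one sample.

    ``reads`` yields either plain sequences or FASTQ ``(id, seq, qual)``
    tuples (qualities are ignored).  Returns a counts Series indexed by every
    manifest oligo (zeros kept) and a mapping report with total/mapped read
    numbers, the mapping fraction and per-reason unmapped tallies.
    """
    policy = policy or index.policy
    counts = Counter()
    unmapped = Counter()
    total = 0
    for item in reads:
        seq = item[1] if isinstance(item, tuple) else item
        total += 1
        oligo_id, reason = map_read(seq, index, policy)
        if oligo_id is not None:
            counts[oligo_id] += 1
        else:
            unmapped[reason] += 1
    col = pd.Series({oid: counts.get(oid, 0) for oid in index.oligo_ids}, name=sample_id, dtype=int)
    mapped = int(col.sum())
    report = {
        "sample_id": sample_id,
        "total_reads": total,
        "mapped_reads": mapped,
        "mapping_fraction": (mapped / total) if total else float("nan"),
        "unmapped": dict(unmapped),
    }
    return col, report


def qc_recovery(counts: pd.DataFrame, threshold: float = 0.70) -> pd.DataFrame:
    """Per-sample oligo recovery QC.

    A sample passes when at least ``threshold`` (default 70%, boundary
    inclusive) of all manifest oligos have a count of at least one.
    """
    if counts.shape[0] == 0:
        raise ValueError("empty manifest: counts table has no oligo rows")
    frac = (counts >= 1).sum(axis=0) / counts.shape[0]
    return pd.DataFrame({"recovered_fraction": frac, "pass": frac >= threshold})
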