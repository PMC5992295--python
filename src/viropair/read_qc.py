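"""Read-level quality control for virome sequencing reads.

Four filters applied in a fixed order, then an optional host screen:

1. truncate each read at the first base with Phred quality below
   ``phred_min`` (default 30); a read that truncation pushes below the
   minimum length is removed and counted against this rule;
2. remove reads containing a homopolymer run of >= ``homopolymer_max``
   (default 8) identical bases;
3. remove reads shorter than 50 nt or longer than 300 nt (bounds
   inclusive-retained: a 50 nt or 300 nt read survives);
4. remove reads containing any ambiguous (non-ACGT) base;
5. optionally remove reads with a local-alignment hit to a host reference
   at E below ``host_e_max`` (default 1e-5).

Each removed read is counted against the FIRST rule that removes it, so the
per-rule counts always sum to input minus output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

from .homology import DEFAULT_SCORING, ScoringParams, local_align

_UNAMBIGUOUS = frozenset("ACGT")


@dataclass
class Read:
    """One sequencing read: id, sequence, Phred+33 quality string, sample label."""

    id: str
    seq: str
    qual: str
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def phred(self) -> list[int]:
        return [ord(c) - 33 for c in self.qual]


@dataclass(frozen=True)
class QCParams:
    phred_min: int = 30
    homopolymer_max: int = 8
    len_min: int = 50
    len_max: int = 300
    host_e_max: float = 1e-5

    def __post_init__(self) -> None:
        if self.phred_min < 0:
            raise ValueError("phred_min must be >= 0")
        if self.len_min > self.len_max:
            raise ValueError("len_min must be <= len_max")
        if self.homopolymer_max < 1:
            raise ValueError("homopolymer_max must be >= 1")


@dataclass
class QCReport:
    """Per-rule removal counts; input = output + sum(removed)."""

    n_input: int = 0
    removed_quality_short: int = 0
    removed_homopolymer: int = 0
    removed_length: int = 0
    removed_ambiguous: int = 0
    removed_host: int = 0
    n_output: int = 0

    @property
    def total_removed(self) -> int:
        return (
            self.removed_quality_short
            + self.removed_homopolymer
            + self.removed_length
            + self.removed_ambiguous
            + self.removed_host
        )

    def as_dict(self) -> dict:
        return asdict(self)


def trim_by_quality(read: Read, phred_min: int = 30) -> Read:
    """Truncate a read at the first position with quality < ``phred_min``.

    The empty read is a legal result (it falls to the length filter later).
    """
    cut = len(read.seq)
    for i, q in enumerate(read.qual):
        if ord(q) - 33 < phred_min:
            cut = i
            break
    if cut == len(read.seq):
        return read
    return Read(read.id, read.seq[:cut], read.qual[:cut], read.source)


def has_long_homopolymer(seq: str, k: int = 8) -> bool:
    """True iff some base repeats >= ``k`` times consecutively."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not seq:
        return False
    run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run >= k:
            return True
    return k <= 1


def screen_host(
    reads: Sequence[Read],
    host_reference: Sequence[str] | str,
    e_max: float = 1e-5,
    scoring: ScoringParams = DEFAULT_SCORING,
) -> tuple[list[Read], int]:
    """Remove reads with a local-alignment hit to the host at E < ``e_max``."""
    if isinstance(host_reference, str):
        host_reference = [host_reference]
    host_seqs = [s for s in host_reference if s]
    if not host_seqs:
        raise ValueError("host reference is empty")
    retained: list[Read] = []
    removed = 0
    for read in reads:
        is_host = False
        for ref in host_seqs:
            hit = local_align(read.seq, ref, scoring)
            if hit is not None and hit.e_value < e_max:
                is_host = True
                break
        if is_host:
            removed += 1
        else:
            retained.append(read)
    return retained, removed


def qc_pipeline(
    reads: Iterable[Read],
    params: QCParams = QCParams(),
    host_reference: Sequence[str] | str | None = None,
    truncate: bool = True,
) -> tuple[list[Read], QCReport]:
    """Run the full QC cascade; returns retained reads and a QCReport.

    ``truncate=False`` switches rule 1 from truncation to whole-read
    discard when any base falls below ``phred_min``.
    """
    report = QCReport()
    survivors: list[Read] = []
    for read in reads:
        report.n_input += 1
        trimmed = trim_by_quality(read, params.phred_min)
        if not truncate and len(trimmed.seq) != len(read.seq):
            report.removed_quality_short += 1
            continue
        if len(trimmed.seq) != len(read.seq) and len(trimmed.seq) < params.len_min:
            report.removed_quality_short += 1
            continue
        if has_long_homopolymer(trimmed.seq, params.homopolymer_max):
            report.removed_homopolymer += 1
            continue
        if not params.len_min <= len(trimmed.seq) <= params.len_max:
            report.removed_length += 1
            continue
        if any(c not in _UNAMBIGUOUS for c in trimmed.seq):
            report.removed_ambiguous += 1
            continue
        survivors.append(trimmed)
    if host_reference is not None:
        survivors, n_host = screen_host(survivors, host_reference, params.host_e_max)
        report.removed_host = n_host
    report.n_output = len(survivors)
    assert report.n_input == report.n_output + report.total_removed
    return survivors, report
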