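"""Read quality control: terminal-N trimming and length/quality filtering.

A minimal re-specification of shotgun-read cleaning as used upstream of
model training: leading/trailing runs of N are trimmed (with matching
quality trimming), then reads shorter than a minimum length or with a mean
Phred score under a threshold are rejected.  Paired mates are treated as
independent reads and survivors concatenated.  Adapter detection and
overlap merging are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .seqio import ReadRecord

__all__ = ["QCParams", "QCReport", "qc_read", "qc_readset"]


@dataclass(frozen=True)
class QCParams:
    """Filtering thresholds.

    min_length: minimum post-trim read length in bases (ancient-DNA
    pipelines conventionally discard fragments under 25 bp).
    min_mean_quality: minimum arithmetic mean Phred score over the read.
    trim_terminal_n: remove leading/trailing N runs before filtering.
    """

    min_length: int = 25
    min_mean_quality: float = 20.0
    trim_terminal_n: bool = True

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.min_mean_quality < 0:
            raise ValueError("min_mean_quality must be >= 0")


@dataclass(frozen=True)
class QCReport:
    input_reads: int
    retained_reads: int

    @property
    def discarded_fraction(self) -> float:
        if self.input_reads == 0:
            return 0.0
        return 1.0 - self.retained_reads / self.input_reads


def qc_read(read: ReadRecord, params: QCParams = QCParams()) -> ReadRecord | None:
    """Trim and filter one read; returns None when the read is rejected."""
    seq = read.sequence
    qual = read.quality
    if params.trim_terminal_n:
        start = 0
        end = len(seq)
        while start < end and seq[start] == "N":
            start += 1
        while end > start and seq[end - 1] == "N":
            end -= 1
        seq = seq[start:end]
        qual = qual[start:end]
    if len(seq) < params.min_length:
        return None
    mean_q = sum(ord(c) - 33 for c in qual) / len(qual)
    if mean_q < params.min_mean_quality:
        return None
    if seq == read.sequence:
        return read
    return ReadRecord(id=read.id, sequence=seq, quality=qual, mate=read.mate)


def qc_readset(
    reads: Iterable[ReadRecord], params: QCParams = QCParams()
) -> tuple[list[ReadRecord], QCReport]:
    """Filter a read collection, preserving input order.

    Idempotent: re-applying to the retained set changes nothing.
    """
    retained = []
    n_in = 0
    for read in reads:
        n_in += 1
        kept = qc_read(read, params)
        if kept is not None:
            retained.append(kept)
    return retained, QCReport(input_reads=n_in, retained_reads=len(retained))
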