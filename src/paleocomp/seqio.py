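"""Sequence and alignment I/O.

FASTA and FASTQ parsing is delegated to Biopython, SAM to pysam; this module
maps them onto the toolkit's plain record types and enforces the ingest
contract: sequences are uppercased, U becomes T, any other IUPAC ambiguity
code collapses to N, and anything else is a format error.  SAM keeps its
1-based coordinates at the file boundary; everything internal is 0-based
half-open, and the converters here are the only place that shifts.
"""

from __future__ import annotations

import os
import string
import tempfile
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "ReadRecord",
    "AlignmentRecord",
    "FormatError",
    "SamConsistencyError",
    "FLAG_UNMAPPED",
    "FLAG_REVERSE",
    "ingest_sequence",
    "parse_fasta",
    "parse_fastq",
    "write_fasta",
    "write_fastq",
    "read_sam",
    "write_sam",
    "write_tsv",
    "atomic_path",
]

FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10


class FormatError(ValueError):
    """Malformed FASTA/FASTQ input."""


class SamConsistencyError(ValueError):
    """SAM records inconsistent with the supplied references."""


# IUPAC letters: keep ACGT, map U->T, collapse every other letter to N.
_INGEST = {}
for _c in string.ascii_uppercase:
    _INGEST[_c] = "N"
    _INGEST[_c.lower()] = "N"
for _c in "ACGTN":
    _INGEST[_c] = _c
    _INGEST[_c.lower()] = _c
_INGEST["U"] = _INGEST["u"] = "T"
_INGEST_TABLE = str.maketrans(_INGEST)


def ingest_sequence(raw: str) -> str:
    """Normalize a raw sequence string to the {A,C,G,T,N} alphabet."""
    cleaned = raw.translate(_INGEST_TABLE)
    leftover = set(cleaned) - set("ACGTN")
    if leftover:
        raise FormatError(f"non-nucleotide characters in sequence: {sorted(leftover)!r}")
    return cleaned


@dataclass
class SequenceRecord:
    """A reference sequence: id token, free-text description, ACGTN string."""

    id: str
    description: str = ""
    sequence: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise FormatError(f"invalid sequence id: {self.id!r}")
        if not self.sequence:
            raise FormatError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadRecord:
    """A sequencing read with Phred+33 qualities; mate is 1, 2 or 0 (unpaired)."""

    id: str
    sequence: str
    quality: str
    mate: int = 0

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.sequence):
            raise FormatError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def phred(self) -> list[int]:
        return [ord(c) - 33 for c in self.quality]


@dataclass
class AlignmentRecord:
    """A SAM alignment restricted to the M/S/=/X cigar dialect.

    ``pos`` is the 1-based leftmost reference coordinate (0 for unmapped
    records); only the unmapped (0x4) and reverse-strand (0x10) flag bits are
    interpreted.  Optional fields are carried as opaque (tag, type, value)
    tuples.
    """

    qname: str
    flag: int
    rname: str
    pos: int
    cigar: str
    seq: str
    qual: str = "*"
    mapq: int = 255
    tags: tuple = ()

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def parse_fasta(source: str | Path | IO[str]) -> list[SequenceRecord]:
    """Parse (possibly line-wrapped) FASTA into :class:`SequenceRecord` s."""
    records = []
    try:
        for rec in SeqIO.parse(source, "fasta"):
            seq = ingest_sequence(str(rec.seq))
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id) :].strip()
            records.append(SequenceRecord(id=rec.id, description=desc, sequence=seq))
    except ValueError as exc:  # Biopython signals structural problems this way
        raise FormatError(str(exc)) from exc
    return records


def parse_fastq(source: str | Path | IO[str]) -> list[ReadRecord]:
    """Parse 4-line FASTQ; qualities are kept verbatim (Phred+33)."""
    records = []
    try:
        for rec in SeqIO.parse(source, "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            mate = 0
            rid = rec.id
            if rid.endswith("/1"):
                mate = 1
            elif rid.endswith("/2"):
                mate = 2
            records.append(
                ReadRecord(
                    id=rid,
                    sequence=ingest_sequence(str(rec.seq)),
                    quality=qual,
                    mate=mate,
                )
            )
    except ValueError as exc:
        raise FormatError(str(exc)) from exc
    return records


def write_fasta(
    records: Iterable[SequenceRecord], dest: str | Path | IO[str], width: int = 70
) -> None:
    own = isinstance(dest, (str, Path))
    handle = open(dest, "w") if own else dest
    try:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")
    finally:
        if own:
            handle.close()


def write_fastq(records: Iterable[ReadRecord], dest: str | Path | IO[str]) -> None:
    own = isinstance(dest, (str, Path))
    handle = open(dest, "w") if own else dest
    try:
        for rec in records:
            handle.write(f"@{rec.id}\n{rec.sequence}\n+\n{rec.quality}\n")
    finally:
        if own:
            handle.close()


# ---------------------------------------------------------------------------
# SAM (via pysam)
# ---------------------------------------------------------------------------

_SUPPORTED_CIGAR_OPS = set("MS=X")


def _check_cigar(rec: AlignmentRecord) -> None:
    import re

    if rec.is_unmapped:
        return
    ops = re.findall(r"(\d+)([A-Z=])", rec.cigar)
    if not ops or "".join(f"{n}{o}" for n, o in ops) != rec.cigar:
        raise SamConsistencyError(f"{rec.qname}: unparseable cigar {rec.cigar!r}")
    bad = {o for _, o in ops} - _SUPPORTED_CIGAR_OPS
    if bad:
        raise SamConsistencyError(
            f"{rec.qname}: cigar ops {sorted(bad)} outside the M/S/=/X subset"
        )
    qlen = sum(int(n) for n, o in ops if o in "MS=X")
    if qlen != len(rec.seq):
        raise SamConsistencyError(
            f"{rec.qname}: cigar query length {qlen} != seq length {len(rec.seq)}"
        )


def write_sam(
    records: Iterable[AlignmentRecord],
    references: Sequence[tuple[str, int]],
    path: str | Path,
) -> None:
    """Write records to a text SAM file with @SQ lines for ``references``.

    Mapped records whose rname is absent from ``references`` raise
    :class:`SamConsistencyError`.
    """
    names = [n for n, _ in references]
    name_to_id = {n: i for i, n in enumerate(names)}
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": n, "LN": int(l)} for n, l in references],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            _check_cigar(rec)
            seg = pysam.AlignedSegment(header)
            seg.query_name = rec.qname
            seg.flag = rec.flag
            if rec.is_unmapped:
                seg.reference_id = -1
                seg.reference_start = -1
            else:
                if rec.rname not in name_to_id:
                    raise SamConsistencyError(
                        f"{rec.qname}: rname {rec.rname!r} absent from references"
                    )
                if rec.pos < 1:
                    raise SamConsistencyError(
                        f"{rec.qname}: mapped record with pos {rec.pos} < 1"
                    )
                seg.reference_id = name_to_id[rec.rname]
                seg.reference_start = rec.pos - 1  # SAM is 1-based on disk
                seg.cigarstring = rec.cigar
            seg.mapping_quality = rec.mapq
            seg.query_sequence = rec.seq
            if rec.qual != "*":
                seg.query_qualities = pysam.qualitystring_to_array(rec.qual)
            if rec.tags:
                seg.set_tags([(t, v, ty) for t, ty, v in rec.tags])
            out.write(seg)


def read_sam(path: str | Path) -> tuple[list[AlignmentRecord], list[tuple[str, int]]]:
    """Parse a text SAM file back into records plus its @SQ references."""
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        references = list(zip(sam.references, sam.lengths))
        for seg in sam:
            qual = "*"
            if seg.query_qualities is not None:
                qual = pysam.qualities_to_qualitystring(seg.query_qualities)
            # SAM text has a single integer type code; pysam reports the
            # packed in-memory width, so fold c/C/s/S/I back to 'i'
            tags = tuple(
                (tag, "i" if ty in "cCsSiI" else ty, val)
                for tag, val, ty in seg.get_tags(with_value_type=True)
            )
            records.append(
                AlignmentRecord(
                    qname=seg.query_name,
                    flag=seg.flag,
                    rname="*" if seg.reference_id < 0 else seg.reference_name,
                    pos=0 if seg.is_unmapped else seg.reference_start + 1,
                    cigar=seg.cigarstring or "*",
                    seq=seg.query_sequence or "",
                    qual=qual,
                    mapq=seg.mapping_quality,
                    tags=tags,
                )
            )
    return records, references


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------


def write_tsv(frame, dest: str | Path, float_format: str = "%.6g") -> None:
    """Write a DataFrame as tab-separated text with a header row."""
    frame.to_csv(dest, sep="\t", index=False, float_format=float_format)


@contextmanager
def atomic_path(path: str | Path) -> Iterator[str]:
    """Write to a temp file in the target directory, then rename into place."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    try:
        yield tmp
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)
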