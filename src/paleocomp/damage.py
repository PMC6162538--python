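"""Misincorporation profiling and ancient-vs-contaminant classification.

Post-mortem cytosine deamination leaves a chemical signature in ancient DNA:
an excess of C->T substitutions at the 5' ends of reads and, on the
complementary strand, G->A at the 3' ends, decaying towards the read
interior.  Modern contaminant DNA shows no such terminal excess.  This
module counts reference->read substitutions from SAM alignments by distance
from each read end (after strand correction, so position 1 is always the
biological 5' terminus) and applies a two-condition decision rule — an
absolute terminal C->T floor plus a fold change over the interior baseline —
to call a read set damaged (ancient-compatible) or not.

Only substitutions are profiled: cigars are restricted to M/S/=/X and
records with indels are rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .seqio import AlignmentRecord, SequenceRecord

__all__ = [
    "SUBSTITUTION_TYPES",
    "DamageProfile",
    "DamageSummary",
    "UnsupportedCigarError",
    "misincorporation_profile",
    "damage_summary",
]

#: the 12 ordered reference->read substitution types
SUBSTITUTION_TYPES = tuple(
    f"{r}>{q}" for r in "ACGT" for q in "ACGT" if r != q
)
_TYPE_INDEX = {t: i for i, t in enumerate(SUBSTITUTION_TYPES)}
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class UnsupportedCigarError(ValueError):
    """Alignment uses cigar operations outside the M/S/=/X subset."""


@dataclass
class DamageProfile:
    """Substitution frequencies by distance from the 5' and 3' read ends.

    ``counts5``/``counts3`` have shape (12, P): events of each substitution
    type at positions 1..P from the respective end (read orientation).
    ``denom5``/``denom3`` have shape (4, P): aligned positions with each
    reference base, the frequency denominators.
    """

    p: int
    counts5: np.ndarray
    counts3: np.ndarray
    denom5: np.ndarray
    denom3: np.ndarray
    n_alignments: int = 0

    def frequency(self, end: str, sub: str) -> np.ndarray:
        """Frequency curve of one substitution type from one end ('5' or '3')."""
        counts = self.counts5 if end == "5" else self.counts3
        denom = self.denom5 if end == "5" else self.denom3
        ref_base = sub[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            f = counts[_TYPE_INDEX[sub]] / denom[_BASE_INDEX[ref_base]]
        return np.where(denom[_BASE_INDEX[ref_base]] > 0, f, 0.0)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: end, position, substitution, count, denominator,
        frequency."""
        rows = []
        for end in ("5", "3"):
            counts = self.counts5 if end == "5" else self.counts3
            denom = self.denom5 if end == "5" else self.denom3
            for sub in SUBSTITUTION_TYPES:
                freq = self.frequency(end, sub)
                for pos in range(self.p):
                    rows.append(
                        (
                            end,
                            pos + 1,
                            sub,
                            int(counts[_TYPE_INDEX[sub], pos]),
                            int(denom[_BASE_INDEX[sub[0]], pos]),
                            freq[pos],
                        )
                    )
        return pd.DataFrame(
            rows,
            columns=["end", "position", "substitution", "count", "denominator", "frequency"],
        )


@dataclass(frozen=True)
class DamageSummary:
    """Terminal vs interior deamination summary and the damage call.

    ``damaged`` is True when the terminal 5' C->T frequency clears both an
    absolute floor and a fold change over the interior baseline; None when
    there was no terminal coverage to decide on.
    """

    ct5_terminal: float
    ga3_terminal: float
    interior_baseline: float
    damaged: bool | None
    abs_min: float = 0.05
    fold: float = 2.0


def _aligned_pairs(rec: AlignmentRecord) -> list[tuple[int, int]]:
    """(query_position, reference_offset) pairs for M/=/X ops; S consumes
    query only.  Reference offset is relative to rec.pos (0-based)."""
    ops = _CIGAR_RE.findall(rec.cigar)
    if not ops or "".join(f"{n}{o}" for n, o in ops) != rec.cigar:
        raise UnsupportedCigarError(f"{rec.qname}: unparseable cigar {rec.cigar!r}")
    pairs = []
    q = 0
    r = 0
    for n_str, op in ops:
        n = int(n_str)
        if op in "M=X":
            pairs.extend((q + i, r + i) for i in range(n))
            q += n
            r += n
        elif op == "S":
            q += n
        else:
            raise UnsupportedCigarError(
                f"{rec.qname}: cigar op {op!r} outside the M/S/=/X subset "
                "(indel-containing alignments are not profiled)"
            )
    return pairs


def misincorporation_profile(
    alignments: Iterable[AlignmentRecord],
    refs: Mapping[str, str] | Iterable[SequenceRecord],
    p: int = 25,
) -> DamageProfile:
    """Count reference->read substitution events near read ends.

    Reverse-strand alignments are orientation-corrected (both bases
    complemented, positions mirrored) so that position 1 is the biological
    5' end of the read as sequenced.  Soft-clipped bases count towards the
    distance from the read end but contribute no events.  N bases on either
    side are skipped.  Unmapped records are ignored; a mapped record whose
    rname is unknown raises KeyError.
    """
    if not isinstance(refs, Mapping):
        refs = {r.id: r.sequence for r in refs}
    counts5 = np.zeros((12, p), dtype=np.int64)
    counts3 = np.zeros((12, p), dtype=np.int64)
    denom5 = np.zeros((4, p), dtype=np.int64)
    denom3 = np.zeros((4, p), dtype=np.int64)
    n_aln = 0
    for rec in alignments:
        if rec.is_unmapped:
            continue
        if rec.rname not in refs:
            raise KeyError(f"alignment {rec.qname!r} maps to unknown reference {rec.rname!r}")
        ref_seq = refs[rec.rname]
        n_aln += 1
        read_len = len(rec.seq)
        start0 = rec.pos - 1
        for qpos, roff in _aligned_pairs(rec):
            rpos = start0 + roff
            if rpos >= len(ref_seq):
                raise KeyError(
                    f"alignment {rec.qname!r} runs past the end of {rec.rname!r}"
                )
            ref_base = ref_seq[rpos]
            read_base = rec.seq[qpos]
            if rec.is_reverse:
                ref_base = _COMP[ref_base]
                read_base = _COMP[read_base]
                pos_in_read = read_len - 1 - qpos
            else:
                pos_in_read = qpos
            if ref_base == "N" or read_base == "N":
                continue
            d5 = pos_in_read  # 0-based distance from the 5' end
            d3 = read_len - 1 - pos_in_read
            ref_i = _BASE_INDEX[ref_base]
            if d5 < p:
                denom5[ref_i, d5] += 1
                if read_base != ref_base:
                    counts5[_TYPE_INDEX[f"{ref_base}>{read_base}"], d5] += 1
            if d3 < p:
                denom3[ref_i, d3] += 1
                if read_base != ref_base:
                    counts3[_TYPE_INDEX[f"{ref_base}>{read_base}"], d3] += 1
    return DamageProfile(
        p=p,
        counts5=counts5,
        counts3=counts3,
        denom5=denom5,
        denom3=denom3,
        n_alignments=n_aln,
    )


def damage_summary(
    profile: DamageProfile, abs_min: float = 0.05, fold: float = 2.0
) -> DamageSummary:
    """Summarize terminal deamination and call the damage status.

    ct5_terminal: mean C->T frequency at 5' positions 1-3; ga3_terminal:
    mean G->A at 3' positions 1-3; interior_baseline: mean of both curves
    over positions 11..P.  damaged = (ct5 >= abs_min) and
    (ct5 >= fold * interior_baseline); None if the terminal positions have
    no coverage at all.
    """
    ct5 = profile.frequency("5", "C>T")
    ga3 = profile.frequency("3", "G>A")
    term_cov = (
        profile.denom5[_BASE_INDEX["C"], :3].sum()
        + profile.denom3[_BASE_INDEX["G"], :3].sum()
    )
    ct5_terminal = float(ct5[:3].mean())
    ga3_terminal = float(ga3[:3].mean())
    interior = float(np.concatenate([ct5[10 : profile.p], ga3[10 : profile.p]]).mean())
    if term_cov == 0:
        damaged: bool | None = None
    else:
        damaged = (ct5_terminal >= abs_min) and (ct5_terminal >= fold * interior)
    return DamageSummary(
        ct5_terminal=ct5_terminal,
        ga3_terminal=ga3_terminal,
        interior_baseline=interior,
        damaged=damaged,
        abs_min=abs_min,
        fold=fold,
    )
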