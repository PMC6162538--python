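"""Relative-compression similarity: NRC/NRS, reference ranking, database
intra-similarity, and per-read similarity filtering.

The Normalized Relative Compression (NRC) of a target x under a model
trained exclusively on other data is ``bits(x) / (2 |x|)`` — code length
normalized by the 2 bits/base of the DNA alphabet.  NRC near 1 means the
model carries no information about x; near 0, x is almost fully predictable.
The Normalized Relative Similarity is its percent complement,
``NRS = 100 (1 - min(NRC, 1))``, a conservative similarity estimate that
does not overestimate.

Per-read scoring is the one place the convention differs: inside a 101 bp
read the first k_max positions have no full-depth context and carry the flat
2-bit fallback, a fixed overhead that would cap read NRS far below 100 no
matter how well the read matches.  Read NRC is therefore computed over the
mixture-coded (informative) positions only; whole-sequence NRC keeps the
plain bits/(2L) definition, where the k_max-position edge is negligible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fcm_core import (
    DEFAULT_ENSEMBLE,
    READ_ENSEMBLE,
    EnsembleConfig,
    FrozenModel,
    ReadCost,
    train_model,
)
from .seqio import ReadRecord, SequenceRecord

__all__ = [
    "SimilarityRecord",
    "FilterResult",
    "similarity_from_bits",
    "read_similarity",
    "rank_references",
    "intra_similarity_matrix",
    "train_reference_model",
    "per_read_similarity",
    "filter_reads_by_similarity",
    "RANKING_COLUMNS",
]

RANKING_COLUMNS = ["rank", "ref_id", "ref_length", "bits", "nrc", "nrs"]


@dataclass(frozen=True)
class SimilarityRecord:
    """One row of a ranking table: a reference scored under a sample model."""

    ref_id: str
    ref_length: int
    bits: float
    nrc: float
    nrs: float


def similarity_from_bits(bits: float, length: int) -> tuple[float, float]:
    """(NRC, NRS) from a code length and the target length in bases.

    NRC = bits / (2 length); NRS = 100 (1 - min(NRC, 1)) — NRC is clipped at
    1 before the percent complement, so incompressible targets score 0%.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if bits < 0:
        raise ValueError("bits must be non-negative")
    nrc = bits / (2.0 * length)
    nrs = 100.0 * (1.0 - min(nrc, 1.0))
    return nrc, nrs


def read_similarity(cost: ReadCost) -> tuple[float, float]:
    """(NRC, NRS) of a single read, normalized over informative positions.

    Reads too short to contain any full-depth context score NRC 1 (NRS 0):
    the model demonstrably predicted nothing.
    """
    if cost.n_informative == 0:
        return 1.0, 0.0
    nrc = cost.informative_bits / (2.0 * cost.n_informative)
    return nrc, 100.0 * (1.0 - min(nrc, 1.0))


def rank_references(
    model: FrozenModel,
    refs: Iterable[SequenceRecord],
    top_n: int | None = 500,
) -> pd.DataFrame:
    """Score every reference under the frozen sample model and rank by NRS.

    References are compressed independently (mixture weights reset each
    time).  Sorted by NRS descending, ties broken by ref_id; truncated to
    ``top_n`` rows (None = keep all).  Zero-length references are skipped
    with a warning.
    """
    rows = []
    for ref in refs:
        if len(ref.sequence) < 1:
            warnings.warn(f"reference {ref.id!r} is empty; skipped")
            continue
        bits = model.encode_cost(ref.sequence)
        nrc, nrs = similarity_from_bits(bits, len(ref.sequence))
        rows.append((ref.id, len(ref.sequence), bits, nrc, nrs))
    frame = pd.DataFrame(rows, columns=["ref_id", "ref_length", "bits", "nrc", "nrs"])
    frame = frame.sort_values(
        ["nrs", "ref_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if top_n is not None:
        frame = frame.head(top_n).copy()
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return frame


def intra_similarity_matrix(
    refs: Sequence[SequenceRecord],
    config: EnsembleConfig = DEFAULT_ENSEMBLE,
) -> pd.DataFrame:
    """Pairwise NRS among references: entry (i, j) scores reference j under
    a model trained only on reference i.

    Near-duplicate references (e.g. two assemblies of one species) show as
    high off-diagonal blocks, separating redundant detections from
    independent ones.  The diagonal is computed like any entry.
    """
    if len(refs) < 2:
        raise ValueError("intra-similarity needs at least 2 references")
    ids = [r.id for r in refs]
    matrix = np.zeros((len(refs), len(refs)))
    for i, ref_i in enumerate(refs):
        model = train_model([ref_i.sequence], config)
        for j, ref_j in enumerate(refs):
            bits = model.encode_cost(ref_j.sequence)
            _, nrs = similarity_from_bits(bits, len(ref_j.sequence))
            matrix[i, j] = nrs
    return pd.DataFrame(matrix, index=ids, columns=ids)


def train_reference_model(
    reference: SequenceRecord | str,
    config: EnsembleConfig = READ_ENSEMBLE,
) -> FrozenModel:
    """Train a frozen model on a single reference sequence (both strands are
    captured when the ensemble's models use inverted-repeat counting)."""
    seq = reference if isinstance(reference, str) else reference.sequence
    return train_model([seq], config)


def per_read_similarity(
    reference: SequenceRecord | str,
    reads: Sequence[ReadRecord],
    config: EnsembleConfig = READ_ENSEMBLE,
    model: FrozenModel | None = None,
) -> pd.DataFrame:
    """Score each read against a reference-trained model.

    A model is trained on the reference (unless a pre-trained ``model`` is
    supplied), frozen, and every read scored independently, weights reset per
    read.  Output preserves read order; columns: read_id, length, bits, nrc,
    nrs.
    """
    if model is None:
        model = train_reference_model(reference, config)
    costs = model.encode_reads(reads)
    rows = []
    for read, cost in zip(reads, costs):
        nrc, nrs = read_similarity(cost)
        rows.append((read.id, cost.length, cost.total_bits, nrc, nrs))
    return pd.DataFrame(rows, columns=["read_id", "length", "bits", "nrc", "nrs"])


@dataclass
class FilterResult:
    """Outcome of similarity-threshold read partitioning."""

    below: list[ReadRecord]
    above: list[ReadRecord]
    table: pd.DataFrame
    threshold: float

    @property
    def n_below(self) -> int:
        return len(self.below)

    @property
    def n_above(self) -> int:
        return len(self.above)


def filter_reads_by_similarity(
    reads: Sequence[ReadRecord],
    reference: SequenceRecord | str,
    threshold: float = 0.95,
    config: EnsembleConfig = READ_ENSEMBLE,
) -> FilterResult:
    """Partition reads by similarity to a reference.

    Reads with nrs/100 strictly above ``threshold`` go to ``above`` (the
    endogenous-like set, removed before re-analysing the remainder); the
    rest go to ``below``.  Threshold 0.95 accepts a 0.05 read dissimilarity,
    keeping flanking and evolutionarily drifted regions in the re-analysis.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    table = per_read_similarity(reference, reads, config)
    above_mask = (table["nrs"].to_numpy() / 100.0) > threshold
    below = [r for r, hit in zip(reads, above_mask) if not hit]
    above = [r for r, hit in zip(reads, above_mask) if hit]
    return FilterResult(below=below, above=above, table=table, threshold=threshold)
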