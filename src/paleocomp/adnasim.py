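"""Synthetic ancient-metagenome generator.

Emulates a nonamplified shotgun sample of an ancient specimen: an endogenous
genome fragmented into short inserts (truncated log-normal, never under
25 bp), mixed with modern contaminant genomes at given proportions,
deaminated at the fragment ends (position-dependent C->T from the 5' end and
G->A from the 3' end, decaying geometrically), sequenced as fixed-length
reads with per-base error and Phred+33 qualities.  Every read carries full
ground truth (source, coordinates, strand, pre-damage fragment), emitted as
FASTQ + truth SAM + manifest.  All outputs are pure functions of the
configuration, including its seed.

The damage model is a simplified exponential-decay deamination, not a
nick-based fragmentation chemistry model: it reproduces the terminal
C->T / G->A signature that damage-pattern classification relies on, which
is what desk-scale validation needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fcm_core import reverse_complement
from .seqio import (
    AlignmentRecord,
    FLAG_REVERSE,
    ReadRecord,
    SequenceRecord,
    atomic_path,
    write_fasta,
    write_fastq,
    write_sam,
    write_tsv,
)

__all__ = [
    "DamageParams",
    "FragmentDist",
    "ContaminantSpec",
    "SimConfig",
    "Fragment",
    "SimResult",
    "random_genome",
    "mutate_sequence",
    "generate_references",
    "fragment_genome",
    "apply_damage",
    "simulate_sample",
    "write_sim",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class DamageParams:
    """Deamination parameters.

    A cytosine at 0-based 5' offset i flips to T with probability
    ``baseline + (d5 - baseline) * decay**i``; a guanine at 3' offset j
    flips to A with ``baseline + (d3 - baseline) * decay**j``.
    """

    d5: float = 0.30
    d3: float = 0.30
    decay: float = 0.5
    baseline: float = 0.01

    def __post_init__(self) -> None:
        for name in ("d5", "d3", "decay", "baseline"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class FragmentDist:
    """Log-normal insert-size distribution truncated to
    [min_length, read_length + max_overhang].

    Defaults (mu = ln 70, sigma = 0.35) give the short-fragment regime
    typical of ancient libraries while respecting the 25-base floor.
    """

    mu: float = math.log(70.0)
    sigma: float = 0.35
    min_length: int = 25
    max_overhang: int = 50


@dataclass(frozen=True)
class ContaminantSpec:
    """One contaminant source.

    Either ``sequence`` is supplied or a genome of ``length`` bases is
    generated.  ``divergence_from`` names another source whose genome is
    substitution-mutated at rate ``divergence`` to produce this one (a
    shared ancestor).  ``damage`` defaults to None: contaminants model
    modern, undamaged DNA.
    """

    id: str
    proportion: float
    length: int | None = None
    sequence: str | None = None
    divergence: float = 0.0
    divergence_from: str | None = None
    damage: DamageParams | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.proportion <= 1.0):
            raise ValueError("proportion must be in [0, 1]")
        if self.sequence is None and self.length is None and self.divergence_from is None:
            raise ValueError(f"contaminant {self.id!r}: need sequence, length or ancestor")
        if not (0.0 <= self.divergence <= 1.0):
            raise ValueError("divergence must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of a synthetic ancient sample."""

    seed: int = 1
    endogenous_id: str = "endogenous"
    endogenous_length: int = 50_000
    contaminants: tuple[ContaminantSpec, ...] = ()
    coverage: float | None = None
    read_count: int | None = None
    read_length: int = 101
    fragment: FragmentDist = field(default_factory=FragmentDist)
    damage: DamageParams | None = field(default_factory=DamageParams)
    error_rate: float = 0.001
    quality_mean: float = 36.0
    quality_sd: float = 3.0
    markov_order: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 25:
            raise ValueError("read_length must be >= 25")
        if not (0.0 <= self.error_rate <= 1.0):
            raise ValueError("error_rate must be in [0, 1]")
        total = sum(c.proportion for c in self.contaminants)
        if total > 1.0 + 1e-9:
            raise ValueError("contaminant proportions sum past 1")
        if self.markov_order not in (0, 2):
            raise ValueError("markov_order must be 0 (i.i.d.) or 2")

    @property
    def endogenous_proportion(self) -> float:
        return 1.0 - sum(c.proportion for c in self.contaminants)


@dataclass(frozen=True)
class Fragment:
    """A sampled insert: 0-based start on the source, strand, and the
    strand-oriented (pre-damage) sequence."""

    start: int
    strand: str  # '+' or '-'
    sequence: str


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------


def random_genome(length: int, rng: np.random.Generator, markov_order: int = 0) -> str:
    """Sample a genome: i.i.d.-uniform (order 0) or order-2 Markov with
    Dirichlet(1)-sampled transition rows."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if markov_order == 0:
        return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()
    if markov_order != 2:
        raise ValueError("markov_order must be 0 or 2")
    trans = rng.dirichlet(np.ones(4), size=16)  # rows indexed by 2-mer context
    cum = np.cumsum(trans, axis=1)
    out = np.empty(length, dtype=np.int64)
    out[:2] = rng.integers(0, 4, size=2)
    u = rng.random(length)
    for t in range(2, length):
        ctx = out[t - 2] * 4 + out[t - 1]
        out[t] = int(np.searchsorted(cum[ctx], u[t]))
    return bytes(_BASES[out]).decode()


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently at ``rate`` (always to a different
    base); N positions are untouched."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    acgt = np.array([arr == b for b in _BASES]).any(axis=0)
    hit = (rng.random(len(arr)) < rate) & acgt
    idx = np.nonzero(hit)[0]
    if len(idx):
        base_i = np.searchsorted(np.sort(_BASES), arr[idx])
        # map the current base's index via its position in sorted ACGT
        order = np.argsort(_BASES)
        cur = order[base_i]
        shift = rng.integers(1, 4, size=len(idx))
        arr[idx] = _BASES[(cur + shift) % 4]
    return arr.tobytes().decode()


def generate_references(cfg: SimConfig, rng: np.random.Generator) -> list[SequenceRecord]:
    """Endogenous + contaminant genomes, deterministic under the rng state.

    Contaminants with ``divergence_from`` are mutated copies of the named
    source (which must precede them: the endogenous genome or an earlier
    contaminant)."""
    refs = [
        SequenceRecord(
            id=cfg.endogenous_id,
            description="endogenous source",
            sequence=random_genome(cfg.endogenous_length, rng, cfg.markov_order),
        )
    ]
    by_id = {refs[0].id: refs[0].sequence}
    for spec in cfg.contaminants:
        if spec.sequence is not None:
            seq = spec.sequence
        elif spec.divergence_from is not None:
            if spec.divergence_from not in by_id:
                raise ValueError(
                    f"contaminant {spec.id!r}: unknown ancestor {spec.divergence_from!r}"
                )
            seq = mutate_sequence(by_id[spec.divergence_from], spec.divergence, rng)
        else:
            seq = random_genome(spec.length, rng, cfg.markov_order)
            if spec.divergence > 0:
                seq = mutate_sequence(seq, spec.divergence, rng)
        rec = SequenceRecord(id=spec.id, description="contaminant source", sequence=seq)
        refs.append(rec)
        by_id[spec.id] = seq
    return refs


# ---------------------------------------------------------------------------
# fragmentation / damage / sequencing
# ---------------------------------------------------------------------------


def _sample_length(
    dist: FragmentDist, read_length: int, genome_length: int, rng: np.random.Generator
) -> int:
    upper = min(read_length + dist.max_overhang, genome_length)
    lower = min(dist.min_length, genome_length)
    for _ in range(1000):
        raw = int(round(rng.lognormal(dist.mu, dist.sigma)))
        if lower <= raw <= upper:
            return raw
    return lower  # pathological parameterization: fall back to the floor


def fragment_genome(
    genome: str,
    n: int,
    dist: FragmentDist,
    rng: np.random.Generator,
    read_length: int = 101,
) -> list[Fragment]:
    """Draw ``n`` fragments: truncated log-normal lengths, uniform starts,
    uniform strand; reverse-strand fragments are reverse-complemented."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = []
    for _ in range(n):
        flen = _sample_length(dist, read_length, len(genome), rng)
        start = int(rng.integers(0, len(genome) - flen + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = genome[start : start + flen]
        if strand == "-":
            seq = reverse_complement(seq)
        out.append(Fragment(start=start, strand=strand, sequence=seq))
    return out


def apply_damage(
    fragment: str, damage: DamageParams | None, rng: np.random.Generator
) -> str:
    """Deaminate one fragment (no-op when ``damage`` is None).

    C at 5' offset i -> T with baseline + (d5-baseline)*decay**i;
    G at 3' offset j -> A with baseline + (d3-baseline)*decay**j.
    A position is a C or a G, never both, so one uniform draw per position
    decides.
    """
    if damage is None:
        return fragment
    L = len(fragment)
    if L == 0:
        return fragment
    arr = np.frombuffer(fragment.encode(), dtype=np.uint8).copy()
    offsets5 = np.arange(L, dtype=np.float64)
    offsets3 = offsets5[::-1]
    p_ct = damage.baseline + (damage.d5 - damage.baseline) * damage.decay**offsets5
    p_ga = damage.baseline + (damage.d3 - damage.baseline) * damage.decay**offsets3
    u = rng.random(L)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    arr[is_c & (u < p_ct)] = ord("T")
    arr[is_g & (u < p_ga)] = ord("A")
    return arr.tobytes().decode()


def _sequence_read(
    fragment: str,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Truncate a fragment to the read length, apply per-base error, and
    draw Phred+33 qualities."""
    read = fragment[: cfg.read_length]
    L = len(read)
    arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
    if cfg.error_rate > 0:
        acgt = np.array([arr == b for b in _BASES]).any(axis=0)
        hit = (rng.random(L) < cfg.error_rate) & acgt
        idx = np.nonzero(hit)[0]
        if len(idx):
            order = np.argsort(_BASES)
            cur = order[np.searchsorted(np.sort(_BASES), arr[idx])]
            shift = rng.integers(1, 4, size=len(idx))
            arr[idx] = _BASES[(cur + shift) % 4]
    quals = np.clip(np.rint(rng.normal(cfg.quality_mean, cfg.quality_sd, L)), 2, 41)
    qual = bytes((quals + 33).astype(np.uint8)).decode()
    return arr.tobytes().decode(), qual


# ---------------------------------------------------------------------------
# the full sample
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    """A simulated sample with complete per-read ground truth."""

    config: SimConfig
    refs: list[SequenceRecord]
    reads: list[ReadRecord]
    truth: list[AlignmentRecord]
    fragments: list[Fragment]
    sources: list[str]
    manifest: pd.DataFrame


def _total_reads(cfg: SimConfig) -> int:
    if cfg.read_count is not None:
        return cfg.read_count
    coverage = cfg.coverage if cfg.coverage is not None else 5.0
    endo = max(cfg.endogenous_proportion, 1e-9)
    return max(1, int(round(coverage * cfg.endogenous_length / cfg.read_length / endo)))


def simulate_sample(cfg: SimConfig) -> SimResult:
    """Generate the sample: references, reads, truth alignments, manifest.

    Deterministic: identical configurations (including the seed) produce
    byte-identical outputs.  Truth SAM coordinates point at the genuine
    source interval of each read; reverse-strand reads are stored
    reference-oriented with the 0x10 flag, per SAM convention.
    """
    rng = np.random.default_rng(cfg.seed)
    refs = generate_references(cfg, rng)
    damage_of = {cfg.endogenous_id: cfg.damage}
    for spec in cfg.contaminants:
        damage_of[spec.id] = spec.damage
    genomes = {r.id: r.sequence for r in refs}
    source_ids = [r.id for r in refs]
    props = [cfg.endogenous_proportion] + [c.proportion for c in cfg.contaminants]
    n_total = _total_reads(cfg)
    choice = rng.choice(len(source_ids), size=n_total, p=np.asarray(props) / sum(props))

    reads: list[ReadRecord] = []
    truth: list[AlignmentRecord] = []
    fragments: list[Fragment] = []
    sources: list[str] = []
    for i in range(n_total):
        src = source_ids[int(choice[i])]
        genome = genomes[src]
        frag = fragment_genome(genome, 1, cfg.fragment, rng, cfg.read_length)[0]
        damaged = apply_damage(frag.sequence, damage_of[src], rng)
        seq, qual = _sequence_read(damaged, cfg, rng)
        rid = f"read{i:06d}"
        reads.append(ReadRecord(id=rid, sequence=seq, quality=qual))
        flen = len(frag.sequence)
        rlen = len(seq)
        if frag.strand == "+":
            pos = frag.start + 1
            sam_seq, sam_qual = seq, qual
            flag = 0
        else:
            # the read covers the last rlen bases of the source interval
            pos = frag.start + (flen - rlen) + 1
            sam_seq, sam_qual = reverse_complement(seq), qual[::-1]
            flag = FLAG_REVERSE
        truth.append(
            AlignmentRecord(
                qname=rid,
                flag=flag,
                rname=src,
                pos=pos,
                cigar=f"{rlen}M",
                seq=sam_seq,
                qual=sam_qual,
                mapq=60,
            )
        )
        fragments.append(frag)
        sources.append(src)

    counts = pd.Series(sources).value_counts()
    manifest = pd.DataFrame(
        {
            "source": source_ids,
            "genome_length": [len(genomes[s]) for s in source_ids],
            "proportion_requested": props,
            "n_reads": [int(counts.get(s, 0)) for s in source_ids],
            "damaged": [damage_of[s] is not None for s in source_ids],
        }
    )
    manifest["seed"] = cfg.seed
    return SimResult(
        config=cfg,
        refs=refs,
        reads=reads,
        truth=truth,
        fragments=fragments,
        sources=sources,
        manifest=manifest,
    )


def write_sim(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write sample.fq, truth.sam, refs.fa and manifest.tsv atomically."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reads": outdir / "sample.fq",
        "truth": outdir / "truth.sam",
        "refs": outdir / "refs.fa",
        "manifest": outdir / "manifest.tsv",
    }
    with atomic_path(paths["reads"]) as tmp:
        write_fastq(result.reads, tmp)
    with atomic_path(paths["refs"]) as tmp:
        write_fasta(result.refs, tmp)
    with atomic_path(paths["truth"]) as tmp:
        write_sam(result.truth, [(r.id, len(r.sequence)) for r in result.refs], tmp)
    with atomic_path(paths["manifest"]) as tmp:
        write_tsv(result.manifest, tmp)
    return paths
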