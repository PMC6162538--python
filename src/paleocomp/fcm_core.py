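"""Finite-context-model mixture coder for DNA.

This module implements a *relative compressor*: an ensemble of order-k Markov
(finite-context) models over the {A,C,G,T} alphabet whose counts are learned
from a training corpus (e.g. the reads of a shotgun sample), then frozen.
Evaluating a target sequence under the frozen ensemble yields a code length in
bits; short code lengths mean the target shares information with the training
data.  The ensemble combines:

* regular context models of several depths, with additive-alpha smoothing and
  optional *inverted-repeat* (IR) counting, which records every k+1 window
  together with its reverse-complement twin and so makes the model
  strand-symmetric;
* a *substitution-tolerant* context model that, on a misprediction, repairs
  its own context history with the predicted symbol (up to a tolerance) so
  that isolated substitutions do not wipe out an otherwise matching context;
* soft-blending of the per-model probabilities with a decaying forgetting
  factor gamma: weights are updated as ``w_m <- normalize(w_m**gamma * P_m)``,
  favouring the models that predicted recent symbols well.

Counting and per-model probability gathering are vectorized with numpy; the
inherently sequential mixture/tolerant recursion runs in a tight scalar loop.
"""

from __future__ import annotations

import json
import math
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ALPHABET",
    "FALLBACK_BITS",
    "CMConfig",
    "TolerantCMConfig",
    "EnsembleConfig",
    "DEFAULT_ENSEMBLE",
    "READ_ENSEMBLE",
    "CountBuilder",
    "ContextCounts",
    "FrozenModel",
    "ReadCost",
    "EncodeResult",
    "TolerantState",
    "encode_symbols",
    "reverse_complement",
    "complement",
    "cm_probability",
    "cm_train_update",
    "tolerant_step",
    "mixture_step",
    "adaptive_encode_cost",
    "train_model",
]

ALPHABET = "ACGT"
#: flat cost charged at positions that cannot be coded by the mixture
#: (symbol N, or fewer than k_max clean preceding symbols): the uniform
#: 2 bits/base of the 4-letter alphabet.
FALLBACK_BITS = 2.0

_SYM_INDEX = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_A2I = np.full(256, -2, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _A2I[ord(_c)] = _i
_A2I[ord("N")] = -1


class AlphabetError(ValueError):
    """Sequence contains symbols outside {A,C,G,T,N}."""


def encode_symbols(seq: str) -> np.ndarray:
    """Map a DNA string to int8 codes (A=0, C=1, G=2, T=3, N=-1)."""
    arr = _A2I[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == -2).any():
        bad = sorted(set(seq) - set("ACGTN"))
        raise AlphabetError(f"symbols outside ACGTN: {bad!r}")
    return arr


def complement(base: str) -> str:
    if base not in "ACGTN":
        raise AlphabetError(f"not a DNA base: {base!r}")
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Reverse complement (A<->T, C<->G, N->N); an involution."""
    encode_symbols(seq)  # validate alphabet
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CMConfig:
    """A regular finite-context model: order ``k``, additive smoothing
    ``alpha``, and strand-symmetric (inverted-repeat) counting if ``ir``."""

    k: int
    alpha: float
    ir: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.k <= 24):
            raise ValueError(f"context order k must be in [1, 24], got {self.k}")
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")


@dataclass(frozen=True)
class TolerantCMConfig:
    """Substitution-tolerant context model.

    Shares the count store of the regular model with the same depth and keeps
    an *edited* context history: on a misprediction the predicted (argmax)
    symbol replaces the observed one in the history, surviving up to
    ``tolerance`` accumulated misses before the history resets to the literal
    past.
    """

    k: int
    alpha: float
    tolerance: int

    def __post_init__(self) -> None:
        if not (1 <= self.k <= 24):
            raise ValueError(f"context order k must be in [1, 24], got {self.k}")
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass(frozen=True)
class EnsembleConfig:
    """Mixture of regular and tolerant context models.

    ``gamma`` is the decaying forgetting factor of the soft-blending weight
    update; ``cache_mb`` bounds the per-model count-table memory (lowest-count
    contexts are pruned deterministically when exceeded; ``None`` = exact).
    """

    regular: tuple[CMConfig, ...]
    tolerant: tuple[TolerantCMConfig, ...] = ()
    gamma: float = 0.95
    cache_mb: float | None = 250.0

    def __post_init__(self) -> None:
        if not self.regular:
            raise ValueError("at least one regular context model is required")
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must be in (0, 1]")
        depths = {m.k for m in self.regular}
        for t in self.tolerant:
            if t.k not in depths:
                raise ValueError(
                    f"tolerant model of depth {t.k} has no same-depth regular "
                    "model to share counts with"
                )

    @property
    def kmax(self) -> int:
        return max(m.k for m in self.regular)

    @property
    def n_models(self) -> int:
        return len(self.regular) + len(self.tolerant)


#: Default ensemble: four regular CMs and one tolerant CM with a 0.95
#: forgetting factor — the configuration used for whole-sample training.
DEFAULT_ENSEMBLE = EnsembleConfig(
    regular=(
        CMConfig(k=20, alpha=0.005, ir=True),
        CMConfig(k=14, alpha=0.01, ir=True),
        CMConfig(k=11, alpha=0.1, ir=False),
        CMConfig(k=6, alpha=1.0, ir=False),
    ),
    tolerant=(TolerantCMConfig(k=20, alpha=0.1, tolerance=5),),
    gamma=0.95,
    cache_mb=250.0,
)

#: Reduced ensemble for scoring short (~101 bp) reads against a reference:
#: deep contexts barely fire inside a read, so only moderate depths are kept.
#: Alphas are small because a single pass over a reference leaves count-1
#: contexts, where heavy smoothing would dominate the per-read code length.
READ_ENSEMBLE = EnsembleConfig(
    regular=(
        CMConfig(k=11, alpha=0.01, ir=True),
        CMConfig(k=6, alpha=1.0, ir=True),
    ),
    tolerant=(),
    gamma=0.95,
    cache_mb=250.0,
)


# ---------------------------------------------------------------------------
# count stores
# ---------------------------------------------------------------------------


class CountBuilder:
    """Mutable, dictionary-backed count store for one context model.

    This is the reference (and training-time diagnostic) path: contexts are
    plain strings and updates happen one event at a time, honouring the
    inverted-repeat twin rule.  The batch trainer must agree with it exactly.
    """

    def __init__(self, cfg: CMConfig) -> None:
        self.cfg = cfg
        self.counts: dict[str, list[int]] = {}

    def update(self, context: str, symbol: str) -> None:
        """Record one event; with IR also its reverse-complement twin.

        For the window ``w = context + symbol`` of length k+1 the twin event
        is symbol ``complement(w[0])`` under context ``rc(w[1:])``.
        """
        if len(context) != self.cfg.k:
            raise ValueError(f"context length {len(context)} != k={self.cfg.k}")
        self._inc(context, symbol)
        if self.cfg.ir:
            window = context + symbol
            self._inc(reverse_complement(window[1:]), complement(window[0]))

    def _inc(self, context: str, symbol: str) -> None:
        row = self.counts.setdefault(context, [0, 0, 0, 0])
        row[_SYM_INDEX[symbol]] += 1

    def get_counts(self, context: str) -> tuple[int, int, int, int]:
        return tuple(self.counts.get(context, (0, 0, 0, 0)))

    def freeze(self) -> "ContextCounts":
        codes = np.empty(len(self.counts), dtype=np.int64)
        counts = np.empty((len(self.counts), 4), dtype=np.int64)
        for i, (ctx, row) in enumerate(self.counts.items()):
            code = 0
            for ch in ctx:
                code = code * 4 + _SYM_INDEX[ch]
            codes[i] = code
            counts[i] = row
        order = np.argsort(codes)
        return ContextCounts(self.cfg.k, codes[order], counts[order])


def cm_train_update(builder: CountBuilder, context: str, symbol: str) -> CountBuilder:
    """Functional form of :meth:`CountBuilder.update` (returns the builder)."""
    builder.update(context, symbol)
    return builder


class ContextCounts:
    """Read-only count table of one regular context model.

    Contexts are packed 2 bits/symbol into int64 codes, kept sorted so that
    batched lookups are a single ``searchsorted``.  Unseen contexts read as
    all-zero counts.
    """

    __slots__ = ("k", "codes", "counts", "totals", "_codes_list")

    def __init__(self, k: int, codes: np.ndarray, counts: np.ndarray) -> None:
        self.k = int(k)
        self.codes = np.asarray(codes, dtype=np.int64)
        self.counts = np.asarray(counts, dtype=np.int64)
        self.totals = self.counts.sum(axis=1)
        self._codes_list: list[int] | None = None

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def n_contexts(self) -> int:
        return len(self.codes)

    @property
    def total_events(self) -> int:
        return int(self.totals.sum())

    def rows_for(self, query: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row indices and a found-mask for an array of context codes."""
        idx = np.searchsorted(self.codes, query)
        idx_c = np.minimum(idx, max(len(self.codes) - 1, 0))
        if len(self.codes):
            found = self.codes[idx_c] == query
        else:
            found = np.zeros(len(query), dtype=bool)
        return idx_c, found

    def counts_for_code(self, code: int) -> tuple[int, int, int, int]:
        if self._codes_list is None:
            self._codes_list = self.codes.tolist()
        lst = self._codes_list
        i = bisect_left(lst, code)
        if i < len(lst) and lst[i] == code:
            row = self.counts[i]
            return int(row[0]), int(row[1]), int(row[2]), int(row[3])
        return (0, 0, 0, 0)

    def get_counts(self, context: str) -> tuple[int, int, int, int]:
        if len(context) != self.k:
            raise ValueError(f"context length {len(context)} != k={self.k}")
        code = 0
        for ch in context:
            code = code * 4 + _SYM_INDEX[ch]
        return self.counts_for_code(code)

    def equals(self, other: "ContextCounts") -> bool:
        return (
            self.k == other.k
            and np.array_equal(self.codes, other.codes)
            and np.array_equal(self.counts, other.counts)
        )


def cm_probability(store, cfg, context: str, symbol: str) -> float:
    """P(symbol | context) = (n(c,s) + alpha) / (sum_s' n(c,s') + 4 alpha).

    ``store`` is anything with ``get_counts(context)`` (:class:`CountBuilder`
    or :class:`ContextCounts`).
    """
    counts = store.get_counts(context)
    a = cfg.alpha
    return (counts[_SYM_INDEX[symbol]] + a) / (sum(counts) + 4.0 * a)


# ---------------------------------------------------------------------------
# batch training
# ---------------------------------------------------------------------------


def _window_context_codes(s: np.ndarray, k: int, starts: np.ndarray) -> np.ndarray:
    """Packed codes of s[t:t+k] for each t in ``starts`` (chunked matmul)."""
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    out = np.empty(len(starts), dtype=np.int64)
    win = sliding_window_view(s, k)
    chunk = 1 << 18
    for lo in range(0, len(starts), chunk):
        sel = starts[lo : lo + chunk]
        out[lo : lo + chunk] = win[sel].astype(np.int64) @ powers
    return out


def _count_model(s: np.ndarray, cfg: CMConfig, cache_mb: float | None) -> ContextCounts:
    """Count all valid (context, symbol) events of one model over a symbol
    stream (int8 codes, -1 marks N / read separators)."""
    k = cfg.k
    n = len(s)
    if n < k + 1:
        return ContextCounts(k, np.empty(0, np.int64), np.empty((0, 4), np.int64))
    # window s[t:t+k+1] is valid iff it contains no negative symbol
    bad = np.concatenate(([0], np.cumsum(s < 0)))
    valid = (bad[k + 1 :] - bad[: n - k]) == 0
    starts = np.nonzero(valid)[0]
    if len(starts) == 0:
        return ContextCounts(k, np.empty(0, np.int64), np.empty((0, 4), np.int64))
    ctx = _window_context_codes(s, k, starts)
    sym = s[starts + k].astype(np.int64)
    keys = ctx * 4 + sym
    if cfg.ir:
        # twin of window w0..wk: context rc(w1..wk), symbol complement(w0);
        # code(rc(w1..wk)) = sum_i (3 - w_i) * 4**(i-1)
        comp = (3 - s).astype(np.int8)
        powers_rev = 4 ** np.arange(0, k, dtype=np.int64)
        win = sliding_window_view(comp, k)
        tctx = np.empty(len(starts), dtype=np.int64)
        chunk = 1 << 18
        for lo in range(0, len(starts), chunk):
            sel = starts[lo : lo + chunk] + 1
            tctx[lo : lo + chunk] = win[sel].astype(np.int64) @ powers_rev
        tsym = 3 - s[starts].astype(np.int64)
        keys = np.concatenate([keys, tctx * 4 + tsym])
    ukeys, kcounts = np.unique(keys, return_counts=True)
    uctx = ukeys >> 2
    usym = (ukeys & 3).astype(np.intp)
    ctx_codes, first = np.unique(uctx, return_index=True)
    rows = np.searchsorted(ctx_codes, uctx)
    counts = np.zeros((len(ctx_codes), 4), dtype=np.int64)
    counts[rows, usym] = kcounts
    store = ContextCounts(k, ctx_codes, counts)
    if cache_mb is not None:
        budget = int(cache_mb * 2**20 // 40)  # ~40 bytes per context row
        if store.n_contexts > budget > 0:
            order = np.lexsort((store.codes, -store.totals))[:budget]
            keep = np.sort(order)
            store = ContextCounts(k, store.codes[keep], store.counts[keep])
    return store


def _as_sequences(reads: Iterable) -> list[str]:
    out = []
    for r in reads:
        out.append(r if isinstance(r, str) else r.sequence)
    return out


def _concatenate(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate sequences with single N separators.

    Returns the int8 stream and the start offset of each sequence.  The
    separator makes every cross-boundary window invalid, so contexts never
    span read boundaries.
    """
    starts = np.empty(len(seqs), dtype=np.int64)
    parts = []
    off = 0
    sep = np.array([-1], dtype=np.int8)
    for i, q in enumerate(seqs):
        starts[i] = off
        a = encode_symbols(q)
        parts.append(a)
        off += len(a)
        if i != len(seqs) - 1:
            parts.append(sep)
            off += 1
    if not parts:
        return np.empty(0, dtype=np.int8), starts
    return np.concatenate(parts), starts


def train_model(reads: Iterable, cfg: EnsembleConfig = DEFAULT_ENSEMBLE) -> "FrozenModel":
    """Learn the ensemble's count tables from a read set and freeze them.

    ``reads`` may be raw strings or records with a ``sequence`` attribute.
    Every regular model counts each in-read position that has k clean
    (non-N) preceding symbols; tolerant models share stores and contribute
    no counts.  The result is read-only: evaluation never mutates counts.
    """
    seqs = _as_sequences(reads)
    stream, _ = _concatenate(seqs)
    stores = tuple(_count_model(stream, m, cfg.cache_mb) for m in cfg.regular)
    return FrozenModel(cfg, stores)


# ---------------------------------------------------------------------------
# mixture / tolerant primitives (reference forms, also used by tests)
# ---------------------------------------------------------------------------


def mixture_step(
    weights: Sequence[float], probs: Sequence[float], gamma: float
) -> tuple[float, list[float]]:
    """One soft-blending step.

    Returns the mixture probability ``sum_m w_m P_m`` under the *current*
    weights, and the updated weights ``normalize(w_m**gamma * P_m)``.
    """
    p_mix = sum(w * p for w, p in zip(weights, probs))
    raw = [w**gamma * p for w, p in zip(weights, probs)]
    z = sum(raw)
    return p_mix, [r / z for r in raw]


@dataclass
class TolerantState:
    """Edit buffer (k symbols) and miss counter of a tolerant model."""

    buffer: str
    misses: int = 0


def tolerant_step(
    state: TolerantState,
    store,
    cfg: TolerantCMConfig,
    observed: str,
    literal_context: str,
) -> tuple[float, TolerantState]:
    """One tolerant-model step (reference implementation).

    The probability of ``observed`` is read from the shared store using the
    *edit* buffer as context.  After the symbol is revealed: on a hit
    (observed equals the store's argmax prediction, ties broken A<C<G<T) the
    observed symbol is appended and the miss counter decays by one (floor 0);
    on a miss the predicted symbol is appended instead and the counter
    increments; once misses exceed the tolerance the buffer resets to
    ``literal_context`` (the true last k symbols, including ``observed``)
    and the counter zeroes.
    """
    counts = store.get_counts(state.buffer)
    a = cfg.alpha
    p = (counts[_SYM_INDEX[observed]] + a) / (sum(counts) + 4.0 * a)
    best = 0
    for i in range(1, 4):
        if counts[i] > counts[best]:
            best = i
    predicted = ALPHABET[best]
    if observed == predicted:
        new = TolerantState(state.buffer[1:] + observed, max(0, state.misses - 1))
    else:
        new = TolerantState(state.buffer[1:] + predicted, state.misses + 1)
        if new.misses > cfg.tolerance:
            new = TolerantState(literal_context, 0)
    return p, new


# ---------------------------------------------------------------------------
# frozen model evaluation
# ---------------------------------------------------------------------------


@dataclass
class ReadCost:
    """Code-length summary of one read under a frozen model."""

    length: int
    total_bits: float
    informative_bits: float
    n_informative: int


@dataclass
class EncodeResult:
    """Per-position code lengths of a sequence under a frozen model.

    ``informative`` marks the positions coded by the mixture; the rest
    carry the flat 2-bit fallback.
    """

    bits: np.ndarray
    informative: np.ndarray

    @property
    def total_bits(self) -> float:
        return float(self.bits.sum())


class FrozenModel:
    """Trained, read-only context-model ensemble (the "sample model")."""

    def __init__(self, config: EnsembleConfig, stores: tuple[ContextCounts, ...]):
        if len(stores) != len(config.regular):
            raise ValueError("one count store per regular model is required")
        for cfg, st in zip(config.regular, stores):
            if cfg.k != st.k:
                raise ValueError("store depth does not match model depth")
        self.config = config
        self.stores = stores
        self._store_by_k = {st.k: st for st in stores}

    @property
    def kmax(self) -> int:
        ks = [m.k for m in self.config.regular]
        ks += [t.k for t in self.config.tolerant]
        return max(ks)

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, seq: str) -> EncodeResult:
        """Per-position code lengths of one sequence (weights reset once,
        at the start)."""
        s, starts = _concatenate([seq]) if seq else (np.empty(0, np.int8), np.zeros(1, np.int64))
        bits, informative = self._evaluate_stream(s, np.array([0], dtype=np.int64))
        return EncodeResult(bits=bits, informative=informative)

    def encode_cost(self, seq: str) -> float:
        """Total code length in bits (empty sequence costs 0)."""
        if not seq:
            return 0.0
        return self.evaluate(seq).total_bits

    def encode_reads(self, reads: Iterable) -> list[ReadCost]:
        """Score each read independently (mixture weights reset per read)."""
        seqs = _as_sequences(reads)
        if not seqs:
            return []
        stream, starts = _concatenate(seqs)
        bits, informative = self._evaluate_stream(stream, starts)
        out = []
        for i, q in enumerate(seqs):
            lo = int(starts[i])
            hi = lo + len(q)
            b = bits[lo:hi]
            m = informative[lo:hi]
            out.append(
                ReadCost(
                    length=len(q),
                    total_bits=float(b.sum()),
                    informative_bits=float(b[m].sum()),
                    n_informative=int(m.sum()),
                )
            )
        return out

    # -- internals ----------------------------------------------------------

    def _evaluate_stream(
        self, s: np.ndarray, seg_starts: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate a concatenated symbol stream.

        ``seg_starts`` are offsets where mixture weights reset (one entry per
        independent sequence).  Returns per-position bits (fallback positions
        = 2.0, separator positions excluded by the caller via slicing) and
        the informative mask.
        """
        L = len(s)
        bits = np.full(L, FALLBACK_BITS, dtype=np.float64)
        informative = np.zeros(L, dtype=bool)
        kmax = self.kmax
        if L == 0:
            return bits, informative
        # a position t is mixture-coded iff t >= kmax, s[t] != N and the
        # previous kmax symbols are clean (no N, no read separator)
        bad = np.concatenate(([0], np.cumsum(s < 0, dtype=np.int64)))
        ok = np.zeros(L, dtype=bool)
        if L > kmax:
            t = np.arange(kmax, L)
            ok[kmax:] = (s[kmax:] >= 0) & ((bad[t] - bad[t - kmax]) == 0)
        pos = np.nonzero(ok)[0]
        # separator/fallback N positions inside the stream still read 2.0 in
        # `bits`; callers slice per-read ranges so separators never surface.
        if len(pos) == 0:
            informative[:] = False
            return bits, informative
        informative[pos] = True

        sym = s[pos].astype(np.int64)
        codes_by_k: dict[int, np.ndarray] = {}

        def ctx_codes(k: int) -> np.ndarray:
            if k not in codes_by_k:
                codes_by_k[k] = _window_context_codes(s, k, pos - k)
            return codes_by_k[k]

        per_model_p: list[list[float]] = []
        for cfg, store in zip(self.config.regular, self.stores):
            q = ctx_codes(cfg.k)
            rows, found = store.rows_for(q)
            if len(store):
                n_sym = np.where(found, store.counts[rows, sym], 0)
                tot = np.where(found, store.totals[rows], 0)
            else:
                n_sym = np.zeros(len(q), dtype=np.int64)
                tot = n_sym
            p = (n_sym + cfg.alpha) / (tot + 4.0 * cfg.alpha)
            per_model_p.append(p.tolist())

        tol_specs = []
        for tcfg in self.config.tolerant:
            store = self._store_by_k[tcfg.k]
            tol_specs.append(
                (
                    tcfg.alpha,
                    tcfg.tolerance,
                    (1 << (2 * tcfg.k)) - 1,
                    store.codes.tolist(),
                    store.counts,
                    store.totals.tolist() if len(store) else [],
                    ctx_codes(tcfg.k).tolist(),
                )
            )

        n_reg = len(self.config.regular)
        n_tol = len(tol_specs)
        nm = n_reg + n_tol
        gamma = self.config.gamma
        pos_list = pos.tolist()
        sym_list = sym.tolist()
        seg_of = np.searchsorted(seg_starts, pos, side="right").tolist()
        log2 = math.log2
        uniform = [1.0 / nm] * nm

        out_bits = [0.0] * len(pos_list)
        w = list(uniform)
        # tolerant runtime state: (buffer_code, misses, force_literal)
        tstate = [(0, 0, True) for _ in range(n_tol)]
        prev_t = -2
        prev_seg = -1
        pm = [0.0] * nm
        for i, t in enumerate(pos_list):
            seg = seg_of[i]
            if seg != prev_seg:
                w = list(uniform)
                for j in range(n_tol):
                    tstate[j] = (0, 0, True)
            discont = t != prev_t + 1
            for m in range(n_reg):
                pm[m] = per_model_p[m][i]
            o = sym_list[i]
            for j, (a, tol, mask, codes_l, counts_m, totals_l, lit) in enumerate(
                tol_specs
            ):
                buf, miss, force = tstate[j]
                if force or discont:
                    buf = lit[i]
                    miss = 0
                r = bisect_left(codes_l, buf)
                if r < len(codes_l) and codes_l[r] == buf:
                    row = counts_m[r]
                    c0 = int(row[0]); c1 = int(row[1]); c2 = int(row[2]); c3 = int(row[3])
                    tot = totals_l[r]
                else:
                    c0 = c1 = c2 = c3 = 0
                    tot = 0
                if o == 0:
                    cs = c0
                elif o == 1:
                    cs = c1
                elif o == 2:
                    cs = c2
                else:
                    cs = c3
                pm[n_reg + j] = (cs + a) / (tot + 4.0 * a)
                # argmax with ties broken A<C<G<T
                best, cb = 0, c0
                if c1 > cb:
                    best, cb = 1, c1
                if c2 > cb:
                    best, cb = 2, c2
                if c3 > cb:
                    best, cb = 3, c3
                if o == best:
                    buf = ((buf << 2) | o) & mask
                    miss = miss - 1 if miss > 0 else 0
                    force = False
                else:
                    buf = ((buf << 2) | best) & mask
                    miss += 1
                    force = miss > tol
                tstate[j] = (buf, miss, force)
            p_mix = 0.0
            z = 0.0
            raw = [0.0] * nm
            for m in range(nm):
                wp = w[m]
                p = pm[m]
                p_mix += wp * p
                r_ = (wp**gamma) * p
                raw[m] = r_
                z += r_
            out_bits[i] = -log2(p_mix)
            for m in range(nm):
                w[m] = raw[m] / z
            prev_t = t
            prev_seg = seg
        bits[pos] = out_bits
        return bits, informative

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Save as an .npz dump (config header + per-model context/count
        tables).  Not an interchange format."""
        meta = {
            "regular": [
                {"k": m.k, "alpha": m.alpha, "ir": m.ir} for m in self.config.regular
            ],
            "tolerant": [
                {"k": t.k, "alpha": t.alpha, "tolerance": t.tolerance}
                for t in self.config.tolerant
            ],
            "gamma": self.config.gamma,
            "cache_mb": self.config.cache_mb,
        }
        arrays = {"meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
        for i, st in enumerate(self.stores):
            arrays[f"codes_{i}"] = st.codes
            arrays[f"counts_{i}"] = st.counts
        # a file handle keeps numpy from appending ".npz" to the path
        with open(path, "wb") as fh:
            np.savez_compressed(fh, **arrays)

    @classmethod
    def load(cls, path) -> "FrozenModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            regular = tuple(CMConfig(**m) for m in meta["regular"])
            tolerant = tuple(TolerantCMConfig(**t) for t in meta["tolerant"])
            cfg = EnsembleConfig(
                regular=regular,
                tolerant=tolerant,
                gamma=meta["gamma"],
                cache_mb=meta["cache_mb"],
            )
            stores = tuple(
                ContextCounts(m.k, data[f"codes_{i}"], data[f"counts_{i}"])
                for i, m in enumerate(regular)
            )
        return cls(cfg, stores)


# ---------------------------------------------------------------------------
# adaptive single-model coder (training-time diagnostics / oracle variant)
# ---------------------------------------------------------------------------


def adaptive_encode_cost(seq: str, cfg: CMConfig) -> float:
    """Adaptive code length of ``seq`` under a single context model that
    starts empty and updates its counts after coding each symbol.

    Positions with symbol N, or with fewer than k clean preceding symbols,
    cost the flat 2 bits and do not update counts.  Used as a self-check of
    the estimator arithmetic; the frozen ensemble is the production path.
    """
    builder = CountBuilder(cfg)
    k = cfg.k
    total = 0.0
    clean = 0  # clean (non-N) symbols immediately preceding the cursor
    for t, ch in enumerate(seq):
        if ch == "N":
            total += FALLBACK_BITS
            clean = 0
            continue
        if ch not in _SYM_INDEX:
            raise AlphabetError(f"symbol {ch!r} outside ACGTN")
        if clean < k:
            total += FALLBACK_BITS
            clean += 1
            continue
        ctx = seq[t - k : t]
        total += -math.log2(cm_probability(builder, cfg, ctx, ch))
        builder.update(ctx, ch)
        clean += 1
    return total
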