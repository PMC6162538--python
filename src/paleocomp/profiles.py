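"""Complexity profiles and similar-segment extraction.

The information profile of a reference under a frozen sample model is the
per-position code length, in bits, of one left-to-right evaluation (weights
adapting, counts frozen).  Dips in the profile mark regions of the reference
represented in the sample.  Converting bits to a bounded similarity
``s = 1 - min(bits, 2)/2``, low-pass smoothing it, and extracting
above-threshold runs yields a segment map — the per-region counterpart of
the whole-genome NRS.

Smoothing uses a circular (wrap-around) centered moving average: most
organelle, plasmid and prokaryotic references are circular molecules, and
the circular kernel preserves the profile mean exactly, so segmenting never
creates or destroys similarity mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fcm_core import FALLBACK_BITS, FrozenModel
from .seqio import SequenceRecord

__all__ = [
    "InformationProfile",
    "Segment",
    "FilterParams",
    "information_profile",
    "similarity_track",
    "smooth_and_segment",
    "segments_to_frame",
    "frame_to_segments",
    "render_map",
    "SEGMENT_COLUMNS",
]

SEGMENT_COLUMNS = ["ref_id", "start", "end", "mean_similarity"]


@dataclass
class InformationProfile:
    """Per-position code length (bits) of one reference under a model."""

    ref_id: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.float64)
        if self.bits.ndim != 1:
            raise ValueError("profile must be one-dimensional")
        if (self.bits < 0).any():
            raise ValueError("code lengths cannot be negative")

    def __len__(self) -> int:
        return len(self.bits)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ref_id": self.ref_id,
                "position": np.arange(1, len(self.bits) + 1),
                "bits": self.bits,
            }
        )


@dataclass(frozen=True)
class Segment:
    """A similar region; 0-based half-open internally (TSV output is 1-based
    closed)."""

    ref_id: str
    start: int
    end: int
    mean_similarity: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FilterParams:
    """Segment-extraction knobs.

    window: moving-average width in positions; threshold: similarity cut in
    (0,1); min_len: minimum segment length kept; merge_gap: segments closer
    than this merge (defaults to the window).
    """

    window: int = 500
    threshold: float = 0.5
    min_len: int = 100
    merge_gap: int | None = None

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")

    @property
    def gap(self) -> int:
        return self.window if self.merge_gap is None else self.merge_gap


def information_profile(model: FrozenModel, ref: SequenceRecord) -> InformationProfile:
    """Evaluate a reference and keep the per-position bits.

    Positions the mixture cannot code (N, or the first k_max) carry the flat
    2-bit fallback, exactly as in the total code length.
    """
    result = model.evaluate(ref.sequence)
    return InformationProfile(ref_id=ref.id, bits=result.bits)


def _circular_moving_average(values: np.ndarray, window: int) -> np.ndarray:
    n = len(values)
    if window <= 1 or n == 1:
        return values.astype(np.float64, copy=True)
    w = min(window, n)
    left = (w - 1) // 2
    right = w // 2
    padded = np.concatenate([values[n - left :], values, values[:right]])
    kernel = np.full(w, 1.0 / w)
    return np.convolve(padded, kernel, mode="valid")


def similarity_track(profile: InformationProfile, window: int = 500) -> np.ndarray:
    """Smoothed per-position similarity ``s = 1 - min(bits, 2)/2`` in [0,1].

    Bits are clamped at 2 first, so momentary coder excursions above
    2 bits/base cannot push similarity negative.
    """
    s = 1.0 - np.minimum(profile.bits, FALLBACK_BITS) / FALLBACK_BITS
    return _circular_moving_average(s, window)


def smooth_and_segment(
    profile: InformationProfile, params: FilterParams = FilterParams()
) -> list[Segment]:
    """Extract maximal above-threshold runs of the smoothed similarity.

    Runs with smoothed s >= threshold become candidate segments; segments
    separated by less than ``merge_gap`` merge; merged segments shorter than
    ``min_len`` are dropped.  Reported mean similarity is the mean of the
    smoothed track over the segment.
    """
    if len(profile) == 0:
        raise ValueError("profile is empty")
    smoothed = similarity_track(profile, params.window)
    above = smoothed >= params.threshold
    runs: list[tuple[int, int]] = []
    in_run = False
    start = 0
    for i, flag in enumerate(above):
        if flag and not in_run:
            in_run = True
            start = i
        elif not flag and in_run:
            in_run = False
            runs.append((start, i))
    if in_run:
        runs.append((start, len(above)))
    merged: list[tuple[int, int]] = []
    for lo, hi in runs:
        if merged and lo - merged[-1][1] < params.gap:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))
    segments = []
    for lo, hi in merged:
        if hi - lo < params.min_len:
            continue
        segments.append(
            Segment(
                ref_id=profile.ref_id,
                start=lo,
                end=hi,
                mean_similarity=float(np.clip(smoothed[lo:hi].mean(), 0.0, 1.0)),
            )
        )
    return segments


def segments_to_frame(segments: Sequence[Segment]) -> pd.DataFrame:
    """Tabular form; coordinates are converted to 1-based closed."""
    rows = [
        (s.ref_id, s.start + 1, s.end, s.mean_similarity) for s in segments
    ]
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def frame_to_segments(frame: pd.DataFrame) -> list[Segment]:
    """Inverse of :func:`segments_to_frame` (back to 0-based half-open)."""
    return [
        Segment(
            ref_id=str(r.ref_id),
            start=int(r.start) - 1,
            end=int(r.end),
            mean_similarity=float(r.mean_similarity),
        )
        for r in frame.itertuples(index=False)
    ]


# four-colour quartile palette, low to high similarity
_QUARTILE_COLOURS = ("#2c7bb6", "#abd9e9", "#fdae61", "#d7191c")


def _quartile_colour(similarity: float) -> str:
    idx = min(3, int(similarity * 4.0))
    return _QUARTILE_COLOURS[idx]


def render_map(
    segments: Sequence[Segment],
    ref_lengths: Mapping[str, int],
    width: float = 900.0,
    bar_height: float = 18.0,
    gap: float = 10.0,
) -> str:
    """Render segments as an SVG map: one horizontal bar per reference,
    segments coloured by similarity quartile.  Byte-deterministic for fixed
    input."""
    names = list(ref_lengths)
    max_len = max((ref_lengths[n] for n in names), default=1)
    label_w = 160.0
    height = gap + len(names) * (bar_height + gap)
    scale = (width - label_w - 20.0) / max(max_len, 1)
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
        f'height="{height:.0f}" font-family="monospace" font-size="11">'
    ]
    by_ref: dict[str, list[Segment]] = {n: [] for n in names}
    for seg in segments:
        if seg.ref_id in by_ref:
            by_ref[seg.ref_id].append(seg)
    y = gap
    for name in names:
        bar_w = ref_lengths[name] * scale
        parts.append(
            f'<text x="4" y="{y + bar_height * 0.72:.2f}">{name}</text>'
        )
        parts.append(
            f'<rect x="{label_w:.2f}" y="{y:.2f}" width="{bar_w:.2f}" '
            f'height="{bar_height:.2f}" fill="#eeeeee" stroke="#555555"/>'
        )
        for seg in sorted(by_ref[name], key=lambda s: s.start):
            x = label_w + seg.start * scale
            w = max((seg.end - seg.start) * scale, 0.5)
            colour = _quartile_colour(seg.mean_similarity)
            parts.append(
                f'<rect x="{x:.2f}" y="{y:.2f}" width="{w:.2f}" '
                f'height="{bar_height:.2f}" fill="{colour}"/>'
            )
        y += bar_height + gap
    parts.append("</svg>")
    return "\n".join(parts)
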