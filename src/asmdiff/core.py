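"""Shared domain types and interval algebra.

Every pipeline stage works on 0-based half-open coordinates on named
sequences.  External formats that use 1-based inclusive coordinates
(nucmer show-coords, GFF3) are converted at the I/O boundary and
converted back on write, so all arithmetic in the package follows a
single convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "AlignmentBlock",
    "WindowDensity",
    "ParameterError",
    "InputError",
    "merge_intervals",
    "contains",
    "window_density",
]


class ParameterError(ValueError):
    """A stage parameter violates its documented domain."""


class InputError(ValueError):
    """An input record is inconsistent with its declared context."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open span [start, end) on a named sequence.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unknown).  Ordering is
    lexicographic by (seq_id, start, end), which is the sort order every
    writer in the package emits.
    """

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ParameterError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ParameterError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ParameterError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class AlignmentBlock:
    """One whole-genome alignment segment.

    ``orientation`` is ``inverted`` exactly when the raw query
    coordinates were given with start > end; the stored query interval
    is always normalised to start < end.
    """

    ref: GenomicInterval
    query: GenomicInterval
    orientation: str  # "forward" | "inverted"
    pct_identity: float

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "inverted"):
            raise ParameterError(f"bad orientation {self.orientation!r}")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise InputError(
                f"percent identity outside [0, 100]: {self.pct_identity}"
            )

    @property
    def ref_aln_length(self) -> int:
        return self.ref.length()

    @property
    def inverted(self) -> bool:
        return self.orientation == "inverted"


@dataclass(frozen=True)
class WindowDensity:
    """Feature count and covered-base fraction for one tiling window."""

    window: GenomicInterval
    count: int
    fraction: float

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ParameterError("window count must be non-negative")
        if not 0.0 <= self.fraction <= 1.0:
            raise ParameterError(f"window fraction outside [0, 1]: {self.fraction}")


def merge_intervals(
    intervals: Iterable[GenomicInterval], max_gap: int
) -> list[GenomicInterval]:
    """Merge intervals whose separation is at most ``max_gap``.

    Separation between consecutive intervals on the same sequence is
    ``next.start - prev.end``; bookended intervals have separation 0 and
    always merge.  Merging never crosses sequence names.  Output is the
    minimal disjoint cover, sorted by (seq_id, start).
    """
    if max_gap < 0:
        raise ParameterError(f"max_gap must be >= 0, got {max_gap}")
    ordered = sorted(intervals, key=lambda iv: (iv.seq_id, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ordered:
        if merged and merged[-1].seq_id == iv.seq_id and iv.start - merged[-1].end <= max_gap:
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(prev.seq_id, prev.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.seq_id, iv.start, iv.end))
    return merged


def contains(outer: GenomicInterval, inner: GenomicInterval) -> bool:
    """True iff ``inner`` lies entirely within ``outer`` (same sequence)."""
    return outer.contains(inner)


def window_density(
    features: Sequence[GenomicInterval],
    seq_lengths: Mapping[str, int],
    width: int = 100_000,
) -> list[WindowDensity]:
    """Tile each sequence with fixed-width windows and summarise features.

    A feature is *counted* in the window containing its start offset,
    so per-sequence counts always sum to the number of features there.
    ``fraction`` is the covered-base fraction of the window (union of
    feature overlaps / window length), for coverage-type tracks.
    """
    if width <= 0:
        raise ParameterError(f"window width must be > 0, got {width}")
    for f in features:
        if f.seq_id not in seq_lengths:
            raise InputError(f"feature on unknown sequence: {f}")
        if f.end > seq_lengths[f.seq_id]:
            raise InputError(
                f"feature beyond sequence length {seq_lengths[f.seq_id]}: {f}"
            )

    by_seq: dict[str, list[GenomicInterval]] = {}
    for f in features:
        by_seq.setdefault(f.seq_id, []).append(f)

    out: list[WindowDensity] = []
    for seq_id in sorted(seq_lengths):
        seq_len = seq_lengths[seq_id]
        n_windows = max(1, math.ceil(seq_len / width))
        counts = [0] * n_windows
        covered = [0] * n_windows
        feats = sorted(by_seq.get(seq_id, []), key=lambda iv: iv.start)
        merged_cov = merge_intervals(feats, 0) if feats else []
        for f in feats:
            counts[min(f.start // width, n_windows - 1)] += 1
        for m in merged_cov:
            w0, w1 = m.start // width, (m.end - 1) // width
            for w in range(w0, min(w1, n_windows - 1) + 1):
                lo = max(m.start, w * width)
                hi = min(m.end, min((w + 1) * width, seq_len))
                covered[w] += max(0, hi - lo)
        for w in range(n_windows):
            w_start = w * width
            w_end = min(w_start + width, seq_len)
            out.append(
                WindowDensity(
                    window=GenomicInterval(seq_id, w_start, w_end),
                    count=counts[w],
                    fraction=covered[w] / (w_end - w_start),
                )
            )
    return out
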