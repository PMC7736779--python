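"""Region-context analyses on a reference assembly.

Covers: placing another assembly's gap flanks (to locate sequence that
assembly is missing), repeat composition of placed regions,
pericentromere localisation from genetically mapped flanking markers,
and CpG methylation calling with 100-kb window tracks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import (
    GenomicInterval,
    InputError,
    WindowDensity,
    merge_intervals,
    window_density,
)
from .io import GapFlankAlignment, GeneModel, MarkerHit, MethylationSite
from .params import GapPlacementParams, MethylationParams

__all__ = [
    "PlacedGap",
    "PericentromereCall",
    "place_gaps",
    "repeat_composition",
    "locate_pericentromere",
    "compare_pericentromeres",
    "call_methylation",
]


@dataclass(frozen=True)
class PlacedGap:
    """A gap placed on the reference: span from leftmost flank start to
    rightmost flank end."""

    gap_id: str
    span: GenomicInterval

    @property
    def span_bases(self) -> int:
        return self.span.length()


@dataclass(frozen=True)
class PericentromereCall:
    chromosome: str
    region: GenomicInterval
    gene_count: int = 0

    @property
    def size_bases(self) -> int:
        return self.region.length()


def place_gaps(
    flank_alignments: Sequence[GapFlankAlignment],
    params: GapPlacementParams | None = None,
) -> tuple[list[PlacedGap], dict[str, str], dict]:
    """Place gaps whose flank pair satisfies the stringent criteria.

    A (left, right) candidate pair qualifies when both flanks hit the
    same sequence, each scores above ``min_score``, each aligns at least
    ``min_aligned_length`` bases, and the enclosing span stays under
    ``max_span``.  Among qualifying pairs the minimal span wins.

    Returns (placed, rejections, summary); ``rejections`` maps gap_id to
    the reason the gap could not be placed, so placed + rejected always
    partition the input gaps.
    """
    p = params or GapPlacementParams()
    by_gap: dict[str, dict[str, list[GapFlankAlignment]]] = {}
    for f in flank_alignments:
        by_gap.setdefault(f.gap_id, {"left": [], "right": []})[f.side].append(f)

    placed: list[PlacedGap] = []
    rejections: dict[str, str] = {}
    for gap_id in sorted(by_gap):
        lefts, rights = by_gap[gap_id]["left"], by_gap[gap_id]["right"]
        if not lefts or not rights:
            rejections[gap_id] = "missing_side"
            continue
        best = None
        saw_same_seq = saw_filter_pass = False
        for lf in lefts:
            for rf in rights:
                if lf.target.seq_id != rf.target.seq_id:
                    continue
                saw_same_seq = True
                if not (lf.score > p.min_score and rf.score > p.min_score):
                    continue
                if not (
                    lf.aligned_length >= p.min_aligned_length
                    and rf.aligned_length >= p.min_aligned_length
                ):
                    continue
                saw_filter_pass = True
                start = min(lf.target.start, rf.target.start)
                end = max(lf.target.end, rf.target.end)
                if end - start >= p.max_span:
                    continue
                span = GenomicInterval(lf.target.seq_id, start, end)
                if best is None or span.length() < best.length():
                    best = span
        if best is not None:
            placed.append(PlacedGap(gap_id=gap_id, span=best))
        elif not saw_same_seq:
            rejections[gap_id] = "cross_sequence"
        elif not saw_filter_pass:
            rejections[gap_id] = "score_or_length"
        else:
            rejections[gap_id] = "span"

    spans = [g.span_bases for g in placed]
    summary = {
        "n_input_gaps": len(by_gap),
        "n_placed": len(placed),
        "n_rejected": len(rejections),
        "total_span_bases": sum(spans),
        "mean_span_bases": round(sum(spans) / len(spans), 1) if spans else 0.0,
    }
    return placed, rejections, summary


def repeat_composition(
    regions: Sequence[GenomicInterval],
    repeats: Sequence[tuple[GenomicInterval, str]],
) -> tuple[float, dict[str, int]]:
    """Masked fraction and per-class base counts of repeats in regions.

    Overlapping annotations are resolved by union: overall across all
    classes for the masked fraction, per class for the class table, so
    no base is counted twice within a class.
    """
    region_union = merge_intervals(regions, 0)
    total_bases = sum(r.length() for r in region_union)
    if total_bases == 0:
        return 0.0, {}

    def clip(iv: GenomicInterval) -> list[GenomicInterval]:
        out = []
        for r in region_union:
            if r.overlaps(iv):
                out.append(
                    GenomicInterval(r.seq_id, max(r.start, iv.start), min(r.end, iv.end))
                )
        return out

    clipped_all: list[GenomicInterval] = []
    by_class: dict[str, list[GenomicInterval]] = {}
    for iv, cls in repeats:
        pieces = clip(iv)
        clipped_all.extend(pieces)
        by_class.setdefault(cls, []).extend(pieces)

    masked = sum(iv.length() for iv in merge_intervals(clipped_all, 0))
    per_class = {
        cls: sum(iv.length() for iv in merge_intervals(ivs, 0))
        for cls, ivs in sorted(by_class.items())
    }
    return masked / total_bases, per_class


def locate_pericentromere(
    markers: Sequence[MarkerHit],
    genes: Sequence[GeneModel] | None = None,
) -> tuple[list[PericentromereCall], list[str]]:
    """Delimit each chromosome's pericentromere by its flanking markers.

    The region runs from the rightmost left-flank marker to the
    leftmost right-flank marker (marker midpoints are point positions
    here).  Chromosomes whose flanks are inverted are flagged and get
    no call — that signals a misassembly or marker error.
    """
    by_chrom: dict[str, dict[str, list[int]]] = {}
    for m in markers:
        by_chrom.setdefault(m.seq_id, {"left": [], "right": []})[m.side].append(m.position)

    calls: list[PericentromereCall] = []
    flagged: list[str] = []
    for chrom in sorted(by_chrom):
        lefts, rights = by_chrom[chrom]["left"], by_chrom[chrom]["right"]
        if not lefts or not rights:
            flagged.append(chrom)
            continue
        start, end = max(lefts), min(rights)
        if start >= end:
            flagged.append(chrom)
            continue
        region = GenomicInterval(chrom, start, end)
        gene_count = (
            sum(1 for g in genes if g.span.overlaps(region)) if genes else 0
        )
        calls.append(PericentromereCall(chromosome=chrom, region=region, gene_count=gene_count))
    return calls, flagged


def compare_pericentromeres(
    calls_a: Sequence[PericentromereCall], calls_b: Sequence[PericentromereCall]
) -> dict[str, dict]:
    """Per-chromosome size and gene-count fold changes (A over B)."""
    b_by_chrom = {c.chromosome: c for c in calls_b}
    out = {}
    for ca in calls_a:
        cb = b_by_chrom.get(ca.chromosome)
        if cb is None:
            continue
        out[ca.chromosome] = {
            "size_a": ca.size_bases,
            "size_b": cb.size_bases,
            "size_fold": ca.size_bases / cb.size_bases if cb.size_bases else float("inf"),
            "genes_a": ca.gene_count,
            "genes_b": cb.gene_count,
            "gene_fold": ca.gene_count / cb.gene_count if cb.gene_count else float("inf"),
        }
    return out


def call_methylation(
    sites: Sequence[MethylationSite],
    seq_lengths: Mapping[str, int],
    params: MethylationParams | None = None,
) -> tuple[list[MethylationSite], list[WindowDensity]]:
    """Call methylated CpGs and build the windowed density track.

    A site is methylated iff its frequency is strictly above
    ``min_frequency`` and its depth is at least ``min_depth``.  The
    track reports called / assessed CpG per window, where assessed
    means covered by at least one read.
    """
    p = params or MethylationParams()
    for s in sites:
        if s.depth > 0 and not 0 <= s.methylated_frequency <= 1:
            raise InputError(f"frequency outside [0, 1] at {s.seq_id}:{s.position}")
    called = [
        s for s in sites
        if s.depth >= p.min_depth and s.methylated_frequency > p.min_frequency
    ]

    def to_iv(s: MethylationSite) -> GenomicInterval:
        return GenomicInterval(s.seq_id, s.position, s.position + 1)

    assessed = [to_iv(s) for s in sites if s.depth > 0]
    called_ivs = [to_iv(s) for s in called]
    assessed_track = window_density(assessed, seq_lengths, p.window_width)
    called_track = window_density(called_ivs, seq_lengths, p.window_width)
    track = [
        WindowDensity(
            window=a.window,
            count=c.count,
            fraction=(c.count / a.count) if a.count else 0.0,
        )
        for a, c in zip(assessed_track, called_track)
    ]
    return called, track
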