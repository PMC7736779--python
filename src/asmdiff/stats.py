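"""Assembly metrics: contig splitting, N50/L50, anchoring summary.

Contigs are obtained by splitting scaffolds at N-runs (any run of at
least ``min_gap_run`` N characters counts as a gap).  Soft-masked
lowercase bases are ordinary ACGT — masking is annotation, not missing
data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core import InputError, ParameterError

__all__ = ["AssemblyMetrics", "split_contigs", "n50_l50", "anchoring_summary"]


@dataclass
class AssemblyMetrics:
    contig_count: int
    contig_n50: int
    contig_l50: int
    max_contig: int
    cumulative_size: int            # scaffold bases including N
    cumulative_size_acgt: int       # scaffold bases excluding N
    gap_count: int
    anchored_bases: int
    anchored_acgt_bases: int
    anchored_pct: float
    per_chromosome_gap_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not (self.anchored_acgt_bases <= self.anchored_bases <= self.cumulative_size):
            raise InputError("anchoring totals are inconsistent")


def _gap_runs(seq: str, min_gap_run: int) -> list[tuple[int, int]]:
    pattern = re.compile(f"[Nn]{{{min_gap_run},}}")
    return [(m.start(), m.end()) for m in pattern.finditer(seq)]


def split_contigs(
    scaffolds: Mapping[str, str], min_gap_run: int = 1
) -> tuple[dict[str, list[int]], dict[str, int]]:
    """Split each scaffold at N-runs of length >= ``min_gap_run``.

    Returns (per-scaffold contig lengths, per-scaffold gap counts).
    N-runs shorter than the threshold stay inside a contig and count
    toward its length.
    """
    if not scaffolds:
        raise InputError("empty sequence set")
    if min_gap_run < 1:
        raise ParameterError(f"min_gap_run must be >= 1, got {min_gap_run}")
    contig_lengths: dict[str, list[int]] = {}
    gap_counts: dict[str, int] = {}
    for name, seq in scaffolds.items():
        runs = _gap_runs(seq, min_gap_run)
        gap_counts[name] = len(runs)
        lengths, pos = [], 0
        for gs, ge in runs:
            if gs > pos:
                lengths.append(gs - pos)
            pos = ge
        if len(seq) > pos:
            lengths.append(len(seq) - pos)
        contig_lengths[name] = lengths
    return contig_lengths, gap_counts


def n50_l50(lengths: Sequence[int]) -> tuple[int, int]:
    """N50 and L50 of a length list.

    N50 is the length at which the descending cumulative sum first
    reaches half the total; L50 is that contig's 1-based rank.
    """
    if not lengths:
        raise InputError("empty length list")
    if any(x <= 0 for x in lengths):
        raise InputError("lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for rank, x in enumerate(ordered, 1):
        acc += x
        if acc >= half:
            return x, rank
    raise AssertionError("unreachable")


def anchoring_summary(
    scaffolds: Mapping[str, str],
    chromosome_assignment: Mapping[str, str],
    min_gap_run: int = 1,
) -> AssemblyMetrics:
    """Full metric set for an assembly plus its chromosome assignment.

    ``chromosome_assignment`` maps scaffold name -> chromosome name, or
    the literal ``unplaced``.  Anchored bases are the total length of
    chromosome-assigned sequence; the ACGT variant excludes N.
    """
    if not scaffolds:
        raise InputError("empty sequence set")
    unknown = set(chromosome_assignment) - set(scaffolds)
    if unknown:
        raise InputError(f"assignment names unknown scaffolds: {sorted(unknown)}")

    contig_lengths, gap_counts = split_contigs(scaffolds, min_gap_run)
    all_contigs = [x for lens in contig_lengths.values() for x in lens]
    n50, l50 = n50_l50(all_contigs) if all_contigs else (0, 0)

    cumulative = sum(len(s) for s in scaffolds.values())
    n_total = sum(s.upper().count("N") for s in scaffolds.values())
    anchored = anchored_acgt = 0
    per_chrom_gaps: dict[str, int] = {}
    for name, seq in scaffolds.items():
        chrom = chromosome_assignment.get(name, "unplaced")
        if chrom != "unplaced":
            anchored += len(seq)
            anchored_acgt += len(seq) - seq.upper().count("N")
            per_chrom_gaps[chrom] = per_chrom_gaps.get(chrom, 0) + gap_counts[name]

    return AssemblyMetrics(
        contig_count=len(all_contigs),
        contig_n50=n50,
        contig_l50=l50,
        max_contig=max(all_contigs) if all_contigs else 0,
        cumulative_size=cumulative,
        cumulative_size_acgt=cumulative - n_total,
        gap_count=sum(gap_counts.values()),
        anchored_bases=anchored,
        anchored_acgt_bases=anchored_acgt,
        anchored_pct=round(100.0 * anchored / cumulative, 2),
        per_chromosome_gap_counts=dict(sorted(per_chrom_gaps.items())),
    )
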