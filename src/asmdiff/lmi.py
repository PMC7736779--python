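"""Detection of large misassembled inverted (LMI) regions.

A whole-genome alignment between two assemblies of the same genotype
represents a true large inversion as many small inverted blocks
interleaved with alignment noise.  Candidate blocks are first filtered
at 98% identity / 1 kb, then the reference-side intervals of *inverted*
blocks go through a staged merge/filter ladder:

  1. merge blocks separated by <= 100 kb
  2. keep merged intervals  > 100 kb
  3. merge survivors separated by <= 300 kb
  4. keep merged intervals  > 700 kb
  5. merge survivors separated by <= 1 Mb

Size filters are strict; merges are inclusive of the gap bound.  Only
reference-side coordinates drive merging, per sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import AlignmentBlock, GenomicInterval, merge_intervals
from .io import GeneModel
from .params import LmiParams

__all__ = ["LmiRegion", "filter_blocks", "detect_lmi", "annotate_lmi", "lmi_summary"]


@dataclass(frozen=True)
class LmiRegion:
    """One detected misassembled inverted region on the reference."""

    region: GenomicInterval
    supporting_blocks: int
    gene_count: int = 0

    @property
    def span_bases(self) -> int:
        return self.region.length()


def filter_blocks(
    blocks: list[AlignmentBlock], params: LmiParams | None = None
) -> list[AlignmentBlock]:
    """Keep blocks at >= min_identity and reference span >= min length."""
    p = params or LmiParams()
    return [
        b
        for b in blocks
        if b.pct_identity >= p.min_identity and b.ref_aln_length >= p.min_block_length
    ]


def detect_lmi(
    blocks: list[AlignmentBlock], params: LmiParams | None = None
) -> list[LmiRegion]:
    """Run the merge/filter ladder on the inverted blocks.

    ``supporting_blocks`` counts the input inverted blocks overlapping
    each final region by at least one base.
    """
    p = params or LmiParams()
    inverted = [b.ref for b in blocks if b.inverted]
    stage1 = merge_intervals(inverted, p.gap1)
    stage2 = [iv for iv in stage1 if iv.length() > p.min_size1]
    stage3 = merge_intervals(stage2, p.gap2)
    stage4 = [iv for iv in stage3 if iv.length() > p.min_size2]
    stage5 = merge_intervals(stage4, p.gap3)
    return [
        LmiRegion(
            region=region,
            supporting_blocks=sum(1 for iv in inverted if region.overlaps(iv)),
        )
        for region in stage5
    ]


def annotate_lmi(regions: list[LmiRegion], genes: list[GeneModel]) -> list[LmiRegion]:
    """Attach gene counts: genes overlapping a region by >= 1 base."""
    return [
        LmiRegion(
            region=r.region,
            supporting_blocks=r.supporting_blocks,
            gene_count=sum(1 for g in genes if g.span.overlaps(r.region)),
        )
        for r in regions
    ]


def lmi_summary(regions: list[LmiRegion]) -> dict:
    return {
        "n_regions": len(regions),
        "total_span_bases": sum(r.span_bases for r in regions),
        "total_genes": sum(r.gene_count for r in regions),
        "largest_span_bases": max((r.span_bases for r in regions), default=0),
    }
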