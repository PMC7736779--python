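"""Splicing-event calling from long-read exon chains.

An intron retention (IR) is called when a read exon fully contains an
annotated intron; an exon skipping (ES) when a read intron — kept below
3 kb to avoid counting mapping artefacts — fully contains an annotated
internal exon.  Event identity is (gene, feature interval); multiple
supporting reads accumulate onto one event.

Short-read IR calls come from a precomputed per-intron minimum
unspliced-read depth table; the call is simply min_depth >= threshold,
which makes the threshold sweep monotone by construction.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import GenomicInterval, InputError
from .io import ExonChain, GeneModel
from .params import SplicingParams

__all__ = [
    "SpliceEvent",
    "filter_chains",
    "cluster_best",
    "assign_genes",
    "call_intron_retention",
    "call_exon_skipping",
    "shortread_ir",
    "compare_event_sets",
    "splice_site_fraction",
]


@dataclass(frozen=True)
class SpliceEvent:
    kind: str  # "intron_retention" | "exon_skipping"
    gene_id: str
    feature: GenomicInterval
    supporting_reads: frozenset[str]

    def __post_init__(self):
        if self.kind not in ("intron_retention", "exon_skipping"):
            raise InputError(f"bad event kind {self.kind!r}")
        if not self.supporting_reads:
            raise InputError("event without supporting reads")

    @property
    def key(self) -> tuple:
        return (self.kind, self.gene_id, self.feature.seq_id,
                self.feature.start, self.feature.end)


def filter_chains(
    chains: list[ExonChain], params: SplicingParams | None = None, preset: str = "strict"
) -> list[ExonChain]:
    """Retention filter on coverage and identity.

    ``strict`` is the gene-prediction input filter (>= 80% of the read
    aligned at >= 95% identity); ``event`` relaxes identity to the
    event-calling floor (> 90%) with no coverage requirement.
    """
    p = params or SplicingParams()
    if preset == "strict":
        return [
            c for c in chains
            if c.read_coverage_fraction >= p.min_read_coverage
            and c.pct_identity >= p.min_identity
        ]
    if preset == "event":
        return [c for c in chains if c.pct_identity > p.event_min_identity]
    raise InputError(f"unknown preset {preset!r}")


def cluster_best(chains: list[ExonChain]) -> list[ExonChain]:
    """Single-linkage clustering of chains by genomic-span overlap;
    keep one chain per cluster (highest score, ties by longest span
    then read id)."""
    ordered = sorted(chains, key=lambda c: (c.seq_id, c.span.start, c.span.end))
    kept: list[ExonChain] = []
    cluster: list[ExonChain] = []
    cluster_end = None

    def flush():
        if cluster:
            best = min(cluster, key=lambda c: (-c.score, -c.span.length(), c.read_id))
            kept.append(best)

    for c in ordered:
        if cluster and c.seq_id == cluster[-1].seq_id and c.span.start < cluster_end:
            cluster.append(c)
            cluster_end = max(cluster_end, c.span.end)
        else:
            flush()
            cluster = [c]
            cluster_end = c.span.end
    flush()
    return kept


def assign_genes(
    chains: Sequence[ExonChain], genes: Sequence[GeneModel]
) -> dict[str, list[ExonChain]]:
    """Assign each chain to the gene with maximal span overlap.

    Chains overlapping no gene are dropped from event calling.
    """
    by_seq: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_seq.setdefault(g.seq_id, []).append(g)
    max_len: dict[str, int] = {}
    for seq_id, gs in by_seq.items():
        gs.sort(key=lambda g: g.span.start)
        max_len[seq_id] = max(g.span.length() for g in gs)
    starts = {seq_id: [g.span.start for g in gs] for seq_id, gs in by_seq.items()}

    assigned: dict[str, list[ExonChain]] = {}
    for c in chains:
        gs = by_seq.get(c.seq_id)
        if not gs:
            continue
        span = c.span
        lo = bisect.bisect_left(starts[c.seq_id], span.start - max_len[c.seq_id])
        hi = bisect.bisect_right(starts[c.seq_id], span.end)
        best_gene, best_overlap = None, 0
        for g in gs[lo:hi]:
            ov = min(span.end, g.span.end) - max(span.start, g.span.start)
            if ov > best_overlap or (
                ov == best_overlap and ov > 0 and best_gene and g.gene_id < best_gene.gene_id
            ):
                best_gene, best_overlap = g, ov
        if best_gene is not None and best_overlap > 0:
            assigned.setdefault(best_gene.gene_id, []).append(c)
    return assigned


def _collect_events(raw: dict[tuple, set[str]], kind: str) -> list[SpliceEvent]:
    events = [
        SpliceEvent(kind=kind, gene_id=gene_id,
                    feature=GenomicInterval(seq_id, start, end),
                    supporting_reads=frozenset(reads))
        for (gene_id, seq_id, start, end), reads in raw.items()
    ]
    events.sort(key=lambda e: (e.feature.seq_id, e.feature.start, e.gene_id))
    return events


def call_intron_retention(
    chains: Sequence[ExonChain], genes: Sequence[GeneModel]
) -> list[SpliceEvent]:
    """One event per (gene, intron) entirely covered by a read exon."""
    gene_by_id = {g.gene_id: g for g in genes}
    support: dict[tuple, set[str]] = {}
    for gene_id, gene_chains in assign_genes(chains, genes).items():
        introns = gene_by_id[gene_id].introns
        for c in gene_chains:
            for intron in introns:
                if any(exon.contains(intron) for exon in c.exons):
                    key = (gene_id, intron.seq_id, intron.start, intron.end)
                    support.setdefault(key, set()).add(c.read_id)
    return _collect_events(support, "intron_retention")


def call_exon_skipping(
    chains: Sequence[ExonChain],
    genes: Sequence[GeneModel],
    params: SplicingParams | None = None,
) -> list[SpliceEvent]:
    """One event per (gene, internal exon) entirely covered by a read
    intron below the size guard.  Terminal exons are never callable."""
    p = params or SplicingParams()
    gene_by_id = {g.gene_id: g for g in genes}
    support: dict[tuple, set[str]] = {}
    for gene_id, gene_chains in assign_genes(chains, genes).items():
        internal = gene_by_id[gene_id].exons[1:-1]
        if not internal:
            continue
        for c in gene_chains:
            for read_intron in c.introns:
                if (
                    p.es_guard_on == "read_intron"
                    and read_intron.length() >= p.max_read_intron
                ):
                    continue
                for exon in internal:
                    if p.es_guard_on == "exon" and exon.length() >= p.max_read_intron:
                        continue
                    if read_intron.contains(exon):
                        key = (gene_id, exon.seq_id, exon.start, exon.end)
                        support.setdefault(key, set()).add(c.read_id)
    return _collect_events(support, "exon_skipping")


def shortread_ir(
    intron_coverage: Iterable[tuple[str, GenomicInterval, int]],
    depth_threshold: int,
) -> set[tuple]:
    """Call retained introns from precomputed minimum unspliced depth.

    ``intron_coverage`` rows are (gene_id, intron, min_depth); an intron
    is retained iff min_depth >= depth_threshold.  Returns event keys
    compatible with :func:`compare_event_sets`.
    """
    return {
        ("intron_retention", gene_id, intron.seq_id, intron.start, intron.end)
        for gene_id, intron, depth in intron_coverage
        if depth >= depth_threshold
    }


def compare_event_sets(set_a: set, set_b: set) -> dict:
    """Overlap summary between two event-key sets."""
    inter = set_a & set_b
    union = set_a | set_b
    return {
        "n_a": len(set_a),
        "n_b": len(set_b),
        "n_common": len(inter),
        "frac_of_a": len(inter) / len(set_a) if set_a else 0.0,
        "frac_of_b": len(inter) / len(set_b) if set_b else 0.0,
        "jaccard": len(inter) / len(union) if union else 0.0,
    }


def splice_site_fraction(
    chains: Sequence[ExonChain], genome: Mapping[str, str]
) -> float:
    """Fraction of read introns with canonical GT..AG boundaries.

    Strand is resolved by testing both orientations: GT..AG on the
    forward strand or its reverse complement CT..AC.
    """
    total = canonical = 0
    for c in chains:
        seq = genome.get(c.seq_id)
        if seq is None:
            raise InputError(f"sequence {c.seq_id} absent from genome")
        for intron in c.introns:
            if intron.end > len(seq):
                raise InputError(f"intron beyond sequence bounds: {intron}")
            donor = seq[intron.start : intron.start + 2].upper()
            acceptor = seq[intron.end - 2 : intron.end].upper()
            total += 1
            if (donor == "GT" and acceptor == "AG") or (donor == "CT" and acceptor == "AC"):
                canonical += 1
    return canonical / total if total else 0.0
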