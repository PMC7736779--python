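"""Readers and writers for the external formats the pipeline touches.

All readers validate strictly and report the offending line number;
all writers emit deterministic, sorted output.  Coordinates are
converted between the external conventions (1-based inclusive for
show-coords/GFF3, 0-based half-open for BED) and the package-internal
0-based half-open convention at this boundary.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO

from .core import AlignmentBlock, GenomicInterval, InputError

__all__ = [
    "GeneModel",
    "ExonChain",
    "ProteinHit",
    "MethylationSite",
    "GapFlankAlignment",
    "MarkerHit",
    "ParseError",
    "COORDS_COLUMNS",
    "read_alignment_coords",
    "write_alignment_coords",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_bed12_chains",
    "write_bed12_chains",
    "read_hit_table",
    "write_hit_table",
    "read_methylation_tsv",
    "write_methylation_tsv",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_flank_table",
    "write_flank_table",
    "read_marker_tsv",
    "write_marker_tsv",
]


class ParseError(InputError):
    """Malformed input row; message carries file and line number."""


def _derive_introns(exons: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    return [
        GenomicInterval(a.seq_id, a.end, b.start, a.strand)
        for a, b in zip(exons, exons[1:])
        if b.start > a.end
    ]


@dataclass(frozen=True)
class GeneModel:
    """A gene as an exon chain; introns are always derived, never stored."""

    gene_id: str
    seq_id: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self):
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise InputError(f"gene {self.gene_id}: exons overlap or unsorted")

    @property
    def introns(self) -> list[GenomicInterval]:
        return _derive_introns(self.exons)

    @property
    def strand(self) -> str:
        return self.span.strand


@dataclass(frozen=True)
class ExonChain:
    """A spliced read alignment as ordered exon intervals on the genome."""

    read_id: str
    seq_id: str
    exons: tuple[GenomicInterval, ...]
    pct_identity: float = 100.0
    read_coverage_fraction: float = 1.0
    score: float = 0.0

    def __post_init__(self):
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise InputError(f"read {self.read_id}: exons overlap or unsorted")
        if not 0 <= self.pct_identity <= 100:
            raise InputError(f"read {self.read_id}: identity outside [0, 100]")
        if not 0 <= self.read_coverage_fraction <= 1:
            raise InputError(f"read {self.read_id}: coverage outside [0, 1]")

    @property
    def introns(self) -> list[GenomicInterval]:
        return _derive_introns(self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.seq_id, self.exons[0].start, self.exons[-1].end)


@dataclass(frozen=True)
class ProteinHit:
    """One row of a tabular protein-vs-protein alignment.

    Chromosomes are not part of the tabular format; they are resolved by
    an explicit join against the gene annotation (``unplaced:<name>``
    marks scaffold genes, None marks an unresolvable gene)."""

    query_id: str
    target_id: str
    pct_identity: float
    aln_length: int
    e_value: float
    bit_score: float
    query_len: int | None = None
    target_len: int | None = None
    query_seq_id: str | None = None
    target_seq_id: str | None = None

    def __post_init__(self):
        if self.aln_length <= 0:
            raise InputError(f"hit {self.query_id}->{self.target_id}: aln_length <= 0")
        if not 0 <= self.pct_identity <= 100:
            raise InputError(f"hit {self.query_id}->{self.target_id}: identity outside [0, 100]")


@dataclass(frozen=True)
class MethylationSite:
    """One CpG with its supporting-read depth and methylated frequency."""

    seq_id: str
    position: int
    depth: int
    methylated_frequency: float

    def __post_init__(self):
        if self.depth < 0:
            raise InputError(f"site {self.seq_id}:{self.position}: negative depth")
        if self.depth > 0 and not 0 <= self.methylated_frequency <= 1:
            raise InputError(
                f"site {self.seq_id}:{self.position}: frequency outside [0, 1]"
            )


@dataclass(frozen=True)
class GapFlankAlignment:
    """One placement candidate of a gap flank on the reference."""

    gap_id: str
    side: str  # "left" | "right"
    target: GenomicInterval
    score: float
    aligned_length: int

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise InputError(f"gap {self.gap_id}: side must be left/right")
        if self.aligned_length <= 0:
            raise InputError(f"gap {self.gap_id}: aligned_length must be > 0")


@dataclass(frozen=True)
class MarkerHit:
    """A genetically mapped marker placed on an assembly; ``side`` says
    which flank of its chromosome's centromere it belongs to."""

    marker_id: str
    seq_id: str
    position: int
    side: str  # "left" | "right"

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise InputError(f"marker {self.marker_id}: side must be left/right")


# ---------------------------------------------------------------------------
# show-coords dialect

#: Default column order of headerless `show-coords -H -d -r -T` output.
COORDS_COLUMNS = (
    "ref_start", "ref_end", "query_start", "query_end",
    "ref_len", "query_len", "pct_identity",
    "ref_frame", "query_frame", "ref_name", "query_name",
)


def _split_row(line: str, path, lineno: int, n_min: int) -> list[str]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < n_min:
        raise ParseError(f"{path}:{lineno}: expected >= {n_min} columns, got {len(parts)}")
    return parts


def _num(value: str, path, lineno: int, kind=int):
    try:
        return kind(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-numeric field {value!r}") from None


def read_alignment_coords(
    path: str | Path, columns: Sequence[str] = COORDS_COLUMNS
) -> list[AlignmentBlock]:
    """Parse a headerless show-coords-style table into alignment blocks.

    Raw coordinates are 1-based inclusive.  Query rows given with
    start > end mark inverted alignments; the stored query interval is
    normalised to start < end and the block flagged ``inverted``.
    ``columns`` remaps the dialect if a producer emits a different order.
    """
    idx = {name: i for i, name in enumerate(columns)}
    for req in ("ref_start", "ref_end", "query_start", "query_end",
                "pct_identity", "ref_name", "query_name"):
        if req not in idx:
            raise InputError(f"column mapping lacks required field {req!r}")
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = _split_row(line, path, lineno, max(idx.values()) + 1)
            rs = _num(parts[idx["ref_start"]], path, lineno)
            re_ = _num(parts[idx["ref_end"]], path, lineno)
            qs = _num(parts[idx["query_start"]], path, lineno)
            qe = _num(parts[idx["query_end"]], path, lineno)
            ident = _num(parts[idx["pct_identity"]], path, lineno, float)
            if not 0 <= ident <= 100:
                raise ParseError(f"{path}:{lineno}: identity outside [0, 100]: {ident}")
            if re_ < rs:
                raise ParseError(f"{path}:{lineno}: reference end precedes start")
            orientation = "inverted" if qe < qs else "forward"
            if orientation == "inverted":
                qs, qe = qe, qs
            if qs == qe or rs == re_:
                raise ParseError(f"{path}:{lineno}: zero-length alignment span")
            try:
                block = AlignmentBlock(
                    ref=GenomicInterval(parts[idx["ref_name"]], rs - 1, re_),
                    query=GenomicInterval(parts[idx["query_name"]], qs - 1, qe),
                    orientation=orientation,
                    pct_identity=ident,
                )
            except InputError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            blocks.append(block)
    return blocks


def write_alignment_coords(blocks: Iterable[AlignmentBlock], path: str | Path) -> None:
    """Write blocks back to the headerless 1-based dialect (round-trip
    inverse of :func:`read_alignment_coords` with default columns)."""
    rows = []
    for b in blocks:
        qs, qe = b.query.start + 1, b.query.end
        if b.inverted:
            qs, qe = qe, qs
        rows.append((
            b.ref.start + 1, b.ref.end, qs, qe,
            b.ref.length(), b.query.length(), f"{b.pct_identity:.2f}",
            1, -1 if b.inverted else 1, b.ref.seq_id, b.query.seq_id,
        ))
    rows.sort(key=lambda r: (r[9], r[0], r[1]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


# ---------------------------------------------------------------------------
# GFF3

def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Load gene models from GFF3 via gffutils (in-memory database).

    Exons are attached to their gene through the Parent chain and
    ordered by genomic position regardless of strand.  A gene without
    exons is modelled as a single exon covering its span.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        strand = gene.strand if gene.strand in ("+", "-") else "."
        exon_ivs = sorted(
            GenomicInterval(exon.seqid, exon.start - 1, exon.end, strand)
            for exon in db.children(gene, featuretype="exon")
        )
        if not exon_ivs:
            exon_ivs = [GenomicInterval(gene.seqid, gene.start - 1, gene.end, strand)]
        for exon in exon_ivs:
            if exon.seq_id != gene.seqid:
                raise InputError(f"gene {gene.id}: exon on different sequence")
        genes.append(
            GeneModel(
                gene_id=gene.id,
                seq_id=gene.seqid,
                span=GenomicInterval(gene.seqid, gene.start - 1, gene.end, strand),
                exons=tuple(exon_ivs),
            )
        )
    genes.sort(key=lambda g: (g.seq_id, g.span.start, g.gene_id))
    return genes


def write_gff3_genes(genes: Iterable[GeneModel], path: str | Path, source="asmdiff") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.seq_id, g.span.start, g.gene_id)):
            strand = g.strand if g.strand in ("+", "-") else "."
            fh.write(
                f"{g.seq_id}\t{source}\tgene\t{g.span.start + 1}\t{g.span.end}\t.\t{strand}\t.\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.seq_id}\t{source}\tmRNA\t{g.span.start + 1}\t{g.span.end}\t.\t{strand}\t.\tID={mrna};Parent={g.gene_id}\n"
            )
            for i, e in enumerate(g.exons, 1):
                fh.write(
                    f"{g.seq_id}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{strand}\t.\tID={mrna}.exon{i};Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# BED / BED12

def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = _split_row(line, path, lineno, 3)
            start = _num(parts[1], path, lineno)
            end = _num(parts[2], path, lineno)
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start")
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
            out.append(GenomicInterval(parts[0], start, end, strand))
    return out


def read_bed_classified(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """BED with the name column carrying a class label (repeat families)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = _split_row(line, path, lineno, 4)
            start = _num(parts[1], path, lineno)
            end = _num(parts[2], path, lineno)
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start")
            out.append((GenomicInterval(parts[0], start, end), parts[3]))
    return out


def write_bed(
    regions: Iterable[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    regs = list(regions)
    if names is None:
        rows = sorted((r.seq_id, r.start, r.end) for r in regs)
        lines = [f"{c}\t{s}\t{e}\n" for c, s, e in rows]
    else:
        rows = sorted(
            (r.seq_id, r.start, r.end, n) for r, n in zip(regs, names, strict=True)
        )
        lines = [f"{c}\t{s}\t{e}\t{n}\n" for c, s, e, n in rows]
    with open(path, "w") as fh:
        fh.writelines(lines)


def read_bed12_chains(path: str | Path) -> list[ExonChain]:
    """Parse BED12 (optionally extended with identity / read-coverage
    columns 13-14) into exon chains.

    blockStarts are chrom-relative; the first block must start at 0 and
    the last must end at chromEnd, otherwise the row is rejected.
    """
    chains: list[ExonChain] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = _split_row(line, path, lineno, 12)
            chrom = parts[0]
            start = _num(parts[1], path, lineno)
            end = _num(parts[2], path, lineno)
            name = parts[3]
            score = _num(parts[4], path, lineno, float)
            strand = parts[5] if parts[5] in ("+", "-") else "."
            n_blocks = _num(parts[9], path, lineno)
            sizes = [_num(x, path, lineno) for x in parts[10].rstrip(",").split(",")]
            starts = [_num(x, path, lineno) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError(f"{path}:{lineno}: blockCount disagrees with block lists")
            if starts[0] != 0:
                raise ParseError(f"{path}:{lineno}: first blockStart must be 0")
            if start + starts[-1] + sizes[-1] != end:
                raise ParseError(f"{path}:{lineno}: last block does not reach chromEnd")
            exons = tuple(
                GenomicInterval(chrom, start + bs, start + bs + sz, strand)
                for bs, sz in zip(starts, sizes)
            )
            identity = float(parts[12]) if len(parts) > 12 else 100.0
            coverage = float(parts[13]) if len(parts) > 13 else 1.0
            try:
                chains.append(
                    ExonChain(
                        read_id=name, seq_id=chrom, exons=exons,
                        pct_identity=identity, read_coverage_fraction=coverage,
                        score=score,
                    )
                )
            except InputError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return chains


def write_bed12_chains(chains: Iterable[ExonChain], path: str | Path) -> None:
    rows = []
    for c in sorted(chains, key=lambda c: (c.seq_id, c.span.start, c.read_id)):
        start, end = c.span.start, c.span.end
        sizes = ",".join(str(e.length()) for e in c.exons)
        starts = ",".join(str(e.start - start) for e in c.exons)
        strand = c.exons[0].strand if c.exons[0].strand in ("+", "-") else "+"
        rows.append(
            f"{c.seq_id}\t{start}\t{end}\t{c.read_id}\t{c.score:g}\t{strand}\t"
            f"{start}\t{end}\t0\t{len(c.exons)}\t{sizes}\t{starts}\t"
            f"{c.pct_identity:g}\t{c.read_coverage_fraction:g}\n"
        )
    with open(path, "w") as fh:
        fh.writelines(rows)


# ---------------------------------------------------------------------------
# Protein hit tables

def read_hit_table(
    path: str | Path,
    query_chrom: Mapping[str, str] | None = None,
    target_chrom: Mapping[str, str] | None = None,
    query_lengths: Mapping[str, int] | None = None,
    target_lengths: Mapping[str, int] | None = None,
) -> list[ProteinHit]:
    """Parse a 12-column tabular hit file (or the 14-column variant with
    query/target lengths appended) and join chromosomes from annotation
    maps.  Genes missing from a map get seq_id None (quarantined later,
    never silently dropped)."""
    hits: list[ProteinHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = _split_row(line, path, lineno, 12)
            if len(parts) not in (12, 14):
                raise ParseError(f"{path}:{lineno}: expected 12 or 14 columns, got {len(parts)}")
            q, t = parts[0], parts[1]
            ident = _num(parts[2], path, lineno, float)
            if not 0 <= ident <= 100:
                raise ParseError(f"{path}:{lineno}: identity outside [0, 100]")
            alen = _num(parts[3], path, lineno)
            evalue = _num(parts[10], path, lineno, float)
            bits = _num(parts[11], path, lineno, float)
            qlen = _num(parts[12], path, lineno) if len(parts) == 14 else None
            tlen = _num(parts[13], path, lineno) if len(parts) == 14 else None
            if qlen is None and query_lengths is not None:
                qlen = query_lengths.get(q)
            if tlen is None and target_lengths is not None:
                tlen = target_lengths.get(t)
            try:
                hits.append(
                    ProteinHit(
                        query_id=q, target_id=t, pct_identity=ident,
                        aln_length=alen, e_value=evalue, bit_score=bits,
                        query_len=qlen, target_len=tlen,
                        query_seq_id=query_chrom.get(q) if query_chrom else None,
                        target_seq_id=target_chrom.get(t) if target_chrom else None,
                    )
                )
            except InputError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return hits


def write_hit_table(hits: Iterable[ProteinHit], path: str | Path) -> None:
    """Write the 14-column variant (12 standard columns + qlen + slen)."""
    rows = sorted(hits, key=lambda h: (h.query_id, -h.bit_score, h.target_id))
    with open(path, "w") as fh:
        for h in rows:
            fh.write(
                f"{h.query_id}\t{h.target_id}\t{h.pct_identity:g}\t{h.aln_length}\t0\t0\t"
                f"1\t{h.aln_length}\t1\t{h.aln_length}\t{h.e_value:g}\t{h.bit_score:g}\t"
                f"{h.query_len or 0}\t{h.target_len or 0}\n"
            )


# ---------------------------------------------------------------------------
# Methylation / flanks / markers TSVs

def read_methylation_tsv(path: str | Path) -> list[MethylationSite]:
    """TSV with header ``seq_id  position  depth  methylated_frequency``."""
    sites = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["seq_id", "position", "depth", "methylated_frequency"]
        if header != expected:
            raise ParseError(f"{path}:1: expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = _split_row(line, path, lineno, 4)
            try:
                sites.append(
                    MethylationSite(
                        seq_id=parts[0],
                        position=_num(parts[1], path, lineno),
                        depth=_num(parts[2], path, lineno),
                        methylated_frequency=_num(parts[3], path, lineno, float),
                    )
                )
            except InputError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return sites


def write_methylation_tsv(sites: Iterable[MethylationSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tposition\tdepth\tmethylated_frequency\n")
        for s in sorted(sites, key=lambda s: (s.seq_id, s.position)):
            fh.write(f"{s.seq_id}\t{s.position}\t{s.depth}\t{s.methylated_frequency:g}\n")


def read_flank_table(path: str | Path) -> list[GapFlankAlignment]:
    """TSV: gap_id side target_seq target_start target_end score aligned_length."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["gap_id", "side", "target_seq", "target_start", "target_end",
                    "score", "aligned_length"]
        if header != expected:
            raise ParseError(f"{path}:1: expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = _split_row(line, path, lineno, 7)
            start = _num(parts[3], path, lineno)
            end = _num(parts[4], path, lineno)
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start")
            try:
                out.append(
                    GapFlankAlignment(
                        gap_id=parts[0], side=parts[1],
                        target=GenomicInterval(parts[2], start, end),
                        score=_num(parts[5], path, lineno, float),
                        aligned_length=_num(parts[6], path, lineno),
                    )
                )
            except InputError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return out


def write_flank_table(flanks: Iterable[GapFlankAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gap_id\tside\ttarget_seq\ttarget_start\ttarget_end\tscore\taligned_length\n")
        for f in sorted(flanks, key=lambda f: (f.gap_id, f.side, f.target.start)):
            fh.write(
                f"{f.gap_id}\t{f.side}\t{f.target.seq_id}\t{f.target.start}\t"
                f"{f.target.end}\t{f.score:g}\t{f.aligned_length}\n"
            )


def read_marker_tsv(path: str | Path) -> list[MarkerHit]:
    """TSV: marker_id seq_id position side."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["marker_id", "seq_id", "position", "side"]
        if header != expected:
            raise ParseError(f"{path}:1: expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = _split_row(line, path, lineno, 4)
            try:
                out.append(
                    MarkerHit(
                        marker_id=parts[0], seq_id=parts[1],
                        position=_num(parts[2], path, lineno), side=parts[3],
                    )
                )
            except InputError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return out


def write_marker_tsv(markers: Iterable[MarkerHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id\tseq_id\tposition\tside\n")
        for m in sorted(markers, key=lambda m: (m.seq_id, m.position, m.marker_id)):
            fh.write(f"{m.marker_id}\t{m.seq_id}\t{m.position}\t{m.side}\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
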