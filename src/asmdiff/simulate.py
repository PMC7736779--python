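"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of (parameters, seed): the same call
produces byte-identical files, and the planted ground truth is returned
alongside (and serialised next to) the data, so every stage can be
tested by exact recovery with no external download.

Default scales are desk-sized (a few chromosomes of a few megabases,
thousands of genes, a few reads per gene) so the whole suite runs in
minutes; the real inputs these emulate are hundred-megabase-scale
assemblies and millions of reads.  Planting is deterministic
(first-k assignment) so counts are exact; positions and identities are
drawn from the seeded generator.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import AlignmentBlock, GenomicInterval, ParameterError
from .io import (
    ExonChain,
    GapFlankAlignment,
    GeneModel,
    MarkerHit,
    MethylationSite,
    write_alignment_coords,
    write_bed,
    write_bed12_chains,
    write_fasta,
    write_flank_table,
    write_gff3_genes,
    write_hit_table,
    write_marker_tsv,
    write_methylation_tsv,
    ProteinHit,
)

__all__ = [
    "GenomePairSim",
    "ProteomePairSim",
    "TranscriptSim",
    "RegionSim",
    "gen_genome_pair",
    "gen_proteome_pair",
    "gen_transcripts",
    "gen_region_fixtures",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _ALPHABET[rng.integers(0, 4, size=length)]


def _iv_json(iv: GenomicInterval) -> dict:
    return {"seq_id": iv.seq_id, "start": iv.start, "end": iv.end}


# ---------------------------------------------------------------------------
# Genome pair with planted inversions


@dataclass
class GenomePairSim:
    blocks: list[AlignmentBlock]
    genes: list[GeneModel]
    planted_inversions: list[GenomicInterval]
    inversion_block_counts: list[int]
    decoy_blocks: list[AlignmentBlock]
    chrom_lengths: dict[str, int]
    seqs: dict[str, str] | None
    seed: int

    def to_dir(self, out: str | Path) -> None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        write_alignment_coords(self.blocks, out / "alignment_coords.tsv")
        write_gff3_genes(self.genes, out / "genes_ref.gff3")
        write_bed(self.planted_inversions, out / "truth_inversions.bed")
        truth = {
            "seed": self.seed,
            "planted_inversions": [_iv_json(iv) for iv in self.planted_inversions],
            "inversion_block_counts": self.inversion_block_counts,
            "n_decoy_blocks": len(self.decoy_blocks),
            "chrom_lengths": self.chrom_lengths,
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
        if self.seqs is not None:
            write_fasta(self.seqs, out / "reference.fa")


def gen_genome_pair(
    n_chrom: int = 3,
    chrom_len: int = 8_000_000,
    n_inversions: int = 3,
    inversion_size_range: tuple[int, int] = (800_000, 2_000_000),
    block_len_range: tuple[int, int] = (40_000, 90_000),
    block_gap_range: tuple[int, int] = (10_000, 80_000),
    n_decoys: int = 25,
    decoy_size_range: tuple[int, int] = (5_000, 80_000),
    true_identity_range: tuple[float, float] = (98.2, 99.9),
    decoy_identity_range: tuple[float, float] = (90.0, 97.9),
    gene_spacing: int = 10_000,
    gene_length: int = 3_000,
    with_sequence: bool = False,
    seed: int = 0,
) -> GenomePairSim:
    """Pair of related genomes whose alignment carries planted inversions.

    Each planted inversion is emitted as a run of inverted sub-blocks
    with inter-block gaps below the first merge distance, so the
    detection ladder should recover exactly one region per inversion.
    Decoy inverted blocks are small (below the first size filter);
    alternate decoys additionally fall below the identity filter.
    Forward blocks tile the remainder of every chromosome.

    Planted inversions are separated by at least 1.5 Mb (above the last
    merge distance) and decoys keep 110 kb clearance from every other
    inverted interval, so no decoy chain can reach a reportable size.
    """
    rng = np.random.default_rng(seed)
    if inversion_size_range[0] > inversion_size_range[1]:
        raise ParameterError("bad inversion_size_range")
    chroms = [f"chr{i + 1:02d}" for i in range(n_chrom)]
    chrom_lengths = {c: chrom_len for c in chroms}

    # --- place inversions, round-robin over chromosomes, >= 1.5 Mb apart
    margin = 300_000
    min_separation = 1_500_000
    per_chrom_cursor = {c: margin + int(rng.integers(0, 200_000)) for c in chroms}
    inversions: list[GenomicInterval] = []
    for k in range(n_inversions):
        chrom = chroms[k % n_chrom]
        size = int(rng.integers(inversion_size_range[0], inversion_size_range[1] + 1))
        start = per_chrom_cursor[chrom]
        end = start + size
        if end > chrom_len - margin:
            raise ParameterError(
                "inversions do not fit: increase chrom_len or reduce n/size"
            )
        inversions.append(GenomicInterval(chrom, start, end))
        per_chrom_cursor[chrom] = end + min_separation + int(rng.integers(0, 300_000))
    inversions.sort()

    # --- fragment each inversion into inverted sub-blocks
    blocks: list[AlignmentBlock] = []
    block_counts: list[int] = []
    for inv in inversions:
        pos = inv.start
        count = 0
        while pos < inv.end:
            blen = int(rng.integers(block_len_range[0], block_len_range[1] + 1))
            bend = min(pos + blen, inv.end)
            # absorb a remainder too small to hold another gap + block, so
            # the last sub-block always ends exactly at the inversion end
            if inv.end - bend < block_len_range[0] + block_gap_range[1]:
                bend = inv.end
            ref_iv = GenomicInterval(inv.seq_id, pos, bend)
            # reflect within the inversion for the query side
            q_start = inv.start + (inv.end - bend)
            q_end = inv.start + (inv.end - pos)
            blocks.append(
                AlignmentBlock(
                    ref=ref_iv,
                    query=GenomicInterval(inv.seq_id + "_q", q_start, q_end),
                    orientation="inverted",
                    pct_identity=round(float(rng.uniform(*true_identity_range)), 2),
                )
            )
            count += 1
            if bend >= inv.end:
                break
            pos = bend + int(rng.integers(block_gap_range[0], block_gap_range[1] + 1))
            pos = min(pos, inv.end)  # gaps never extend past the inversion
        block_counts.append(count)

    # --- decoy inverted blocks with clearance from all inverted intervals
    clearance = 110_000
    decoys: list[AlignmentBlock] = []
    occupied = list(inversions)
    for j in range(n_decoys):
        size = int(rng.integers(decoy_size_range[0], decoy_size_range[1] + 1))
        for _ in range(10_000):
            chrom = chroms[int(rng.integers(0, n_chrom))]
            start = int(rng.integers(margin, chrom_len - margin - size))
            iv = GenomicInterval(chrom, start, start + size)
            if all(
                o.seq_id != iv.seq_id
                or iv.start - o.end > clearance
                or o.start - iv.end > clearance
                for o in occupied
            ):
                break
        else:
            raise ParameterError("could not place decoys with required clearance")
        occupied.append(iv)
        identity = round(
            float(rng.uniform(*true_identity_range))
            if j % 2 == 0
            else float(rng.uniform(*decoy_identity_range)),
            2,
        )
        decoys.append(
            AlignmentBlock(
                ref=iv,
                query=GenomicInterval(chrom + "_q", iv.start, iv.end),
                orientation="inverted",
                pct_identity=identity,
            )
        )

    # --- forward blocks tile the complement of the inverted intervals
    inverted_by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in chroms}
    for iv in occupied:
        inverted_by_chrom[iv.seq_id].append(iv)
    for chrom in chroms:
        pieces = sorted(inverted_by_chrom[chrom])
        cursor = 0
        bounds = [(p.start, p.end) for p in pieces] + [(chrom_len, chrom_len)]
        for nxt_start, nxt_end in bounds:
            while cursor + 10_000 <= nxt_start:
                blen = int(rng.integers(80_000, 150_000))
                bend = min(cursor + blen, nxt_start)
                blocks.append(
                    AlignmentBlock(
                        ref=GenomicInterval(chrom, cursor, bend),
                        query=GenomicInterval(chrom + "_q", cursor, bend),
                        orientation="forward",
                        pct_identity=round(float(rng.uniform(98.5, 99.9)), 2),
                    )
                )
                cursor = bend + int(rng.integers(0, 5_000))
            cursor = max(cursor, nxt_end)

    blocks = blocks + decoys
    blocks.sort(key=lambda b: (b.ref.seq_id, b.ref.start, b.ref.end))

    # --- uniformly spaced genes on the reference
    genes: list[GeneModel] = []
    for chrom in chroms:
        for gstart in range(gene_spacing, chrom_len - gene_length, gene_spacing):
            gid = f"g_{chrom}_{gstart // gene_spacing:05d}"
            span = GenomicInterval(chrom, gstart, gstart + gene_length, "+")
            genes.append(GeneModel(gene_id=gid, seq_id=chrom, span=span, exons=(span,)))

    seqs = None
    if with_sequence:
        seqs = {
            chrom: _random_seq(rng, chrom_len).tobytes().decode() for chrom in chroms
        }

    return GenomePairSim(
        blocks=blocks,
        genes=genes,
        planted_inversions=inversions,
        inversion_block_counts=block_counts,
        decoy_blocks=decoys,
        chrom_lengths=chrom_lengths,
        seqs=seqs,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Proteome pair with a known ortholog map


@dataclass
class ProteomePairSim:
    hits_ab: list[ProteinHit]
    hits_ba: list[ProteinHit]
    genes_a: list[GeneModel]
    genes_b: list[GeneModel]
    truth: dict[str, dict]          # gene_a -> {"partner": gene_b|None, "cls": str}
    decoy_b_ids: set[str]           # planted partners that must never be accepted
    seed: int

    def planted_orthologs(self) -> dict[str, str]:
        return {
            a: t["partner"]
            for a, t in self.truth.items()
            if t["cls"] in ("both", "m1_only", "m1_enriched", "m2_only")
        }

    def discordant_genes(self) -> set[str]:
        return {a for a, t in self.truth.items() if t["cls"] == "discordant"}

    def to_dir(self, out: str | Path) -> None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        write_hit_table(self.hits_ab, out / "hits_a_vs_b.tsv")
        write_hit_table(self.hits_ba, out / "hits_b_vs_a.tsv")
        write_gff3_genes(self.genes_a, out / "genes_a.gff3")
        write_gff3_genes(self.genes_b, out / "genes_b.gff3")
        (out / "truth.json").write_text(
            json.dumps(
                {"seed": self.seed, "truth": self.truth,
                 "decoy_b_ids": sorted(self.decoy_b_ids)},
                indent=2, sort_keys=True,
            )
        )


def _mk_gene(gid: str, chrom: str, start: int, length: int = 2_000) -> GeneModel:
    span = GenomicInterval(chrom, start, start + length, "+")
    return GeneModel(gene_id=gid, seq_id=chrom, span=span, exons=(span,))


def gen_proteome_pair(
    n_genes: int = 2_000,
    decoy_fraction: float = 0.10,
    frac_m1_only: float = 0.025,
    frac_m1_enriched: float = 0.025,
    frac_m2_only: float = 0.05,
    frac_discordant: float = 0.01,
    chromosome_shuffle_fraction: float = 0.0,
    n_chrom: int = 2,
    gene_spacing: int = 3_000,
    seed: int = 0,
) -> ProteomePairSim:
    """Two gene sets with a known ortholog map plus paralog decoys.

    Deterministic class planting over the gene index:

    * ``discordant``   — M1 anchors on one partner, M2 passes a second;
    * ``m1_only``      — reciprocal best at ~90% identity (below the M2
      identity floor);
    * ``m1_enriched``  — one-directional 85%-identity hit, recoverable
      only through synteny enrichment;
    * ``m2_only``      — the best hit is a cross-chromosome distractor,
      so no anchor forms, but the true partner passes the M2 filters;
    * ``shuffled``     — the B copy sits on another chromosome and must
      be rejected by both same-chromosome tests;
    * ``both``         — everything else: clean reciprocal orthologs.

    Decoy B-genes receive only one-directional low-identity hits
    (< 80%), violating reciprocity, and must never be accepted.
    """
    if not 0 <= decoy_fraction <= 1:
        raise ParameterError("decoy_fraction must be in [0, 1]")
    fr_sum = (frac_m1_only + frac_m1_enriched + frac_m2_only + frac_discordant
              + chromosome_shuffle_fraction)
    if fr_sum > 1:
        raise ParameterError("class fractions exceed 1")
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1:02d}" for i in range(n_chrom)]
    per_chrom = -(-n_genes // n_chrom)

    n_disc = round(frac_discordant * n_genes)
    n_m1 = round(frac_m1_only * n_genes)
    n_m1e = round(frac_m1_enriched * n_genes)
    n_m2 = round(frac_m2_only * n_genes)
    n_shuf = round(chromosome_shuffle_fraction * n_genes)

    # spread special classes evenly through the index (never at chromosome
    # edges) so synteny enrichment always has flanking anchors
    order = (["discordant"] * n_disc + ["m1_only"] * n_m1
             + ["m1_enriched"] * n_m1e + ["m2_only"] * n_m2
             + ["shuffled"] * n_shuf)
    candidates = [i for i in range(n_genes) if i % per_chrom not in (0, per_chrom - 1)]
    if len(order) > len(candidates):
        raise ParameterError("too many special genes for n_genes")
    step = len(candidates) / max(1, len(order))
    specials = {candidates[int(j * step)]: cls for j, cls in enumerate(order)}

    genes_a: list[GeneModel] = []
    genes_b: list[GeneModel] = []
    hits_ab: list[ProteinHit] = []
    hits_ba: list[ProteinHit] = []
    truth: dict[str, dict] = {}
    decoy_b_ids: set[str] = set()

    lengths = rng.integers(300, 600, size=n_genes)
    extra_pos = {c: per_chrom * gene_spacing + 100_000 for c in chroms}

    def add_pair_hits(a, b, ident, alen, bits, qlen, tlen, both_dirs=True, ev=1e-150):
        hits_ab.append(ProteinHit(a, b, ident, alen, ev, bits, qlen, tlen))
        if both_dirs:
            hits_ba.append(ProteinHit(b, a, ident, alen, ev, bits, tlen, qlen))

    for i in range(n_genes):
        chrom = chroms[i // per_chrom]
        pos = (i % per_chrom) * gene_spacing
        a_id, b_id = f"a{i:05d}", f"b{i:05d}"
        plen = int(lengths[i])
        genes_a.append(_mk_gene(a_id, chrom, pos))
        cls = specials.get(i, "both")

        b_chrom = chrom
        if cls == "shuffled":
            b_chrom = chroms[(chroms.index(chrom) + 1) % n_chrom]
        genes_b.append(_mk_gene(b_id, b_chrom, pos if b_chrom == chrom else extra_pos[b_chrom]))
        if b_chrom != chrom:
            extra_pos[b_chrom] += gene_spacing

        if cls in ("both", "shuffled"):
            ident = float(rng.uniform(96.0, 99.5))
            add_pair_hits(a_id, b_id, ident, int(0.9 * plen), 1_000.0, plen, plen)
            truth[a_id] = {"partner": b_id if cls == "both" else None, "cls": cls}
        elif cls == "m1_only":
            ident = float(rng.uniform(88.0, 93.0))
            add_pair_hits(a_id, b_id, ident, int(0.9 * plen), 1_000.0, plen, plen)
            truth[a_id] = {"partner": b_id, "cls": cls}
        elif cls == "m1_enriched":
            # one direction only: no reciprocal best, no M2; synteny must place it
            add_pair_hits(a_id, b_id, 85.0, int(0.9 * plen), 800.0, plen, plen,
                          both_dirs=False, ev=1e-80)
            truth[a_id] = {"partner": b_id, "cls": cls}
        elif cls == "m2_only":
            # cross-chromosome distractor wins the bit-score race
            x_chrom = chroms[(chroms.index(chrom) + 1) % n_chrom]
            x_id = f"x{i:05d}"
            genes_b.append(_mk_gene(x_id, x_chrom, extra_pos[x_chrom]))
            extra_pos[x_chrom] += gene_spacing
            decoy_b_ids.add(x_id)
            add_pair_hits(a_id, x_id, 90.0, int(0.9 * plen), 1_200.0, plen, plen, ev=1e-120)
            ident = float(rng.uniform(95.5, 99.0))
            add_pair_hits(a_id, b_id, ident, int(0.6 * plen), 1_000.0, plen, plen)
            truth[a_id] = {"partner": b_id, "cls": cls}
        elif cls == "discordant":
            # M1 anchors on b (identity below the M2 floor) ...
            add_pair_hits(a_id, b_id, 90.0, int(0.9 * plen), 1_000.0, plen, plen)
            # ... while a same-chromosome second partner passes M2
            d_id = f"d{i:05d}"
            genes_b.append(_mk_gene(d_id, chrom, extra_pos[chrom]))
            extra_pos[chrom] += gene_spacing
            add_pair_hits(a_id, d_id, 96.0, int(0.6 * plen), 700.0, plen, plen, ev=1e-90)
            truth[a_id] = {"partner": None, "cls": cls}

    # paralog decoys: one-directional, low-identity hits onto extra B genes
    n_decoys = round(decoy_fraction * n_genes)
    source_as = rng.integers(0, n_genes, size=n_decoys)
    for j in range(n_decoys):
        p_id = f"p{j:05d}"
        chrom = chroms[j % n_chrom]
        genes_b.append(_mk_gene(p_id, chrom, extra_pos[chrom]))
        extra_pos[chrom] += gene_spacing
        decoy_b_ids.add(p_id)
        i = int(source_as[j])
        plen = int(lengths[i])
        hits_ab.append(
            ProteinHit(f"a{i:05d}", p_id, float(rng.uniform(70.0, 78.0)),
                       int(0.5 * plen), 1e-30, 300.0, plen, plen)
        )

    genes_a.sort(key=lambda g: (g.seq_id, g.span.start))
    genes_b.sort(key=lambda g: (g.seq_id, g.span.start))
    return ProteomePairSim(
        hits_ab=hits_ab, hits_ba=hits_ba, genes_a=genes_a, genes_b=genes_b,
        truth=truth, decoy_b_ids=decoy_b_ids, seed=seed,
    )


# ---------------------------------------------------------------------------
# Transcripts: genome + annotation + long-read exon chains


@dataclass
class TranscriptSim:
    genome: dict[str, str]
    genes: list[GeneModel]
    chains: list[ExonChain]
    intron_coverage: list[tuple[str, GenomicInterval, int]]
    truth_events: list[tuple[str, str, GenomicInterval]]  # (gene, kind, feature)
    canonical_fraction: float
    seed: int

    def to_dir(self, out: str | Path) -> None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, out / "genome.fa")
        write_gff3_genes(self.genes, out / "genes.gff3")
        write_bed12_chains(self.chains, out / "reads.bed12")
        with open(out / "intron_coverage.tsv", "w") as fh:
            fh.write("gene_id\tseq_id\tstart\tend\tmin_depth\n")
            for gid, iv, depth in self.intron_coverage:
                fh.write(f"{gid}\t{iv.seq_id}\t{iv.start}\t{iv.end}\t{depth}\n")
        truth = {
            "seed": self.seed,
            "canonical_fraction": self.canonical_fraction,
            "events": [
                {"gene": g, "kind": k, **_iv_json(iv)} for g, k, iv in self.truth_events
            ],
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))


def gen_transcripts(
    n_genes: int = 500,
    exons_per_gene: int = 5,
    exon_len_range: tuple[int, int] = (150, 300),
    intron_len_range: tuple[int, int] = (300, 800),
    ir_fraction: float = 0.10,
    es_fraction: float = 0.05,
    reads_per_gene: int = 3,
    canonical_fraction: float = 0.95,
    seed: int = 0,
) -> TranscriptSim:
    """Spliced reads generated noise-free from planted isoforms.

    The first ``round(ir_fraction * n_genes)`` genes carry a retained
    middle intron on one extra read; the next ``round(es_fraction *
    n_genes)`` genes carry a skipped middle exon.  Canonical GT..AG
    dinucleotides are written into the genome for the first
    ``round(canonical_fraction * n_introns)`` introns in genome order;
    the rest get a GC donor, which matches neither orientation.
    """
    for name, frac in (("ir_fraction", ir_fraction), ("es_fraction", es_fraction),
                       ("canonical_fraction", canonical_fraction)):
        if not 0 <= frac <= 1:
            raise ParameterError(f"{name} outside [0, 1]")
    if exons_per_gene < 3:
        raise ParameterError("need >= 3 exons per gene for skippable internal exons")
    rng = np.random.default_rng(seed)
    chrom = "chrT1"
    spacer = 500

    genes: list[GeneModel] = []
    cursor = spacer
    all_introns: list[GenomicInterval] = []
    for i in range(n_genes):
        exons = []
        pos = cursor
        for e in range(exons_per_gene):
            elen = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
            exons.append(GenomicInterval(chrom, pos, pos + elen, "+"))
            pos += elen
            if e < exons_per_gene - 1:
                pos += int(rng.integers(intron_len_range[0], intron_len_range[1] + 1))
        gid = f"t{i:05d}"
        span = GenomicInterval(chrom, exons[0].start, exons[-1].end, "+")
        gene = GeneModel(gene_id=gid, seq_id=chrom, span=span, exons=tuple(exons))
        genes.append(gene)
        all_introns.extend(gene.introns)
        cursor = span.end + spacer

    genome_len = cursor + spacer
    seq = _random_seq(rng, genome_len)
    n_canonical = round(canonical_fraction * len(all_introns))
    for j, intron in enumerate(all_introns):
        donor = b"GT" if j < n_canonical else b"GC"
        seq[intron.start : intron.start + 2] = np.frombuffer(donor, dtype=np.uint8)
        seq[intron.end - 2 : intron.end] = np.frombuffer(b"AG", dtype=np.uint8)
    genome = {chrom: seq.tobytes().decode()}

    n_ir = round(ir_fraction * n_genes)
    n_es = round(es_fraction * n_genes)
    chains: list[ExonChain] = []
    truth_events: list[tuple[str, str, GenomicInterval]] = []

    def chain(read_id: str, exons: Sequence[GenomicInterval]) -> ExonChain:
        return ExonChain(
            read_id=read_id, seq_id=chrom, exons=tuple(exons),
            pct_identity=98.0, read_coverage_fraction=1.0, score=100.0,
        )

    for i, gene in enumerate(genes):
        for r in range(reads_per_gene):
            chains.append(chain(f"{gene.gene_id}_r{r}", gene.exons))
        if i < n_ir:
            introns = gene.introns
            k = len(introns) // 2
            retained = introns[k]
            merged = list(gene.exons)
            merged[k : k + 2] = [
                GenomicInterval(chrom, merged[k].start, merged[k + 1].end, "+")
            ]
            chains.append(chain(f"{gene.gene_id}_ir", merged))
            truth_events.append((gene.gene_id, "intron_retention", retained))
        elif i < n_ir + n_es:
            k = 1 + (len(gene.exons) - 2) // 2  # a middle internal exon
            skipped = gene.exons[k]
            kept = [e for j, e in enumerate(gene.exons) if j != k]
            chains.append(chain(f"{gene.gene_id}_es", kept))
            truth_events.append((gene.gene_id, "exon_skipping", skipped))

    intron_coverage = [
        (gene.gene_id, intron, int(rng.integers(0, 16)))
        for gene in genes
        for intron in gene.introns
    ]

    return TranscriptSim(
        genome=genome, genes=genes, chains=chains,
        intron_coverage=intron_coverage, truth_events=truth_events,
        canonical_fraction=canonical_fraction, seed=seed,
    )


# ---------------------------------------------------------------------------
# Region-context fixtures


@dataclass
class RegionSim:
    flanks: list[GapFlankAlignment]
    placeable_truth: dict[str, GenomicInterval]     # gap_id -> expected span
    unplaceable_reasons: dict[str, str]
    repeats: list[tuple[GenomicInterval, str]]
    markers: list[MarkerHit]
    centromere_truth: dict[str, GenomicInterval]
    methylation_sites: list[MethylationSite]
    methylation_truth: dict[tuple[str, int], bool]
    chrom_lengths: dict[str, int]
    seed: int

    def to_dir(self, out: str | Path) -> None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        write_flank_table(self.flanks, out / "gap_flanks.tsv")
        write_marker_tsv(self.markers, out / "centromere_markers.tsv")
        write_methylation_tsv(self.methylation_sites, out / "methylation.tsv")
        write_bed(
            [iv for iv, _ in self.repeats], out / "repeats.bed",
            names=[cls for _, cls in self.repeats],
        )
        truth = {
            "seed": self.seed,
            "placeable": {g: _iv_json(iv) for g, iv in self.placeable_truth.items()},
            "unplaceable_reasons": self.unplaceable_reasons,
            "centromeres": {c: _iv_json(iv) for c, iv in self.centromere_truth.items()},
            "methylation": {
                f"{s}:{p}": v for (s, p), v in self.methylation_truth.items()
            },
            "chrom_lengths": self.chrom_lengths,
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))


def gen_region_fixtures(
    n_gaps: int = 100,
    placeable_fraction: float = 0.5,
    n_chrom: int = 2,
    chrom_len: int = 10_000_000,
    flank_len: int = 20_000,
    n_repeats: int = 60,
    n_sites: int = 2_000,
    methylated_fraction: int | float = 0.4,
    lowdepth_fraction: float = 0.1,
    seed: int = 0,
) -> RegionSim:
    """Flank-alignment, repeat, marker and methylation fixtures.

    The first ``round(placeable_fraction * n_gaps)`` gaps are placeable
    by construction; the rest cycle through the rejection reasons
    (missing side, cross-sequence flanks, failing score/length, span
    over the limit).  Methylation truth is threshold-separated: called
    sites have frequency >= 0.55 at depth >= 4, uncalled sites either
    frequency <= 0.45 or depth <= 3.
    """
    if not 0 <= placeable_fraction <= 1:
        raise ParameterError("placeable_fraction outside [0, 1]")
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1:02d}" for i in range(n_chrom)]
    chrom_lengths = {c: chrom_len for c in chroms}
    aln_len = min(flank_len, 1_500)

    flanks: list[GapFlankAlignment] = []
    placeable: dict[str, GenomicInterval] = {}
    reasons: dict[str, str] = {}
    n_place = round(placeable_fraction * n_gaps)
    reason_cycle = ["missing_side", "cross_sequence", "score_or_length", "span"]
    for g in range(n_gaps):
        gap_id = f"gap{g:04d}"
        chrom = chroms[g % n_chrom]
        pos = int(rng.integers(100_000, chrom_len - 300_000))
        if g < n_place:
            span = int(rng.integers(20_000, 80_000))
            score = float(rng.uniform(4_500, 8_000))
            flanks.append(GapFlankAlignment(gap_id, "left",
                          GenomicInterval(chrom, pos, pos + aln_len), score, aln_len))
            flanks.append(GapFlankAlignment(gap_id, "right",
                          GenomicInterval(chrom, pos + span - aln_len, pos + span),
                          score, aln_len))
            placeable[gap_id] = GenomicInterval(chrom, pos, pos + span)
            continue
        reason = reason_cycle[(g - n_place) % len(reason_cycle)]
        reasons[gap_id] = reason
        if reason == "missing_side":
            flanks.append(GapFlankAlignment(gap_id, "left",
                          GenomicInterval(chrom, pos, pos + aln_len), 6_000.0, aln_len))
        elif reason == "cross_sequence":
            other = chroms[(g + 1) % n_chrom]
            flanks.append(GapFlankAlignment(gap_id, "left",
                          GenomicInterval(chrom, pos, pos + aln_len), 6_000.0, aln_len))
            flanks.append(GapFlankAlignment(gap_id, "right",
                          GenomicInterval(other, pos, pos + aln_len), 6_000.0, aln_len))
        elif reason == "score_or_length":
            flanks.append(GapFlankAlignment(gap_id, "left",
                          GenomicInterval(chrom, pos, pos + aln_len), 3_000.0, aln_len))
            flanks.append(GapFlankAlignment(gap_id, "right",
                          GenomicInterval(chrom, pos + 30_000, pos + 30_000 + aln_len),
                          3_000.0, aln_len))
        else:  # span
            span = int(rng.integers(120_000, 200_000))
            flanks.append(GapFlankAlignment(gap_id, "left",
                          GenomicInterval(chrom, pos, pos + aln_len), 6_000.0, aln_len))
            flanks.append(GapFlankAlignment(gap_id, "right",
                          GenomicInterval(chrom, pos + span - aln_len, pos + span),
                          6_000.0, aln_len))

    classes = ["LTR/Copia", "LTR/Gypsy", "LINE", "satellite", "DNA"]
    repeats = []
    for _ in range(n_repeats):
        chrom = chroms[int(rng.integers(0, n_chrom))]
        start = int(rng.integers(0, chrom_len - 60_000))
        length = int(rng.integers(500, 50_000))
        repeats.append(
            (GenomicInterval(chrom, start, start + length),
             classes[int(rng.integers(0, len(classes)))])
        )

    markers: list[MarkerHit] = []
    centromeres: dict[str, GenomicInterval] = {}
    for chrom in chroms:
        center = chrom_len // 2 + int(rng.integers(-500_000, 500_000))
        left_edge = center - int(rng.integers(500_000, 1_500_000))
        right_edge = center + int(rng.integers(500_000, 1_500_000))
        centromeres[chrom] = GenomicInterval(chrom, left_edge, right_edge)
        for j in range(3):
            markers.append(MarkerHit(f"{chrom}_L{j}", chrom,
                                     left_edge - j * int(rng.integers(10_000, 80_000)),
                                     "left"))
            markers.append(MarkerHit(f"{chrom}_R{j}", chrom,
                                     right_edge + j * int(rng.integers(10_000, 80_000)),
                                     "right"))

    sites: list[MethylationSite] = []
    meth_truth: dict[tuple[str, int], bool] = {}
    n_meth = round(methylated_fraction * n_sites)
    n_low = round(lowdepth_fraction * n_sites)
    per_chrom_sites = -(-n_sites // n_chrom)
    positions = {}
    for c in chroms:
        draw = np.unique(rng.integers(0, chrom_len, size=per_chrom_sites * 2))
        while len(draw) < per_chrom_sites:  # collision top-up, essentially never
            draw = np.unique(
                np.concatenate([draw, rng.integers(0, chrom_len, size=per_chrom_sites)])
            )
        positions[c] = np.sort(rng.permutation(draw)[:per_chrom_sites])
    counters = {c: 0 for c in chroms}
    for s in range(n_sites):
        chrom = chroms[s % n_chrom]
        pos = int(positions[chrom][counters[chrom]])
        counters[chrom] += 1
        if s < n_meth:
            site = MethylationSite(chrom, pos, int(rng.integers(4, 31)),
                                   float(rng.uniform(0.55, 0.99)))
            state = True
        elif s < n_meth + n_low:
            # high frequency but too shallow: must not be called
            site = MethylationSite(chrom, pos, int(rng.integers(0, 4)),
                                   float(rng.uniform(0.55, 0.99)))
            state = False
        else:
            site = MethylationSite(chrom, pos, int(rng.integers(4, 31)),
                                   float(rng.uniform(0.01, 0.45)))
            state = False
        sites.append(site)
        meth_truth[(chrom, pos)] = state

    sites.sort(key=lambda s: (s.seq_id, s.position))
    return RegionSim(
        flanks=flanks, placeable_truth=placeable, unplaceable_reasons=reasons,
        repeats=repeats, markers=markers, centromere_truth=centromeres,
        methylation_sites=sites, methylation_truth=meth_truth,
        chrom_lengths=chrom_lengths, seed=seed,
    )
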