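"""Gene correspondence between two annotation releases.

Two independent methods link each gene of annotation A (the older
release) to a partner in annotation B:

* **M1** — reciprocal best hits on the same chromosome act as anchors;
  the anchored set is then enriched by synteny: an unanchored A-gene
  accepts its best surviving hit (identity > 80%, coverage > 80% of
  query or target) when the partner lies between the partners of the
  nearest flanking anchors in conserved gene order.
* **M2** — reciprocal hits in both directions, each at >= 95% identity
  with an alignment covering >= 50% of the query protein, on the same
  chromosome (unplaced scaffolds admissible).

The methods are combined per A-gene; genes whose two methods disagree
on the partner are discordant and excluded from the final table.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Mapping

from .io import GeneModel, ProteinHit
from .params import CorrespondenceParams

__all__ = [
    "CorrespondencePair",
    "reciprocal_best_hits",
    "m1_correspondence",
    "m2_correspondence",
    "combine_methods",
]


@dataclass(frozen=True)
class CorrespondencePair:
    gene_a: str
    gene_b: str
    method: str = "M1"          # "M1" | "M2" | "both"
    evidence: str = "reciprocal_hit"  # "rbh_anchor" | "synteny_enriched" | "reciprocal_hit"
    status: str = "concordant"  # "concordant" | "a_only_method" | "discordant"


def _hit_rank(h: ProteinHit) -> tuple:
    # best = highest bit score, ties by lower e-value then smallest partner id
    return (-h.bit_score, h.e_value, h.target_id)


def _best_by_query(hits: Iterable[ProteinHit]) -> dict[str, ProteinHit]:
    best: dict[str, ProteinHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best[h.query_id] = h
    return best


def reciprocal_best_hits(
    hits_ab: list[ProteinHit], hits_ba: list[ProteinHit]
) -> list[CorrespondencePair]:
    """Mutual-argmax matching: (a, b) is returned iff b is a's best
    target and a is b's best target.  The result is a partial
    one-to-one matching, sorted by gene_a."""
    best_ab = _best_by_query(hits_ab)
    best_ba = _best_by_query(hits_ba)
    pairs = []
    for a, hit in best_ab.items():
        b = hit.target_id
        back = best_ba.get(b)
        if back is not None and back.target_id == a:
            pairs.append(CorrespondencePair(a, b, method="M1", evidence="rbh_anchor"))
    pairs.sort(key=lambda p: p.gene_a)
    return pairs


def _chrom_ok(chrom_a: str | None, chrom_b: str | None, accept_unplaced: bool) -> bool:
    if chrom_a is None or chrom_b is None:
        return False
    if accept_unplaced and (chrom_a.startswith("unplaced") or chrom_b.startswith("unplaced")):
        return True
    return chrom_a == chrom_b


def _gene_maps(genes: list[GeneModel]) -> tuple[dict[str, str], dict[str, int]]:
    chrom = {g.gene_id: g.seq_id for g in genes}
    pos = {g.gene_id: g.span.start for g in genes}
    return chrom, pos


def _coverage_ok(h: ProteinHit, min_cov: float) -> bool:
    # coverage of query OR target suffices (either denominator)
    covs = []
    if h.query_len:
        covs.append(h.aln_length / h.query_len)
    if h.target_len:
        covs.append(h.aln_length / h.target_len)
    return any(c > min_cov for c in covs)


def m1_correspondence(
    hits_ab: list[ProteinHit],
    hits_ba: list[ProteinHit],
    genes_a: list[GeneModel],
    genes_b: list[GeneModel],
    params: CorrespondenceParams | None = None,
) -> tuple[list[CorrespondencePair], list[str]]:
    """Anchors (same-chromosome RBH) plus synteny enrichment.

    Returns (pairs, quarantined) where quarantined lists A-genes whose
    chromosome could not be resolved.
    """
    p = params or CorrespondenceParams()
    chrom_a, pos_a = _gene_maps(genes_a)
    chrom_b, pos_b = _gene_maps(genes_b)

    quarantined = sorted(
        {h.query_id for h in hits_ab if h.query_id not in chrom_a}
    )

    rbh = reciprocal_best_hits(hits_ab, hits_ba)
    anchors = [
        pr for pr in rbh
        if pr.gene_a in chrom_a and pr.gene_b in chrom_b
        and chrom_a[pr.gene_a] == chrom_b[pr.gene_b]
    ]
    anchored_a = {pr.gene_a for pr in anchors}

    # per A-chromosome anchor chains ordered by A position
    chains: dict[str, list[tuple[int, str]]] = {}
    for pr in anchors:
        chains.setdefault(chrom_a[pr.gene_a], []).append((pos_a[pr.gene_a], pr.gene_b))
    for chain in chains.values():
        chain.sort()

    # best surviving hit per unanchored A-gene
    surviving = [
        h for h in hits_ab
        if h.pct_identity > p.m1_min_identity and _coverage_ok(h, p.m1_min_coverage)
    ]
    best_surviving = _best_by_query(surviving)

    enriched: list[CorrespondencePair] = []
    for a, hit in sorted(best_surviving.items()):
        if a in anchored_a or a not in chrom_a:
            continue
        b = hit.target_id
        if b not in chrom_b:
            continue
        chain = chains.get(chrom_a[a], [])
        if len(chain) < p.min_anchors_per_chrom:
            continue
        positions = [c[0] for c in chain]
        i = bisect.bisect_left(positions, pos_a[a])
        prev_anchor = chain[i - 1] if i > 0 else None
        next_anchor = chain[i] if i < len(chain) else None
        if prev_anchor and next_anchor:
            b_lo, b_hi = sorted((pos_b[prev_anchor[1]], pos_b[next_anchor[1]]))
            same_seq = (
                chrom_b[b] == chrom_b[prev_anchor[1]] == chrom_b[next_anchor[1]]
            )
            if same_seq and b_lo <= pos_b[b] <= b_hi:
                enriched.append(
                    CorrespondencePair(a, b, method="M1", evidence="synteny_enriched")
                )
        else:
            # chromosome end: single nearest anchor plus a distance cap
            anchor = prev_anchor or next_anchor
            if (
                chrom_b[b] == chrom_b[anchor[1]]
                and abs(pos_b[b] - pos_b[anchor[1]]) <= p.end_anchor_max_distance
            ):
                enriched.append(
                    CorrespondencePair(a, b, method="M1", evidence="synteny_enriched")
                )

    pairs = sorted(anchors + enriched, key=lambda pr: pr.gene_a)
    return pairs, quarantined


def m2_correspondence(
    hits_ab: list[ProteinHit],
    hits_ba: list[ProteinHit],
    genes_a: list[GeneModel],
    genes_b: list[GeneModel],
    params: CorrespondenceParams | None = None,
) -> tuple[list[CorrespondencePair], list[str]]:
    """Reciprocal-hit method with identity/length floors.

    A pair survives iff hits exist in both directions, each at
    >= m2_min_identity with aln_length >= m2_min_coverage of its query
    protein, and the genes share a chromosome (unplaced admissible when
    the flag allows).  Several surviving partners for one A-gene are
    resolved by the highest forward bit score.
    """
    p = params or CorrespondenceParams()
    chrom_a, _ = _gene_maps(genes_a)
    chrom_b, _ = _gene_maps(genes_b)
    quarantined = sorted({h.query_id for h in hits_ab if h.query_id not in chrom_a})

    def passes(h: ProteinHit) -> bool:
        if h.pct_identity < p.m2_min_identity:
            return False
        if not h.query_len:
            return False
        return h.aln_length >= p.m2_min_coverage * h.query_len

    fwd = {}
    for h in hits_ab:
        if passes(h):
            key = (h.query_id, h.target_id)
            if key not in fwd or _hit_rank(h) < _hit_rank(fwd[key]):
                fwd[key] = h
    rev_keys = {(h.target_id, h.query_id) for h in hits_ba if passes(h)}

    best_per_a: dict[str, ProteinHit] = {}
    for (a, b), h in fwd.items():
        if (a, b) not in rev_keys:
            continue
        if not _chrom_ok(chrom_a.get(a), chrom_b.get(b), p.m2_accept_unplaced):
            continue
        cur = best_per_a.get(a)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best_per_a[a] = h
    pairs = [
        CorrespondencePair(a, h.target_id, method="M2", evidence="reciprocal_hit")
        for a, h in sorted(best_per_a.items())
    ]
    return pairs, quarantined


def combine_methods(
    m1: list[CorrespondencePair], m2: list[CorrespondencePair]
) -> tuple[list[CorrespondencePair], dict]:
    """Classify each A-gene and drop discordant genes.

    Returns (final pairs, summary).  The summary reports raw counts and
    percentages: genes shared by both methods, method-specific genes,
    discordant genes, and the final table size.
    """
    map1 = {pr.gene_a: pr for pr in m1}
    map2 = {pr.gene_a: pr for pr in m2}
    final: list[CorrespondencePair] = []
    n_both = n_m1_only = n_m2_only = n_disc = 0
    for a in sorted(set(map1) | set(map2)):
        p1, p2 = map1.get(a), map2.get(a)
        if p1 and p2:
            if p1.gene_b == p2.gene_b:
                n_both += 1
                final.append(
                    CorrespondencePair(a, p1.gene_b, method="both",
                                       evidence=p1.evidence, status="concordant")
                )
            else:
                n_disc += 1
        elif p1:
            n_m1_only += 1
            final.append(
                CorrespondencePair(a, p1.gene_b, method="M1",
                                   evidence=p1.evidence, status="a_only_method")
            )
        else:
            n_m2_only += 1
            final.append(
                CorrespondencePair(a, p2.gene_b, method="M2",
                                   evidence=p2.evidence, status="a_only_method")
            )
    n_m1, n_m2 = len(map1), len(map2)
    summary = {
        "n_m1": n_m1,
        "n_m2": n_m2,
        "n_both": n_both,
        "n_m1_only": n_m1_only,
        "n_m2_only": n_m2_only,
        "n_discordant": n_disc,
        "final_size": len(final),
        "pct_shared_of_m1": round(100.0 * n_both / n_m1, 1) if n_m1 else 0.0,
    }
    return final, summary
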