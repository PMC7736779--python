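"""Gene correspondence: RBH matching, M1/M2 filters, method combination."""

import numpy as np
import pytest

from asmdiff.core import GenomicInterval
from asmdiff.correspondence import (
    CorrespondencePair,
    combine_methods,
    m1_correspondence,
    m2_correspondence,
    reciprocal_best_hits,
)
from asmdiff.io import GeneModel, ProteinHit
from asmdiff.params import CorrespondenceParams


def hit(q, t, bits, ident=97.0, alen=400, ev=1e-50, qlen=450, tlen=450):
    return ProteinHit(q, t, ident, alen, ev, bits, qlen, tlen)


def rbh_oracle(hits_ab, hits_ba):
    def best(hits):
        by_q = {}
        for h in hits:
            by_q.setdefault(h.query_id, []).append(h)
        return {
            q: min(hs, key=lambda h: (-h.bit_score, h.e_value, h.target_id)).target_id
            for q, hs in by_q.items()
        }

    fa, fb = best(hits_ab), best(hits_ba)
    return sorted((a, b) for a, b in fa.items() if fb.get(b) == a)


def gene(gid, chrom, pos):
    span = GenomicInterval(chrom, pos, pos + 1_000, "+")
    return GeneModel(gene_id=gid, seq_id=chrom, span=span, exons=(span,))


class TestReciprocalBestHits:
    def test_mutual_argmax(self):
        ab = [hit("a1", "b1", 500), hit("a1", "b2", 300), hit("a2", "b2", 400)]
        ba = [hit("b1", "a1", 500), hit("b2", "a2", 400)]
        pairs = reciprocal_best_hits(ab, ba)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a1", "b1"), ("a2", "b2")]

    def test_one_directional_hit_never_pairs(self):
        assert reciprocal_best_hits([hit("a1", "b1", 500)], []) == []

    def test_matches_bruteforce_oracle_with_ties(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = int(rng.integers(2, 50))
            # coarse scores force frequent ties; ties resolved by e-value, id
            ab = [
                hit(f"a{i}", f"b{j}", float(rng.integers(1, 6)) * 100,
                    ev=float(rng.choice([1e-10, 1e-20, 1e-30])))
                for i in range(n) for j in range(n) if rng.random() < 0.3
            ]
            ba = [
                hit(f"b{j}", f"a{i}", float(rng.integers(1, 6)) * 100,
                    ev=float(rng.choice([1e-10, 1e-20, 1e-30])))
                for i in range(n) for j in range(n) if rng.random() < 0.3
            ]
            got = sorted((p.gene_a, p.gene_b) for p in reciprocal_best_hits(ab, ba))
            assert got == rbh_oracle(ab, ba)

    def test_symmetry_under_role_swap(self, proteome_sim):
        fwd = reciprocal_best_hits(proteome_sim.hits_ab, proteome_sim.hits_ba)
        rev = reciprocal_best_hits(proteome_sim.hits_ba, proteome_sim.hits_ab)
        assert {(p.gene_a, p.gene_b) for p in fwd} == {
            (p.gene_b, p.gene_a) for p in rev
        }


class TestM1:
    def test_identical_proteomes_all_anchored(self):
        genes_a = [gene(f"a{i}", "chr1", i * 2_000) for i in range(10)]
        genes_b = [gene(f"b{i}", "chr1", i * 2_000) for i in range(10)]
        ab = [hit(f"a{i}", f"b{i}", 900, ident=100.0) for i in range(10)]
        ba = [hit(f"b{i}", f"a{i}", 900, ident=100.0) for i in range(10)]
        pairs, quarantined = m1_correspondence(ab, ba, genes_a, genes_b)
        assert len(pairs) == 10
        assert all(p.evidence == "rbh_anchor" for p in pairs)
        assert quarantined == []

    def test_cross_chromosome_rbh_not_anchor(self):
        genes_a = [gene("a1", "chr1", 0)]
        genes_b = [gene("b1", "chr2", 0)]
        pairs, _ = m1_correspondence(
            [hit("a1", "b1", 900)], [hit("b1", "a1", 900)], genes_a, genes_b
        )
        assert pairs == []

    def test_unresolvable_gene_quarantined(self):
        genes_b = [gene("b1", "chr1", 0)]
        _, quarantined = m1_correspondence(
            [hit("ghost", "b1", 900)], [], [], genes_b
        )
        assert quarantined == ["ghost"]

    def test_synteny_enrichment_recovers_non_rbh_gene(self, proteome_sim):
        pairs, _ = m1_correspondence(
            proteome_sim.hits_ab, proteome_sim.hits_ba,
            proteome_sim.genes_a, proteome_sim.genes_b,
        )
        enriched = {p.gene_a for p in pairs if p.evidence == "synteny_enriched"}
        planted = {a for a, t in proteome_sim.truth.items() if t["cls"] == "m1_enriched"}
        assert enriched == planted


class TestM2:
    def _genes(self):
        return [gene("a1", "chr1", 0)], [gene("b1", "chr1", 0)]

    def test_reciprocal_pair_kept(self):
        ga, gb = self._genes()
        pairs, _ = m2_correspondence(
            [hit("a1", "b1", 800, ident=96.0, alen=270)],
            [hit("b1", "a1", 800, ident=96.0, alen=270)],
            ga, gb,
        )
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a1", "b1")]

    def test_low_identity_one_direction_drops_pair(self):
        ga, gb = self._genes()
        pairs, _ = m2_correspondence(
            [hit("a1", "b1", 800, ident=96.0)],
            [hit("b1", "a1", 800, ident=94.0)],
            ga, gb,
        )
        assert pairs == []

    def test_different_chromosomes_dropped(self):
        ga = [gene("a1", "chr1", 0)]
        gb = [gene("b1", "chr2", 0)]
        pairs, _ = m2_correspondence(
            [hit("a1", "b1", 800, ident=96.0)],
            [hit("b1", "a1", 800, ident=96.0)],
            ga, gb,
        )
        assert pairs == []

    def test_threshold_monotonicity(self, proteome_sim):
        base = CorrespondenceParams()
        strict = CorrespondenceParams(m2_min_identity=97.0, m2_min_coverage=0.7)
        loose_pairs, _ = m2_correspondence(
            proteome_sim.hits_ab, proteome_sim.hits_ba,
            proteome_sim.genes_a, proteome_sim.genes_b, base,
        )
        strict_pairs, _ = m2_correspondence(
            proteome_sim.hits_ab, proteome_sim.hits_ba,
            proteome_sim.genes_a, proteome_sim.genes_b, strict,
        )
        assert {(p.gene_a, p.gene_b) for p in strict_pairs} <= {
            (p.gene_a, p.gene_b) for p in loose_pairs
        }


class TestCombineMethods:
    def test_agreement_is_both(self):
        final, summary = combine_methods(
            [CorrespondencePair("a", "b1")], [CorrespondencePair("a", "b1", method="M2")]
        )
        assert len(final) == 1 and final[0].method == "both"
        assert summary["n_both"] == 1 and summary["n_discordant"] == 0

    def test_disagreement_is_discordant_and_excluded(self):
        final, summary = combine_methods(
            [CorrespondencePair("a", "b1")], [CorrespondencePair("a", "b2", method="M2")]
        )
        assert final == [] and summary["n_discordant"] == 1

    def test_identical_proteomes_fully_shared(self):
        genes_a = [gene(f"a{i}", "chr1", i * 2_000) for i in range(10)]
        genes_b = [gene(f"b{i}", "chr1", i * 2_000) for i in range(10)]
        ab = [hit(f"a{i}", f"b{i}", 900, ident=100.0) for i in range(10)]
        ba = [hit(f"b{i}", f"a{i}", 900, ident=100.0) for i in range(10)]
        m1, _ = m1_correspondence(ab, ba, genes_a, genes_b)
        m2, _ = m2_correspondence(ab, ba, genes_a, genes_b)
        _, summary = combine_methods(m1, m2)
        assert summary["pct_shared_of_m1"] == 100.0

    def test_planted_discordant_genes_exactly_flagged(self, proteome_sim):
        m1, _ = m1_correspondence(
            proteome_sim.hits_ab, proteome_sim.hits_ba,
            proteome_sim.genes_a, proteome_sim.genes_b,
        )
        m2, _ = m2_correspondence(
            proteome_sim.hits_ab, proteome_sim.hits_ba,
            proteome_sim.genes_a, proteome_sim.genes_b,
        )
        final, summary = combine_methods(m1, m2)
        final_genes = {p.gene_a for p in final}
        assert proteome_sim.discordant_genes().isdisjoint(final_genes)
        assert summary["n_discordant"] == len(proteome_sim.discordant_genes())
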