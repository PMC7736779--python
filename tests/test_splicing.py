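"""Splicing-event calling, chain filtering/clustering, splice sites."""

import numpy as np
import pytest

from asmdiff.core import GenomicInterval
from asmdiff.io import ExonChain, GeneModel
from asmdiff.params import SplicingParams
from asmdiff.simulate import gen_transcripts
from asmdiff.splicing import (
    call_exon_skipping,
    call_intron_retention,
    cluster_best,
    compare_event_sets,
    filter_chains,
    shortread_ir,
    splice_site_fraction,
)


def chain(read_id, exons, seq="c", identity=98.0, coverage=1.0, score=0.0):
    return ExonChain(
        read_id=read_id, seq_id=seq,
        exons=tuple(GenomicInterval(seq, s, e) for s, e in exons),
        pct_identity=identity, read_coverage_fraction=coverage, score=score,
    )


def gene(gid, exons, seq="c"):
    ivs = tuple(GenomicInterval(seq, s, e, "+") for s, e in exons)
    span = GenomicInterval(seq, ivs[0].start, ivs[-1].end, "+")
    return GeneModel(gene_id=gid, seq_id=seq, span=span, exons=ivs)


class TestFilterChains:
    def test_low_coverage_dropped(self):
        assert filter_chains([chain("r", [(0, 100)], coverage=0.79, identity=99)]) == []

    def test_boundary_kept(self):
        c = chain("r", [(0, 100)], coverage=1.0, identity=95.0)
        assert filter_chains([c]) == [c]

    def test_matches_predicate_scan(self):
        rng = np.random.default_rng(13)
        chains = [
            chain(f"r{i}", [(0, 100)], coverage=float(rng.uniform(0.5, 1.0)),
                  identity=float(rng.uniform(85, 100)))
            for i in range(200)
        ]
        p = SplicingParams()
        expected = [
            c for c in chains
            if c.read_coverage_fraction >= p.min_read_coverage
            and c.pct_identity >= p.min_identity
        ]
        assert filter_chains(chains, p) == expected
        relaxed = [c for c in chains if c.pct_identity > p.event_min_identity]
        assert filter_chains(chains, p, preset="event") == relaxed


class TestClusterBest:
    def test_overlapping_pair_keeps_higher_score(self):
        a = chain("a", [(0, 100)], score=10)
        b = chain("b", [(50, 150)], score=20)
        assert cluster_best([a, b]) == [b]

    def test_disjoint_chains_all_retained(self):
        a = chain("a", [(0, 100)])
        b = chain("b", [(200, 300)])
        assert cluster_best([a, b]) == [a, b]

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(29)
        for _ in range(30):
            chains = []
            for i in range(int(rng.integers(2, 60))):
                s = int(rng.integers(0, 50_000))
                chains.append(chain(f"r{i}", [(s, s + int(rng.integers(100, 5_000)))],
                                    score=float(rng.integers(0, 100))))
            # brute-force single-linkage components by span overlap
            n = len(chains)
            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for i in range(n):
                for j in range(i + 1, n):
                    if chains[i].span.overlaps(chains[j].span):
                        parent[find(i)] = find(j)
            comps = {}
            for i, c in enumerate(chains):
                comps.setdefault(find(i), []).append(c)
            expected = sorted(
                (min(comp, key=lambda c: (-c.score, -c.span.length(), c.read_id)).read_id
                 for comp in comps.values())
            )
            assert sorted(c.read_id for c in cluster_best(chains)) == expected


class TestIntronRetention:
    def test_read_exon_covering_intron_calls_event(self):
        g = gene("g1", [(500, 1000), (1500, 2000)])
        (event,) = call_intron_retention([chain("r", [(900, 1600)])], [g])
        assert event.feature == GenomicInterval("c", 1000, 1500)
        assert event.supporting_reads == frozenset({"r"})

    def test_partial_cover_no_event(self):
        g = gene("g1", [(500, 1000), (1500, 2000)])
        assert call_intron_retention([chain("r", [(1100, 1600)])], [g]) == []

    def test_duplicate_reads_idempotent(self):
        g = gene("g1", [(500, 1000), (1500, 2000)])
        chains = [chain("r", [(900, 1600)]), chain("r", [(900, 1600)]),
                  chain("r2", [(900, 1600)])]
        (event,) = call_intron_retention(chains, [g])
        assert event.supporting_reads == frozenset({"r", "r2"})
        reversed_events = call_intron_retention(chains[::-1], [g])
        assert reversed_events == [event]


class TestExonSkipping:
    def test_read_intron_covering_internal_exon(self):
        g = gene("g1", [(500, 1000), (1500, 1600), (2900, 3200)])
        # read intron 1000..2900 (1.9 kb) fully contains the middle exon
        (event,) = call_exon_skipping([chain("r", [(600, 1000), (2900, 3100)])], [g])
        assert event.feature == GenomicInterval("c", 1500, 1600)

    def test_size_guard_blocks_large_read_intron(self):
        g = gene("g1", [(500, 1000), (1500, 1600), (4300, 4500)])
        # read intron 1000..4300 = 3300 >= 3000: guarded
        assert call_exon_skipping([chain("r", [(600, 1000), (4300, 4400)])], [g]) == []

    def test_terminal_exons_never_called(self):
        g = gene("g1", [(500, 600), (1000, 1100)])  # no internal exons
        assert call_exon_skipping([chain("r", [(400, 450), (1200, 1300)])], [g]) == []


class TestShortReadIr:
    def _table(self):
        iv = lambda s: GenomicInterval("c", s, s + 100)
        return [("g1", iv(0), 10), ("g2", iv(500), 9), ("g3", iv(1000), 5)]

    def test_threshold_inclusive(self):
        called = shortread_ir(self._table(), 10)
        assert {k[1] for k in called} == {"g1"}

    def test_below_threshold_not_called(self):
        assert {k[1] for k in shortread_ir(self._table(), 10)} == {"g1"}
        assert {k[1] for k in shortread_ir(self._table(), 9)} == {"g1", "g2"}

    def test_sweep_monotone_on_random_tables(self):
        rng = np.random.default_rng(37)
        table = [
            (f"g{i}", GenomicInterval("c", i * 200, i * 200 + 100), int(rng.integers(0, 20)))
            for i in range(300)
        ]
        previous = set()
        for threshold in (15, 10, 8, 5, 1):
            called = shortread_ir(table, threshold)
            assert previous <= called
            previous = called


class TestCompareEventSets:
    def test_identical_and_disjoint(self):
        assert compare_event_sets({1, 2}, {1, 2})["frac_of_a"] == 1.0
        assert compare_event_sets({1}, {2})["jaccard"] == 0.0

    def test_hand_count(self):
        summary = compare_event_sets({"x", "y"}, {"y", "z"})
        assert summary["frac_of_a"] == 0.5
        assert summary["jaccard"] == pytest.approx(1 / 3)


class TestSpliceSiteFraction:
    def test_canonical_and_noncanonical(self):
        genome = {"c": "A" * 100 + "GT" + "A" * 50 + "AG" + "A" * 100}
        canonical = chain("r", [(50, 100), (154, 200)])
        assert splice_site_fraction([canonical], genome) == 1.0
        genome_gc = {"c": "A" * 100 + "GC" + "A" * 50 + "AG" + "A" * 100}
        assert splice_site_fraction([canonical], genome_gc) == 0.0

    def test_minus_strand_orientation_recognised(self):
        # CT..AC on the forward strand is GT..AG on the reverse complement
        genome = {"c": "A" * 100 + "CT" + "A" * 50 + "AC" + "A" * 100}
        assert splice_site_fraction([chain("r", [(50, 100), (154, 200)])], genome) == 1.0

    def test_planted_fraction_exact(self):
        sim = gen_transcripts(n_genes=250, ir_fraction=0, es_fraction=0,
                              canonical_fraction=0.9, seed=2)
        assert splice_site_fraction(sim.chains, sim.genome) == pytest.approx(0.9)


class TestPlantedEventRecovery:
    def test_exact_precision_recall(self, transcript_sim):
        ir = call_intron_retention(transcript_sim.chains, transcript_sim.genes)
        es = call_exon_skipping(transcript_sim.chains, transcript_sim.genes)
        got = {(e.gene_id, e.kind, e.feature.start, e.feature.end) for e in ir + es}
        truth = {
            (g, k, f.start, f.end) for g, k, f in transcript_sim.truth_events
        }
        assert got == truth
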