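"""Canonical k-mer counting, allelic pairing, and greedy primary selection."""

import itertools

import networkx as nx
import numpy as np
import pytest
from Bio.Seq import Seq

from sexdepth.io import Contig
from sexdepth.redundancy import (
    build_kmer_index,
    canonical,
    find_allelic_pairs,
    iter_kmers,
    purge,
    select_primary,
)
from sexdepth.simulate import SimulationConfig, generate_genome


def random_contig(rng, cid, length):
    return Contig(cid, "".join(rng.choice(list("ACGT"), size=length)))


class TestCanonicalCounting:
    def test_canonical_is_min_of_strands(self):
        assert canonical("ACG") == "ACG"
        assert canonical("CGT") == "ACG"  # rc(CGT) = ACG

    def test_acgt_k3_counts_both_orientations(self):
        # "ACGT" k=3: ACG and CGT both canonicalize to ACG -> count 2
        index = build_kmer_index([Contig("c1", "ACG" + "T" + "A" * 20)], k=11)
        # use a direct small check through iter_kmers instead for k=3 semantics
        assert list(iter_kmers("ACGT", 3)) == ["ACG", "ACG"]

    def test_too_short_contig_yields_empty_index(self):
        index = build_kmer_index([Contig("c1", "ACGTACGT")], k=21)
        assert index.counts == {}

    def test_n_windows_skipped(self):
        # k-mers never span an N; blocks shorter than k contribute nothing
        assert list(iter_kmers("ACNGT", 3)) == []
        assert list(iter_kmers("ACGNACG", 3)) == ["ACG", "ACG"]

    def test_identical_twins_give_duo_kmers(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=100))
        index = build_kmer_index([Contig("a", seq), Contig("b", seq)], k=21)
        classes = {index.classify(km) for km in index.counts}
        assert classes == {"duo"}

    @pytest.mark.parametrize("k", [12, 20])
    def test_even_k_rejected(self, k):
        with pytest.raises(ValueError, match="odd"):
            build_kmer_index([Contig("c", "A" * 50)], k=k)

    @pytest.mark.parametrize("k", [9, 33])
    def test_k_out_of_range_rejected(self, k):
        with pytest.raises(ValueError):
            build_kmer_index([Contig("c", "A" * 50)], k=k)

    def test_counts_match_strand_enumeration_oracle(self, rng):
        """Counts agree with a brute-force oracle that canonicalizes every
        substring via Bio.Seq reverse complement, on strings <= 100 bp."""
        for k in (11, 13):
            for _ in range(20):
                seqs = [
                    "".join(rng.choice(list("ACGTN"), size=int(rng.integers(k, 100)),
                                       p=[0.24, 0.24, 0.24, 0.24, 0.04]))
                    for _ in range(3)
                ]
                contigs = [Contig(f"c{i}", s) for i, s in enumerate(seqs)]
                oracle: dict[str, int] = {}
                for s in seqs:
                    for i in range(len(s) - k + 1):
                        sub = s[i : i + k]
                        if "N" in sub:
                            continue
                        rc = str(Seq(sub).reverse_complement())
                        km = min(sub, rc)
                        oracle[km] = oracle.get(km, 0) + 1
                index = build_kmer_index(contigs, k=k)
                assert index.counts == oracle

    def test_classification_invariant_under_contig_order(self, rng):
        contigs = [random_contig(rng, f"c{i}", 200) for i in range(4)]
        a = build_kmer_index(contigs, k=21)
        b = build_kmer_index(contigs[::-1], k=21)
        assert a.counts == b.counts
        assert a.duo_by_contig == b.duo_by_contig


class TestFindAllelicPairs:
    def test_identical_twins_paired_with_s_one(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        contigs = [Contig("a", seq), Contig("b", seq)]
        graph = find_allelic_pairs(build_kmer_index(contigs), contigs)
        assert graph.has_edge("a", "b")
        assert graph.edges["a", "b"]["s"] == pytest.approx(1.0)

    def test_unrelated_contigs_unpaired(self, rng):
        contigs = [random_contig(rng, "a", 50_000), random_contig(rng, "b", 50_000)]
        index = build_kmer_index(contigs)
        graph = find_allelic_pairs(index, contigs, threshold=0.05)
        assert graph.number_of_edges() == 0

    def test_mutated_partial_duplicate_detected(self, rng):
        # 1% substitutions over 90% of the length: ~0.99^21 of k-mers survive
        # identically and stay duo, so s approaches 1 and clears t=0.6
        seq = "".join(rng.choice(list("ACGT"), size=50_000))
        dup = list(seq[:45_000])
        for i in np.flatnonzero(rng.random(45_000) < 0.01):
            dup[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[dup[i]]
        contigs = [Contig("a", seq), Contig("a_alt", "".join(dup))]
        graph = find_allelic_pairs(build_kmer_index(contigs), contigs, threshold=0.6)
        assert graph.has_edge("a", "a_alt")

    def test_repeat_kmers_never_link(self, rng):
        # the same sequence in 3 contigs -> all its k-mers have count 3
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        contigs = [Contig(c, seq) for c in "abc"]
        graph = find_allelic_pairs(build_kmer_index(contigs), contigs, threshold=0.01)
        assert graph.number_of_edges() == 0


def reference_select(graph, lengths):
    """Independent brute-force recursion of the stated greedy rule."""

    def recurse(remaining):
        if not remaining:
            return set(), set()
        keep = min(remaining, key=lambda cid: (-lengths[cid], cid))
        neighbors = set(graph.neighbors(keep)) & remaining
        primary, purged = recurse(remaining - {keep} - neighbors)
        return primary | {keep}, purged | neighbors

    primary, purged = set(), set()
    for comp in nx.connected_components(graph):
        p, q = recurse(set(comp))
        primary |= p
        purged |= q
    return primary, purged


class TestSelectPrimary:
    def _contigs(self, lengths):
        return [Contig(cid, "A" * n) for cid, n in lengths.items()]

    def _graph(self, lengths, edges):
        g = nx.Graph()
        g.add_nodes_from(lengths)
        g.add_edges_from(edges)
        return g

    def test_pair_keeps_longer(self):
        lengths = {"a": 100_000, "b": 90_000}
        primary, purged = select_primary(
            self._graph(lengths, [("a", "b")]), self._contigs(lengths)
        )
        assert primary == {"a"} and purged == {"b"}

    def test_no_edges_everything_primary(self):
        lengths = {"a": 10, "b": 20}
        primary, purged = select_primary(self._graph(lengths, []), self._contigs(lengths))
        assert primary == {"a", "b"} and purged == set()

    def test_chain_keeps_central_longest(self):
        lengths = {"a": 90_000, "b": 100_000, "c": 95_000}
        primary, purged = select_primary(
            self._graph(lengths, [("a", "b"), ("b", "c")]), self._contigs(lengths)
        )
        assert primary == {"b"} and purged == {"a", "c"}

    def test_tie_broken_by_lexicographic_id(self):
        lengths = {"b": 50, "a": 50}
        primary, purged = select_primary(
            self._graph(lengths, [("a", "b")]), self._contigs(lengths)
        )
        assert primary == {"a"} and purged == {"b"}

    def test_matches_reference_on_all_small_graphs(self):
        """Exhaustive: every graph on <= 5 nodes, two length assignments."""
        for n in range(1, 6):
            nodes = [f"n{i}" for i in range(n)]
            possible_edges = list(itertools.combinations(nodes, 2))
            for mask in range(2 ** len(possible_edges)):
                edges = [e for j, e in enumerate(possible_edges) if mask >> j & 1]
                for lengths in (
                    {nd: 10 * (i + 1) for i, nd in enumerate(nodes)},
                    {nd: 50 for nd in nodes},  # all ties
                ):
                    g = self._graph(lengths, edges)
                    contigs = self._contigs(lengths)
                    assert select_primary(g, contigs) == reference_select(g, lengths)

    def test_matches_reference_on_random_graphs(self, rng):
        for n in (6, 7, 8):
            for _ in range(50):
                nodes = [f"n{i}" for i in range(n)]
                lengths = {nd: int(rng.integers(1, 100)) for nd in nodes}
                edges = [
                    e
                    for e in itertools.combinations(nodes, 2)
                    if rng.random() < 0.35
                ]
                g = self._graph(lengths, edges)
                contigs = self._contigs(lengths)
                assert select_primary(g, contigs) == reference_select(g, lengths)


class TestPurgeEndToEnd:
    CFG = SimulationConfig(
        n_autosomes=8,
        n_x_contigs=1,
        n_y_contigs=1,
        contig_length_range=(20_000, 40_000),
        gc_segment_length=10_000,
        window_size=10_000,
        duplicate_fraction=0.2,
        seed=42,
    )

    def test_duplicates_purged_primaries_kept(self):
        genome = generate_genome(self.CFG)
        primary, purged, pairs = purge(genome.contigs)
        purged_ids = {c.id for c in purged}
        dup_ids = {d for _s, d in genome.allelic_pairs}
        assert purged_ids == dup_ids
        true_bp = sum(c.length for c in genome.contigs if c.id not in dup_ids)
        primary_bp = sum(c.length for c in primary)
        assert abs(primary_bp - true_bp) <= 0.02 * true_bp

    def test_purge_is_idempotent(self):
        genome = generate_genome(self.CFG)
        primary, _, _ = purge(genome.contigs)
        primary2, purged2, _ = purge(primary)
        assert purged2 == []
        assert [c.id for c in primary2] == [c.id for c in primary]

    def test_primary_and_purged_partition_input(self):
        genome = generate_genome(self.CFG)
        primary, purged, _ = purge(genome.contigs)
        assert len(primary) + len(purged) == len(genome.contigs)
        assert {c.id for c in primary} | {c.id for c in purged} == set(genome.lengths)

    def test_duplicate_free_input_untouched(self, rng):
        contigs = [random_contig(rng, f"c{i}", 5000) for i in range(4)]
        primary, purged, pairs = purge(contigs)
        assert purged == [] and len(primary) == 4
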