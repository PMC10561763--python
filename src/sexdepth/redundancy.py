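"""Allelic-contig purging via shared low-copy k-mers.

A heterozygous diploid assembly represents many loci twice, once per
haplotype. Such allelic contig pairs share the k-mers of their common locus,
and because each of those k-mers occurs exactly twice assembly-wide ("duo"
k-mers) they can be told apart from repeats without read data. We index
canonical k-mers, classify them by assembly-wide count (unique = 1, duo = 2,
repeat >= 3), score contig pairs by the fraction of the shorter contig's duo
k-mers shared with the other, and within each connected component of the
resulting graph greedily keep the longest contig — the length criterion — and
purge its neighbors.

The duo classification from assembly-internal counts stands in for a
read-based k-mer depth spectrum, which would require the raw reads; the
"non-repeat" restriction (count <= 2) is what keeps repeat-mediated k-mer
sharing from linking unrelated contigs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import networkx as nx
import pandas as pd

from .io import Contig

__all__ = [
    "KmerIndex",
    "canonical",
    "iter_kmers",
    "build_kmer_index",
    "find_allelic_pairs",
    "select_primary",
    "purge",
]

DEFAULT_K = 21
DEFAULT_PAIR_THRESHOLD = 0.6
#: A pair score is only meaningful when the shorter contig has at least this
#: many duo k-mers; genuine haplotigs share thousands, chance collisions 1-2.
DEFAULT_MIN_DUO = 20

_RC = str.maketrans("ACGT", "TGCA")


def canonical(kmer: str) -> str:
    """Lexicographic min of a k-mer and its reverse complement."""
    rc = kmer.translate(_RC)[::-1]
    return kmer if kmer <= rc else rc


def iter_kmers(sequence: str, k: int) -> Iterator[str]:
    """Canonical k-mers of every ACGT-only length-k substring, in order.

    Windows containing N are skipped by splitting on N runs.
    """
    for block in sequence.split("N"):
        if len(block) < k:
            continue
        for i in range(len(block) - k + 1):
            yield canonical(block[i : i + k])


@dataclass
class KmerIndex:
    """Canonical k-mer counts and the per-contig sets of duo k-mers.

    ``counts`` maps canonical k-mer to its total occurrence count across the
    assembly (both strands collapse onto the canonical form). ``duo_by_contig``
    holds, per contig, the distinct duo k-mers (assembly-wide count exactly 2)
    it contains.
    """

    k: int
    counts: dict[str, int]
    duo_by_contig: dict[str, frozenset[str]] = field(default_factory=dict)

    def classify(self, kmer: str) -> str:
        c = self.counts.get(canonical(kmer), 0)
        if c == 0:
            return "absent"
        if c == 1:
            return "unique"
        if c == 2:
            return "duo"
        return "repeat"


def build_kmer_index(contigs: Sequence[Contig], k: int = DEFAULT_K) -> KmerIndex:
    """Count canonical k-mers over the assembly and collect duo sets per contig."""
    if k % 2 == 0:
        raise ValueError(f"k must be odd (palindrome ambiguity), got {k}")
    if not (11 <= k <= 31):
        raise ValueError(f"k must be in [11, 31], got {k}")
    counts: dict[str, int] = {}
    distinct: dict[str, set[str]] = {}
    for contig in contigs:
        seen = distinct.setdefault(contig.id, set())
        for km in iter_kmers(contig.sequence, k):
            counts[km] = counts.get(km, 0) + 1
            seen.add(km)
    duo_by_contig = {
        cid: frozenset(km for km in kms if counts[km] == 2)
        for cid, kms in distinct.items()
    }
    return KmerIndex(k=k, counts=counts, duo_by_contig=duo_by_contig)


def find_allelic_pairs(
    index: KmerIndex,
    contigs: Sequence[Contig],
    threshold: float = DEFAULT_PAIR_THRESHOLD,
    min_duo: int = DEFAULT_MIN_DUO,
) -> nx.Graph:
    """Graph of contigs with edges where the shared-duo-k-mer score passes.

    The score of a pair is ``s(a, b) = |duo(a) ∩ duo(b)| / |duo(shorter)|``:
    the denominator is the *shorter* contig's duo set, so a haplotig fully
    contained in a longer primary scores near 1. Repeat k-mers never enter.
    Edges carry the score as attribute ``s``. Pairs whose shorter contig has
    fewer than ``min_duo`` duo k-mers are never linked: with so little
    support the score cannot be told apart from a chance k-mer collision.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    lengths = {c.id: c.length for c in contigs}
    graph = nx.Graph()
    graph.add_nodes_from((c.id, {"length": c.length}) for c in contigs)

    shared: dict[tuple[str, str], int] = {}
    owners: dict[str, str] = {}
    for cid, kms in index.duo_by_contig.items():
        for km in kms:
            if km in owners and owners[km] != cid:
                pair = tuple(sorted((owners[km], cid)))
                shared[pair] = shared.get(pair, 0) + 1
            else:
                owners[km] = cid

    for (a, b), n_shared in shared.items():
        shorter = a if lengths[a] <= lengths[b] else b
        denom = len(index.duo_by_contig.get(shorter, ()))
        if denom < min_duo:
            continue  # too little duo support to distinguish from chance
        s = n_shared / denom
        if s >= threshold:
            graph.add_edge(a, b, s=s)
    return graph


def select_primary(
    graph: nx.Graph, contigs: Sequence[Contig]
) -> tuple[set[str], set[str]]:
    """Greedy longest-first selection within each allelic component.

    Repeatedly keep the longest remaining contig of a component (ties broken
    by lexicographically smaller id), purge its neighbors, and recurse on
    what is left. Unconnected contigs are always primary. Returns
    ``(primary_ids, purged_ids)``, a partition of the contig set.
    """
    lengths = {c.id: c.length for c in contigs}
    primary: set[str] = set()
    purged: set[str] = set()
    for comp in nx.connected_components(graph):
        remaining = set(comp)
        while remaining:
            keep = min(remaining, key=lambda cid: (-lengths[cid], cid))
            primary.add(keep)
            remaining.discard(keep)
            neighbors = set(graph.neighbors(keep)) & remaining
            purged |= neighbors
            remaining -= neighbors
    primary |= {c.id for c in contigs} - primary - purged
    return primary, purged


def purge(
    contigs: Sequence[Contig],
    k: int = DEFAULT_K,
    threshold: float = DEFAULT_PAIR_THRESHOLD,
    min_duo: int = DEFAULT_MIN_DUO,
) -> tuple[list[Contig], list[Contig], pd.DataFrame]:
    """End-to-end redundancy reduction.

    Returns ``(primary, purged, pairs)`` where ``pairs`` is a table of scored
    contig pairs (a, b, s, decision) with decision "purge_b"/"purge_a"/"kept"
    describing what happened to each paired contig.
    """
    index = build_kmer_index(contigs, k)
    graph = find_allelic_pairs(index, contigs, threshold, min_duo)
    primary_ids, purged_ids = select_primary(graph, contigs)
    rows = []
    for a, b, data in graph.edges(data=True):
        if b in purged_ids and a in primary_ids:
            decision = "purge_b"
        elif a in purged_ids and b in primary_ids:
            decision = "purge_a"
        else:
            decision = "kept"
        rows.append((a, b, data["s"], decision))
    pairs = pd.DataFrame(rows, columns=["a", "b", "s", "decision"])
    primary = [c for c in contigs if c.id in primary_ids]
    purged = [c for c in contigs if c.id in purged_ids]
    return primary, purged, pairs
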