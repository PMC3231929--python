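"""Independent oracles and fixture builders shared across tests."""

from __future__ import annotations

import math

import dendropy
import numpy as np

from fgdpipe.pairwise import Hit, HitTable


def brute_force_local_score(a: str, b: str, scheme) -> int:
    """Exhaustive-gap-length local alignment score (independent oracle).

    D[i][j] is the best score of an alignment ending with a[i] paired
    to b[j]; gap contributions are maximised by scanning every gap
    length explicitly (O(nm(n+m))), a different recurrence from the
    production aligner's affine three-state DP.
    """
    ea, eb = scheme.encode(a), scheme.encode(b)
    m, n = len(ea), len(eb)
    sub = scheme.matrix
    open_, ext = scheme.gap_open, scheme.gap_extend
    D = [[-(10**9)] * n for _ in range(m)]
    best = 0
    for i in range(m):
        for j in range(n):
            s = int(sub[ea[i], eb[j]])
            cand = s  # start a fresh alignment
            if i > 0 and j > 0:
                cand = max(cand, s + D[i - 1][j - 1])
                for k in range(1, i):  # gap consuming a[i-k..i-1]
                    cand = max(cand, s + D[i - 1 - k][j - 1] - open_ - k * ext)
                for k in range(1, j):  # gap consuming b[j-k..j-1]
                    cand = max(cand, s + D[i - 1][j - 1 - k] - open_ - k * ext)
            D[i][j] = cand
            best = max(best, cand)
    return best


def exhaustive_upgma_trees(ids: list[str], d: np.ndarray) -> set[frozenset]:
    """All UPGMA trees reachable by any closest-pair tie choice.

    Cluster-cluster distances are recomputed as plain means over leaf
    pairs from the original matrix (the textbook definition), rather
    than by the production code's incremental weighted update.  Trees
    are encoded as frozensets of (leafset, height) pairs.
    """
    index = {g: i for i, g in enumerate(ids)}

    def dist(c1: frozenset, c2: frozenset) -> float:
        return float(
            np.mean([d[index[a], index[b]] for a in c1 for b in c2])
        )

    results: set[frozenset] = set()

    def recurse(clusters: list[frozenset], nodes: dict[frozenset, float]) -> None:
        if len(clusters) == 1:
            results.add(frozenset(nodes.items()))
            return
        pairs = [
            (dist(clusters[i], clusters[j]), i, j)
            for i in range(len(clusters))
            for j in range(i + 1, len(clusters))
        ]
        dmin = min(p[0] for p in pairs)
        for dd, i, j in pairs:
            if dd > dmin + 1e-12:
                continue
            merged = clusters[i] | clusters[j]
            rest = [c for k, c in enumerate(clusters) if k not in (i, j)]
            nn = dict(nodes)
            nn[merged] = dd / 2.0
            recurse(rest + [merged], nn)

    recurse([frozenset([g]) for g in ids], {frozenset([g]): 0.0 for g in ids})
    return results


def dendrogram_signature(tree) -> frozenset:
    """(leafset, height) encoding matching exhaustive_upgma_trees."""
    out = {}

    def walk(node):
        leaves = frozenset(node.leaves())
        out[leaves] = node.height
        for c in node.children:
            walk(c)

    walk(tree)
    return frozenset(out.items())


def random_ultrametric(
    ids: list[str], rng: np.random.Generator, max_height: float = 0.5
):
    """Random ultrametric tree; returns (Dendrogram, distance ndarray)."""
    from fgdpipe.fgd import Dendrogram

    def build(labels: list[str], height: float) -> Dendrogram:
        if len(labels) == 1:
            return Dendrogram(labels[0], 0.0)
        k = int(rng.integers(1, len(labels)))
        left, right = labels[:k], labels[k:]
        h = float(height)
        child_h = lambda n: 0.0 if n == 1 else float(rng.uniform(0.1 * h, 0.9 * h))
        node = Dendrogram(
            None, h, [build(left, child_h(len(left))), build(right, child_h(len(right)))]
        )
        return node

    labels = list(ids)
    rng.shuffle(labels)
    tree = build(labels, max_height)
    coph = tree.cophenetic()
    n = len(ids)
    d = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                key = (a, b) if a < b else (b, a)
                d[i, j] = d[j, i] = coph[key]
    return tree, d


def rf_distance(newick_a: str, newick_b: str) -> int:
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(ta, tb))


def toy_table(
    orfeomes: dict[str, list[tuple[str, int]]],
    bit_hits: list[tuple[str, str, float, float]],
    self_bits: dict[str, float] | None = None,
) -> HitTable:
    """Hand-built HitTable: ORFs given as (tag, length), hits as
    (query_tag, subject_tag, bit_score, evalue)."""
    seqs = {g: [(t, "A" * n) for t, n in o] for g, o in orfeomes.items()}
    tag_genome = {t: g for g, o in seqs.items() for t, _ in o}
    table = HitTable(
        genome_ids=sorted(seqs),
        orfeomes=seqs,
        tag_genome=tag_genome,
        self_bits=self_bits or {t: 100.0 for t in tag_genome},
    )
    for q, s, bits, ev in bit_hits:
        qg, sg = tag_genome[q], tag_genome[s]
        table.hits.setdefault((qg, sg), []).append(
            Hit(q, s, int(bits), bits, ev, 100.0, 1, 1, 1, 1, 1)
        )
    for pair in table.hits.values():
        pair.sort(key=lambda h: (-h.bit_score, h.query_id, h.subject_id))
    return table


def protein_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)
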