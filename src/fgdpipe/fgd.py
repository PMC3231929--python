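"""Functional genome distribution: ORFeome distance matrix and UPGMA tree.

Genomes are compared through their pooled ORFeomes: each ORF's affinity
to a target genome is its best cross-genome bit score normalised by its
self-alignment bit score (a quantity in [0, 1] combining similarity
level and quality), and the genome-genome distance is one minus the
mean affinity averaged over both directions.  The resulting symmetric
matrix, in distance units (du), is clustered with UPGMA into an
ultrametric dendrogram.

The exact affinity formula used by the original FGD software is
unpublished; the self-normalised bidirectional best-hit ratio used here
is this package's own definition (symmetric, bounded, zero for
identical ORFeomes, one for unrelated ones) and is swappable via the
``affinity`` argument of :func:`build_matrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .pairwise import HitTable

DEFAULT_E_CEILING = 1e-5


class MatrixError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    genome_ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.genome_ids)
        if self.d.shape != (n, n):
            raise MatrixError("matrix shape does not match genome list")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise MatrixError("matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise MatrixError("diagonal must be zero")
        if np.any(self.d < 0) or np.any(self.d > 1 + 1e-12):
            raise MatrixError("entries must lie in [0, 1]")

    def value(self, a: str, b: str) -> float:
        i, j = self.genome_ids.index(a), self.genome_ids.index(b)
        return float(self.d[i, j])

    def to_phylip(self, path: str | Path) -> None:
        """PHYLIP square (lower + upper) distance matrix."""
        with Path(path).open("w") as fh:
            fh.write(f"{len(self.genome_ids)}\n")
            for name, row in zip(self.genome_ids, self.d):
                fh.write(name[:50].ljust(12))
                fh.write(" ".join(f"{v:.6f}" for v in row))
                fh.write("\n")

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("genome_a\tgenome_b\tdistance_du\n")
            for i, a in enumerate(self.genome_ids):
                for j, b in enumerate(self.genome_ids):
                    if i < j:
                        fh.write(f"{a}\t{b}\t{self.d[i, j]:.6f}\n")


def orf_affinity(
    orf: str, target: str, table: HitTable, e_ceiling: float = DEFAULT_E_CEILING
) -> float:
    """Self-normalised best-hit bit ratio of one ORF against a genome."""
    self_bit = table.self_bits.get(orf)
    if self_bit is None:
        raise MatrixError(f"no self bit score for {orf!r}; table malformed")
    qg = table.tag_genome[orf]
    if qg == target:
        return 1.0
    best = 0.0
    for h in table.hits.get((qg, target), ()):
        if h.query_id == orf and h.evalue <= e_ceiling and h.bit_score > best:
            best = h.bit_score
    return min(max(best / self_bit, 0.0), 1.0)


def _mean_affinity(
    A: str, B: str, table: HitTable, e_ceiling: float,
    affinity: Callable[[str, str, HitTable, float], float],
) -> float:
    tags = table.tags(A)
    if not tags:
        raise MatrixError(f"genome {A} has an empty ORFeome")
    return float(np.mean([affinity(t, B, table, e_ceiling) for t in tags]))


def genome_distance(
    A: str,
    B: str,
    table: HitTable,
    e_ceiling: float = DEFAULT_E_CEILING,
    affinity: Callable[[str, str, HitTable, float], float] = orf_affinity,
) -> float:
    """1 - mean bidirectional ORF affinity, in distance units."""
    for g in (A, B):
        if g not in table.orfeomes:
            raise MatrixError(f"genome {g} not in table")
    if A == B:
        return 0.0
    ab = _mean_affinity(A, B, table, e_ceiling, affinity)
    ba = _mean_affinity(B, A, table, e_ceiling, affinity)
    return 1.0 - (ab + ba) / 2.0


def build_matrix(
    table: HitTable,
    e_ceiling: float = DEFAULT_E_CEILING,
    affinity: Callable[[str, str, HitTable, float], float] = orf_affinity,
) -> DistanceMatrix:
    ids = list(table.genome_ids)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = genome_distance(ids[i], ids[j], table, e_ceiling, affinity)
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class Dendrogram:
    """Rooted ultrametric tree; leaves carry genome ids."""

    label: str | None
    height: float
    children: list["Dendrogram"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            assert self.label is not None
            return [self.label]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, decimals: int = 6) -> str:
        def fmt(node: "Dendrogram", parent_height: float) -> str:
            bl = round(parent_height - node.height, decimals)
            if node.is_leaf:
                return f"{node.label}:{bl:.{decimals}f}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{bl:.{decimals}f}"

        if self.is_leaf:
            return f"{self.label};"
        inner = ",".join(fmt(c, self.height) for c in self.children)
        return f"({inner});"

    def cophenetic(self) -> dict[tuple[str, str], float]:
        """Leaf-pair distances implied by the tree (2x merge height)."""
        out: dict[tuple[str, str], float] = {}

        def walk(node: "Dendrogram") -> list[str]:
            if node.is_leaf:
                return node.leaves()
            sub = [walk(c) for c in node.children]
            for i in range(len(sub)):
                for j in range(i + 1, len(sub)):
                    for a in sub[i]:
                        for b in sub[j]:
                            key = (a, b) if a < b else (b, a)
                            out[key] = 2.0 * node.height
            return [x for s in sub for x in s]

        walk(self)
        return out


def upgma(m: DistanceMatrix) -> Dendrogram:
    """Unweighted pair-group clustering with arithmetic-mean updates.

    Cluster distances are member-count-weighted arithmetic means (the
    classical UPGMA update), merge height is half the merged distance,
    and among equidistant candidate pairs the lexicographically smallest
    pair (by sorted leaf label sets) is merged, so output is
    byte-reproducible.
    """
    n = len(m.genome_ids)
    if n == 0:
        raise MatrixError("empty matrix")
    nodes: list[Dendrogram] = [Dendrogram(g, 0.0) for g in m.genome_ids]
    sizes = [1] * n
    keys = [tuple(sorted(node.leaves())) for node in nodes]
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(m.d[i, j])
    active = list(range(n))
    next_id = n
    store: dict[int, Dendrogram] = {i: nodes[i] for i in range(n)}
    size_of = {i: 1 for i in range(n)}
    key_of = {i: keys[i] for i in range(n)}

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                d = get(i, j)
                pair_key = tuple(sorted((key_of[i], key_of[j])))
                cand = (d, pair_key, i, j)
                if best is None or cand < best:
                    best = cand
        assert best is not None
        d, _, i, j = best
        new = Dendrogram(None, d / 2.0, [store[i], store[j]])
        si, sj = size_of[i], size_of[j]
        for k in active:
            if k in (i, j):
                continue
            dk = (si * get(i, k) + sj * get(j, k)) / (si + sj)
            dist[(k, next_id) if k < next_id else (next_id, k)] = dk
        active = [k for k in active if k not in (i, j)] + [next_id]
        store[next_id] = new
        size_of[next_id] = si + sj
        key_of[next_id] = tuple(sorted(key_of[i] + key_of[j]))
        next_id += 1
    root = store[active[0]]
    return root
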