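"""Core / shared / specific gene-set mining from the all-vs-all table.

Presence of a reference ORF in another genome is judged one-directionally:
it is *present* in genome G when its best hit into G has E-value at or
below ``e_present``, and *absent* when no hit into G reaches
``e_absent``.  A single qualifying hit suffices (paralogous families are
not collapsed).  A reciprocal-best-hit refinement is available but off
by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .pairwise import HitTable


class GeneSetError(ValueError):
    pass


@dataclass
class GeneSetResult:
    reference_genome: str
    members: list[str]
    #: locus_tag -> {genome_id -> best E-value (inf when no recorded hit)}
    evidence: dict[str, dict[str, float]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def to_tsv(self, path: str | Path, genomes: list[str] | None = None) -> None:
        with Path(path).open("w") as fh:
            gs = genomes or sorted({g for ev in self.evidence.values() for g in ev})
            fh.write("locus_tag\t" + "\t".join(gs) + "\n")
            for tag in self.members:
                ev = self.evidence.get(tag, {})
                vals = "\t".join(
                    "NA" if math.isinf(ev.get(g, math.inf)) else f"{ev[g]:.3e}"
                    for g in gs
                )
                fh.write(f"{tag}\t{vals}\n")


def _check_genomes(table: HitTable, genomes) -> None:
    missing = [g for g in genomes if g not in table.orfeomes]
    if missing:
        raise GeneSetError(f"genomes not in table: {missing}")


def _is_rbh(table: HitTable, tag: str, genome: str, e_cutoff: float) -> bool:
    hits = table.best_hits(tag, genome)
    if not hits:
        return False
    best = hits[0]
    back = table.best_hits(best.subject_id, table.tag_genome[tag])
    return bool(back) and back[0].subject_id == tag and back[0].evalue <= e_cutoff


def core_genes(
    table: HitTable,
    genomes: set[str] | list[str],
    e_present: float,
    reference: str | None = None,
    reciprocal: bool = False,
) -> GeneSetResult:
    """Reference ORFs with a qualifying hit in every other genome."""
    genomes = sorted(genomes)
    _check_genomes(table, genomes)
    ref = reference or genomes[0]
    if ref not in genomes:
        raise GeneSetError(f"reference {ref} not in genome set")
    others = [g for g in genomes if g != ref]
    members: list[str] = []
    evidence: dict[str, dict[str, float]] = {}
    for tag in table.tags(ref):
        ev = {g: table.best_evalue(tag, g) for g in others}
        ok = all(ev[g] <= e_present for g in others)
        if ok and reciprocal:
            ok = all(_is_rbh(table, tag, g, e_present) for g in others)
        if ok:
            members.append(tag)
            evidence[tag] = ev
    return GeneSetResult(ref, members, evidence)


def shared_fraction(
    table: HitTable,
    A_group: set[str] | list[str],
    B_group: set[str] | list[str],
    e_cutoff: float,
    reference: str | None = None,
) -> float:
    """Percent of A-side reference ORFs with a hit in >= 1 B-group genome."""
    A_group, B_group = sorted(A_group), sorted(B_group)
    if not A_group or not B_group:
        raise GeneSetError("groups must be nonempty")
    _check_genomes(table, A_group + B_group)
    ref = reference or A_group[0]
    tags = table.tags(ref)
    if not tags:
        raise GeneSetError(f"reference {ref} has an empty ORFeome")
    n_shared = sum(
        1
        for tag in tags
        if any(table.best_evalue(tag, g) <= e_cutoff for g in B_group)
    )
    return 100.0 * n_shared / len(tags)


def group_specific(
    table: HitTable,
    in_group: set[str] | list[str],
    out_group: set[str] | list[str],
    e_present: float,
    e_absent: float,
    reference: str | None = None,
) -> GeneSetResult:
    """ORFs conserved across ``in_group`` with no hit into ``out_group``.

    With an empty out-group this reduces to :func:`core_genes`.
    """
    in_group, out_group = sorted(in_group), sorted(out_group)
    if not in_group:
        raise GeneSetError("in_group must be nonempty")
    if set(in_group) & set(out_group):
        raise GeneSetError("in_group and out_group overlap")
    if e_present > e_absent:
        raise GeneSetError("require e_present <= e_absent")
    _check_genomes(table, in_group + out_group)
    ref = reference or in_group[0]
    members: list[str] = []
    evidence: dict[str, dict[str, float]] = {}
    others_in = [g for g in in_group if g != ref]
    for tag in table.tags(ref):
        ev = {g: table.best_evalue(tag, g) for g in others_in + out_group}
        if all(ev[g] <= e_present for g in others_in) and all(
            ev[g] > e_absent for g in out_group
        ):
            members.append(tag)
            evidence[tag] = ev
    return GeneSetResult(ref, members, evidence)


def strain_specific(
    table: HitTable,
    genome: str,
    others: set[str] | list[str],
    e_absent: float,
) -> GeneSetResult:
    """ORFs of ``genome`` with no qualifying hit in any other genome."""
    return group_specific(table, [genome], others, e_present=e_absent,
                          e_absent=e_absent, reference=genome)
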