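"""Synthetic pangenomes with known truth.

A set of bacterial genomes is evolved along a user-supplied tree
(branch lengths in expected substitutions per site): a shared core-gene
backbone, clade- and strain-specific gene families, strain-specific
islands optionally flanked by transposase genes, pseudogenised genes,
and conserved rRNA/tRNA loci.  Protein divergence uses a site-wise
Poisson model (substitution probability 1 - exp(-t), replacements drawn
from a BLOSUM62-derived conditional distribution); codons follow their
amino acid so that nucleotide identity tracks protein identity.  The
generator is byte-reproducible for a fixed seed and returns the full
bookkeeping (family membership, island coordinates, pseudogene list)
needed to score every downstream pipeline stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import yaml

from .genome_io import Feature, GenomeRecord, rotate_genome, write_fasta
from .pairwise import PROTEIN_ALPHABET, _B62_ARR

AA20 = "ARNDCQEGHILKMFPSTWYV"

#: BLOSUM62 background amino-acid frequencies (Henikoff)
AA_FREQS = np.array(
    [0.074, 0.052, 0.045, 0.054, 0.025, 0.034, 0.054, 0.074, 0.026, 0.068,
     0.099, 0.058, 0.025, 0.047, 0.039, 0.057, 0.051, 0.013, 0.032, 0.073]
)
AA_FREQS = AA_FREQS / AA_FREQS.sum()


def _conditional_matrix() -> np.ndarray:
    """P(replacement b | current a), b != a, from BLOSUM62 target freqs.

    BLOSUM62 scores are half-bit log-odds, so the implied pair frequency
    is q_ab ~ p_a p_b 2**(S_ab / 2); conditioning on a and excluding the
    diagonal gives a replacement distribution biased toward accepted
    substitutions.
    """
    idx = [PROTEIN_ALPHABET.index(a) for a in AA20]
    S = _B62_ARR[np.ix_(idx, idx)].astype(float)
    q = AA_FREQS[None, :] * np.power(2.0, S / 2.0)
    np.fill_diagonal(q, 0.0)
    return q / q.sum(axis=1, keepdims=True)


_COND = _conditional_matrix()
_AA_INDEX = {a: i for i, a in enumerate(AA20)}

# NCBI translation table 11, sense codons only; TAA used for stops
_CODONS: dict[str, list[str]] = {}
for _c in (
    a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"
):
    from Bio.Seq import Seq as _Seq

    _aa = str(_Seq(_c).translate(table=11))
    if _aa != "*":
        _CODONS.setdefault(_aa, []).append(_c)

_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# configuration and truth containers


@dataclass
class IslandSpec:
    n_genes: int
    flank_with_transposase: bool = True


@dataclass
class SimConfig:
    """Pangenome simulation parameters.

    ``clade_specific`` keys are comma-joined leaf-name sets ("A,B,C");
    a family is born at the clade's ancestor and present in exactly
    those genomes.  Branch lengths are expected substitutions per site.
    """

    tree: str
    n_core_families: int = 40
    clade_specific: dict[str, int] = field(default_factory=dict)
    strain_specific: dict[str, int] = field(default_factory=dict)
    islands: dict[str, list[IslandSpec]] = field(default_factory=dict)
    gene_len_mean: float = 200.0  # codons
    gene_len_sd: float = 60.0
    gene_len_min: int = 50
    intergenic_len_mean: float = 120.0  # bp
    intergenic_len_sd: float = 40.0
    intergenic_len_min: int = 20
    pseudo_frac: float = 0.0
    n_rrna_operons: int = 0
    n_trnas: int = 0
    circular: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.pseudo_frac <= 1:
            raise ValueError("pseudo_frac must lie in [0, 1]")
        if self.n_core_families < 0:
            raise ValueError("counts must be non-negative")
        def coerce(i) -> IslandSpec:
            if isinstance(i, IslandSpec):
                return i
            if isinstance(i, dict):
                return IslandSpec(**i)
            return IslandSpec(*i)

        self.islands = {
            g: [coerce(i) for i in specs] for g, specs in self.islands.items()
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "islands" in data:
            data["islands"] = {
                g: [IslandSpec(**i) for i in specs]
                for g, specs in data["islands"].items()
            }
        return cls(**data)


@dataclass
class IslandTruth:
    start: int  # 1-based inclusive, includes transposase flanks
    end: int
    member_tags: list[str]
    flanked: bool


@dataclass
class PangenomeTruth:
    truth_tree: str
    family_table: dict[str, dict[str, str]]  # family -> genome -> locus_tag
    family_kind: dict[str, str]  # core | clade | strain | island | transposase
    island_table: dict[str, list[IslandTruth]]
    pseudo_list: list[str]

    def families_of_kind(self, *kinds: str) -> list[str]:
        return [f for f, k in self.family_kind.items() if k in kinds]


# ---------------------------------------------------------------------------
# tree handling


@dataclass
class _Node:
    name: str | None
    length: float
    children: list["_Node"]

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]  # type: ignore[list-item]
        return [x for c in self.children for x in c.leaves()]


def _parse_tree(newick: str) -> _Node:
    t = dendropy.Tree.get(data=newick, schema="newick")

    def conv(nd) -> _Node:
        name = nd.taxon.label if nd.taxon else nd.label
        return _Node(
            name=name,
            length=nd.edge.length or 0.0,
            children=[conv(c) for c in nd.child_nodes()],
        )

    return conv(t.seed_node)


def _find_mrca(node: _Node, leafset: frozenset[str]) -> _Node:
    here = frozenset(node.leaves())
    if not leafset <= here:
        raise ValueError(f"clade {sorted(leafset)} not found in tree")
    for c in node.children:
        if leafset <= frozenset(c.leaves()):
            return _find_mrca(c, leafset)
    return node


# ---------------------------------------------------------------------------
# sequence evolution


def random_protein(length: int, rng: np.random.Generator) -> str:
    aa = rng.choice(len(AA20), size=length, p=AA_FREQS)
    prot = "M" + "".join(AA20[i] for i in aa[1:])
    return prot


def _random_codons(protein: str, rng: np.random.Generator) -> list[str]:
    return [
        _CODONS[a][rng.integers(len(_CODONS[a]))] if a in _CODONS else "NNN"
        for a in protein
    ]


def evolve_protein(ancestor: str, branch_len: float, rng: np.random.Generator) -> str:
    """Site-wise Poisson divergence of a protein along one branch.

    Each site substitutes with probability ``1 - exp(-branch_len)``;
    the replacement is drawn from the BLOSUM62-derived conditional
    distribution over the 19 other residues.  Length is preserved.
    """
    if branch_len < 0:
        raise ValueError("branch length must be non-negative")
    p = 1.0 - math.exp(-branch_len)
    out = list(ancestor)
    hit = rng.random(len(out)) < p
    for i in np.flatnonzero(hit):
        a = out[i]
        if a not in _AA_INDEX:
            continue
        out[i] = AA20[rng.choice(len(AA20), p=_COND[_AA_INDEX[a]])]
    return "".join(out)


def _evolve_gene(
    protein: str, codons: list[str], branch_len: float, rng: np.random.Generator
) -> tuple[str, list[str]]:
    """Codon-aware divergence: substituted sites get a fresh codon."""
    p = 1.0 - math.exp(-branch_len)
    prot = list(protein)
    cods = list(codons)
    hit = rng.random(len(prot)) < p
    for i in np.flatnonzero(hit):
        a = prot[i]
        if a not in _AA_INDEX:
            continue
        b = AA20[rng.choice(len(AA20), p=_COND[_AA_INDEX[a]])]
        prot[i] = b
        cods[i] = _CODONS[b][rng.integers(len(_CODONS[b]))]
    return "".join(prot), cods


def _evolve_dna(seq: str, branch_len: float, rng: np.random.Generator) -> str:
    p = 1.0 - math.exp(-branch_len)
    out = list(seq)
    hit = rng.random(len(out)) < p
    alt = {b: "ACGT".replace(b, "") for b in "ACGT"}
    for i in np.flatnonzero(hit):
        if out[i] in alt:
            out[i] = alt[out[i]][rng.integers(3)]
    return "".join(out)


def _random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=length))


# ---------------------------------------------------------------------------
# simulation


@dataclass
class _FamilyDef:
    family_id: str
    kind: str
    present_in: frozenset[str]
    birth: _Node | None  # None => generated independently at a single leaf
    strand: str
    product: str


def _evolve_down(
    node: _Node,
    state: tuple[str, list[str]],
    rng: np.random.Generator,
    sink: dict[str, tuple[str, list[str]]],
    wanted: frozenset[str],
) -> None:
    if not node.children:
        if node.name in wanted:
            sink[node.name] = state
        return
    for c in node.children:
        if not (frozenset(c.leaves()) & wanted):
            continue
        child_state = _evolve_gene(state[0], state[1], c.length, rng)
        _evolve_down(c, child_state, rng, sink, wanted)


def _evolve_dna_down(
    node: _Node,
    seq: str,
    rng: np.random.Generator,
    sink: dict[str, str],
) -> None:
    if not node.children:
        sink[node.name] = seq  # type: ignore[index]
        return
    for c in node.children:
        _evolve_dna_down(c, _evolve_dna(seq, c.length, rng), rng, sink)


def simulate_pangenome(
    cfg: SimConfig,
) -> tuple[list[GenomeRecord], dict[str, list[tuple[str, str]]], PangenomeTruth]:
    """Generate genomes, proteomes and ground truth from a SimConfig."""
    rng = np.random.default_rng(cfg.seed)
    root = _parse_tree(cfg.tree)
    leaves = root.leaves()
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate leaf names in tree")
    all_leaves = frozenset(leaves)

    # --- define families ---------------------------------------------------
    fams: list[_FamilyDef] = []
    counter = 0

    def new_fam(kind: str, present: frozenset[str], birth: _Node | None,
                product: str) -> _FamilyDef:
        nonlocal counter
        counter += 1
        fam = _FamilyDef(
            family_id=f"F{counter:04d}",
            kind=kind,
            present_in=present,
            birth=birth,
            strand="+" if rng.random() < 0.7 else "-",
            product=product,
        )
        fams.append(fam)
        return fam

    for _ in range(cfg.n_core_families):
        new_fam("core", all_leaves, root, "conserved hypothetical protein")
    for clade_key in sorted(cfg.clade_specific):
        members = frozenset(clade_key.split(","))
        if not members <= all_leaves:
            raise ValueError(f"clade {clade_key!r} names unknown genomes")
        mrca = _find_mrca(root, members)
        for _ in range(cfg.clade_specific[clade_key]):
            new_fam("clade", members, mrca, "clade-specific protein")
    for g in sorted(cfg.strain_specific):
        if g not in all_leaves:
            raise ValueError(f"strain {g!r} not in tree")
        for _ in range(cfg.strain_specific[g]):
            new_fam("strain", frozenset([g]), None, "hypothetical protein")

    # --- evolve backbone genes and spacers ---------------------------------
    per_leaf_genes: dict[str, dict[str, tuple[str, list[str]]]] = {
        g: {} for g in leaves
    }
    for fam in fams:
        length = max(cfg.gene_len_min, int(rng.normal(cfg.gene_len_mean,
                                                      cfg.gene_len_sd)))
        prot = random_protein(length, rng)
        cods = _random_codons(prot, rng)
        if fam.birth is None:
            (g,) = fam.present_in
            per_leaf_genes[g][fam.family_id] = (prot, cods)
        else:
            sink: dict[str, tuple[str, list[str]]] = {}
            _evolve_down(fam.birth, (prot, cods), rng, sink, fam.present_in)
            for g, state in sink.items():
                per_leaf_genes[g][fam.family_id] = state

    order = [f.family_id for f in fams]
    rng.shuffle(order)
    fam_by_id = {f.family_id: f for f in fams}

    n_slots = len(order) + 1
    spacer_per_leaf: list[dict[str, str]] = []
    for _ in range(n_slots):
        length = max(cfg.intergenic_len_min,
                     int(rng.normal(cfg.intergenic_len_mean, cfg.intergenic_len_sd)))
        anc = _random_dna(length, rng)
        sink_d: dict[str, str] = {}
        _evolve_dna_down(root, anc, rng, sink_d)
        spacer_per_leaf.append(sink_d)

    # conserved structural RNA loci (identical across genomes)
    rrna_units = [
        [("rRNA", "16S ribosomal RNA", _random_dna(300, rng)),
         ("spacer", "", _random_dna(60, rng)),
         ("rRNA", "23S ribosomal RNA", _random_dna(500, rng)),
         ("spacer", "", _random_dna(40, rng)),
         ("rRNA", "5S ribosomal RNA", _random_dna(120, rng))]
        for _ in range(cfg.n_rrna_operons)
    ]
    trna_units = [_random_dna(75, rng) for _ in range(cfg.n_trnas)]
    rna_slots: dict[int, list] = {}
    if rrna_units or trna_units:
        pool = [("rrna", u) for u in rrna_units] + [("trna", u) for u in trna_units]
        if len(pool) > len(order):
            raise ValueError("more RNA loci requested than gene junctions")
        slots = rng.choice(len(order), size=len(pool), replace=False)
        for s, item in zip(slots, pool):
            rna_slots.setdefault(int(s), []).append(item)

    # --- island content per genome ------------------------------------------
    island_defs: dict[str, list[dict]] = {g: [] for g in leaves}
    # islands insert at junctions whose backbone gene is core, so both
    # island boundaries abut sequence shared by every genome
    core_junctions = [
        i for i, fid in enumerate(order) if fam_by_id[fid].kind == "core"
    ]
    for g in sorted(cfg.islands):
        specs = cfg.islands[g]
        if len(specs) > len(core_junctions):
            raise ValueError(f"too many islands requested for {g}")
        # keep islands >= 2 backbone slots apart so flank flags stay
        # attributable to their own island
        for _ in range(1000):
            junctions = rng.choice(core_junctions, size=len(specs), replace=False)
            js = sorted(int(j) for j in junctions)
            if all(b - a >= 2 for a, b in zip(js, js[1:])):
                break
        else:  # pragma: no cover
            raise ValueError(f"could not place islands for {g} far enough apart")
        for spec, junction in zip(specs, sorted(int(j) for j in junctions)):
            genes = []
            if spec.flank_with_transposase:
                tl = max(60, int(rng.normal(110, 20)))
                prot = random_protein(tl, rng)
                genes.append((new_fam("transposase", frozenset([g]), None,
                                      "transposase, IS element"), prot))
            for _ in range(spec.n_genes):
                length = max(cfg.gene_len_min,
                             int(rng.normal(cfg.gene_len_mean, cfg.gene_len_sd)))
                prot = random_protein(length, rng)
                genes.append((new_fam("island", frozenset([g]), None,
                                      "island protein"), prot))
            if spec.flank_with_transposase:
                tl = max(60, int(rng.normal(110, 20)))
                prot = random_protein(tl, rng)
                genes.append((new_fam("transposase", frozenset([g]), None,
                                      "transposase, IS element, truncated"), prot))
            island_defs[g].append(
                {"junction": junction, "flanked": spec.flank_with_transposase,
                 "genes": [(f, p, _random_codons(p, rng)) for f, p in genes]}
            )

    # --- assemble genomes ----------------------------------------------------
    genomes: list[GenomeRecord] = []
    proteomes: dict[str, list[tuple[str, str]]] = {}
    family_table: dict[str, dict[str, str]] = {f.family_id: {} for f in fams}
    island_table: dict[str, list[IslandTruth]] = {g: [] for g in leaves}
    pseudo_list: list[str] = []

    for g in leaves:
        parts: list[str] = []
        feats: list[Feature] = []
        proteome: list[tuple[str, str]] = []
        cursor = 0
        tag_no = 0

        # choose pseudogenised gene copies for this genome up front
        leaf_fams = [fid for fid in order if fid in per_leaf_genes[g]]
        island_fids = [f.family_id for isl in island_defs[g] for f, _, _ in isl["genes"]]
        candidates = leaf_fams + island_fids
        n_pseudo = int(round(cfg.pseudo_frac * len(candidates)))
        pseudo_fids = set(
            rng.choice(candidates, size=n_pseudo, replace=False)
        ) if n_pseudo else set()

        def emit_gene(fam: _FamilyDef, prot: str, cods: list[str]) -> str:
            nonlocal cursor, tag_no
            tag_no += 1
            tag = f"{g}_{tag_no:04d}"
            pseudo = fam.family_id in pseudo_fids
            if pseudo:
                stop_at = int(len(prot) * (0.5 + 0.4 * rng.random()))
                stop_at = min(max(stop_at, 1), len(prot) - 1)
                cods = cods[:stop_at] + ["TAA"] + cods[stop_at + 1 :]
                prot_out = prot[:stop_at]
                pseudo_list.append(tag)
            else:
                prot_out = prot
            nt = "".join(cods) + "TAA"
            if fam.strand == "-":
                nt_fwd = _revcomp(nt)
            else:
                nt_fwd = nt
            start = cursor + 1
            parts.append(nt_fwd)
            cursor += len(nt_fwd)
            feats.append(
                Feature(
                    kind="pseudogene" if pseudo else "CDS",
                    locus_tag=tag,
                    start=start,
                    end=cursor,
                    strand=fam.strand,
                    product=fam.product + (", truncated" if pseudo else ""),
                    translation=prot_out,
                    is_pseudo=pseudo,
                )
            )
            proteome.append((tag, prot_out))
            family_table[fam.family_id][g] = tag
            return tag

        def emit_dna(seq: str) -> None:
            nonlocal cursor
            parts.append(seq)
            cursor += len(seq)

        def emit_rna(kind: str, product: str, seq: str) -> None:
            nonlocal cursor, tag_no
            tag_no += 1
            start = cursor + 1
            emit_dna(seq)
            feats.append(
                Feature(kind=kind, locus_tag=f"{g}_{tag_no:04d}", start=start,
                        end=cursor, strand="+", product=product)
            )

        islands_at = {isl["junction"]: isl for isl in island_defs[g]}
        for slot, fid in enumerate(order):
            emit_dna(spacer_per_leaf[slot][g])
            for kind, unit in rna_slots.get(slot, ()):  # conserved RNA loci
                if kind == "rrna":
                    for k2, product, seq in unit:
                        if k2 == "spacer":
                            emit_dna(seq)
                        else:
                            emit_rna("rRNA", product, seq)
                else:
                    emit_rna("tRNA", "tRNA", unit)
            isl = islands_at.get(slot)
            if isl is not None:
                isl_start = cursor + 1
                tags: list[str] = []
                for k, (fam, prot, cods) in enumerate(isl["genes"]):
                    if k:
                        emit_dna(_random_dna(30, rng))
                    tags.append(emit_gene(fam, prot, cods))
                island_table[g].append(
                    IslandTruth(isl_start, cursor, tags, isl["flanked"])
                )
            if fid in per_leaf_genes[g]:
                prot, cods = per_leaf_genes[g][fid]
                emit_gene(fam_by_id[fid], prot, cods)
        emit_dna(spacer_per_leaf[len(order)][g])

        rec = GenomeRecord(
            genome_id=g,
            replicon_id=g,
            sequence="".join(parts),
            features=feats,
            topology="circular" if cfg.circular else "linear",
        )
        if cfg.circular:
            rec = rotate_genome(rec, int(rng.integers(len(rec))))
        genomes.append(rec)
        proteomes[g] = proteome

    truth = PangenomeTruth(
        truth_tree=cfg.tree,
        family_table={f: m for f, m in family_table.items() if m},
        family_kind={f.family_id: f.kind for f in fams},
        island_table=island_table,
        pseudo_list=pseudo_list,
    )
    return genomes, proteomes, truth


#: ultrametric demo tree: a tight pair (A, B) diverging from C inside one
#: clade, with a second clade (D, E) as outgroup — the qualitative
#: structure of closely related dairy strains versus a sister species
DEMO_TREE = "(((A:0.02,B:0.02):0.04,C:0.06):0.09,(D:0.12,E:0.12):0.03);"


def demo_config(seed: int = 0) -> SimConfig:
    """The bundled 5-genome demonstration pangenome (~60 genes/genome)."""
    return SimConfig(
        tree=DEMO_TREE,
        n_core_families=40,
        clade_specific={"A,B,C": 6, "D,E": 5},
        strain_specific={"A": 4, "B": 3, "C": 3, "D": 2, "E": 2},
        islands={
            "A": [IslandSpec(4, True), IslandSpec(3, False)],
            "B": [IslandSpec(3, True)],
            "C": [IslandSpec(4, True)],
        },
        pseudo_frac=0.05,
        n_rrna_operons=3,
        n_trnas=8,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# emission and truth round-trip


def write_pangenome(
    genomes: list[GenomeRecord],
    proteomes: dict[str, list[tuple[str, str]]],
    outdir: str | Path,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in genomes:
        write_fasta([(rec.replicon_id, rec.sequence)], outdir / f"{rec.genome_id}.fna")
        write_fasta(proteomes[rec.genome_id], outdir / f"{rec.genome_id}.faa")
        with (outdir / f"{rec.genome_id}.gff3").open("w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {rec.replicon_id} 1 {len(rec)}\n")
            for f in sorted(rec.features, key=lambda f: (f.start, f.locus_tag)):
                ftype = "pseudogene" if f.is_pseudo else f.kind
                attrs = [f"ID={f.locus_tag}", f"locus_tag={f.locus_tag}"]
                if f.product:
                    attrs.append("product=" + f.product.replace(";", "%3B"))
                if f.translation:
                    attrs.append(f"translation={f.translation}")
                if f.is_pseudo:
                    attrs.append("pseudo=true")
                phase = "0" if f.kind in ("CDS", "pseudogene") else "."
                fh.write(
                    f"{rec.replicon_id}\tfgdpipe_sim\t{ftype}\t{f.start}\t{f.end}"
                    f"\t.\t{f.strand}\t{phase}\t{';'.join(attrs)}\n"
                )


def truth_report(truth: PangenomeTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth_tree.nwk").write_text(truth.truth_tree.strip() + "\n")
    genomes = sorted({g for m in truth.family_table.values() for g in m})
    with (outdir / "family_table.tsv").open("w") as fh:
        fh.write("family_id\tkind\t" + "\t".join(genomes) + "\n")
        for fid in sorted(truth.family_table):
            row = truth.family_table[fid]
            fh.write(
                f"{fid}\t{truth.family_kind[fid]}\t"
                + "\t".join(row.get(g, "-") for g in genomes) + "\n"
            )
    with (outdir / "islands.tsv").open("w") as fh:
        fh.write("genome\tstart\tend\tflanked\tmember_tags\n")
        for g in sorted(truth.island_table):
            for isl in truth.island_table[g]:
                fh.write(
                    f"{g}\t{isl.start}\t{isl.end}\t{isl.flanked}\t"
                    + ",".join(isl.member_tags) + "\n"
                )
    (outdir / "pseudogenes.txt").write_text(
        "".join(t + "\n" for t in truth.pseudo_list)
    )


def load_truth(outdir: str | Path) -> PangenomeTruth:
    outdir = Path(outdir)
    tree = (outdir / "truth_tree.nwk").read_text().strip()
    family_table: dict[str, dict[str, str]] = {}
    family_kind: dict[str, str] = {}
    with (outdir / "family_table.tsv").open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        genomes = header[2:]
        for line in fh:
            f = line.rstrip("\n").split("\t")
            family_kind[f[0]] = f[1]
            family_table[f[0]] = {
                g: t for g, t in zip(genomes, f[2:]) if t != "-"
            }
    island_table: dict[str, list[IslandTruth]] = {}
    with (outdir / "islands.tsv").open() as fh:
        fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            island_table.setdefault(f[0], []).append(
                IslandTruth(int(f[1]), int(f[2]), f[4].split(","), f[3] == "True")
            )
    pseudo = (outdir / "pseudogenes.txt").read_text().split()
    return PangenomeTruth(tree, family_table, family_kind, island_table, pseudo)
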