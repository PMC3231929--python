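"""Genome input/output and deposited-annotation statistics.

Genomes enter the pipeline either as GenBank flat files or as a
FASTA + GFF3 pair.  Externally all coordinates are 1-based inclusive
(GenBank/GFF3 convention); interval arithmetic elsewhere in the package
goes through :func:`feature_interval` / :func:`to_interval`, which are
the only places that translate to 0-based half-open.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

FeatureKind = Literal["CDS", "pseudogene", "tRNA", "rRNA"]

#: genetic code used for bacterial CDS translation when no deposited
#: translation is available (NCBI translation table 11)
BACTERIAL_TABLE = 11


class GenomeValidationError(ValueError):
    """Raised when a parsed record violates a structural invariant."""


@dataclass
class Feature:
    """A single annotated feature on a replicon.

    ``start``/``end`` are 1-based inclusive.  A feature wrapping the
    origin of a circular replicon has ``start > end``; use
    :func:`feature_interval` to obtain its (possibly split) 0-based
    half-open intervals.
    """

    kind: FeatureKind
    locus_tag: str
    start: int
    end: int
    strand: str  # '+' or '-'
    product: str = ""
    translation: str | None = None
    is_pseudo: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeValidationError(
                f"{self.locus_tag}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.translation is not None and self.kind not in ("CDS", "pseudogene"):
            raise GenomeValidationError(
                f"{self.locus_tag}: translation only allowed on CDS/pseudogene"
            )
        if self.kind == "pseudogene":
            self.is_pseudo = True

    @property
    def wraps_origin(self) -> bool:
        return self.start > self.end

    def length(self, replicon_len: int | None = None) -> int:
        if not self.wraps_origin:
            return self.end - self.start + 1
        if replicon_len is None:
            raise GenomeValidationError(
                f"{self.locus_tag} wraps the origin; replicon length required"
            )
        return (replicon_len - self.start + 1) + self.end


@dataclass
class GenomeRecord:
    genome_id: str
    replicon_id: str
    sequence: str
    features: list[Feature] = field(default_factory=list)
    topology: Literal["circular", "linear"] = "linear"

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise GenomeValidationError(f"{self.replicon_id}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise GenomeValidationError(
                f"{self.replicon_id}: non-ACGTN characters {sorted(bad)!r}"
            )
        n = len(self.sequence)
        for f in self.features:
            if not (1 <= f.start <= n and 1 <= f.end <= n):
                raise GenomeValidationError(
                    f"{f.locus_tag}: coordinates {f.start}..{f.end} outside [1, {n}]"
                )
            if f.wraps_origin and self.topology != "circular":
                raise GenomeValidationError(
                    f"{f.locus_tag}: start > end on a linear replicon"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_seq(self, f: Feature) -> str:
        """Nucleotide sequence of a feature in reading orientation."""
        if f.wraps_origin:
            nt = self.sequence[f.start - 1 :] + self.sequence[: f.end]
        else:
            nt = self.sequence[f.start - 1 : f.end]
        if f.strand == "-":
            nt = str(Seq(nt).reverse_complement())
        return nt


@dataclass
class GenomeStats:
    length_bp: int
    gc_pct: float
    orf_count: int
    orfeome_gc_pct: float
    mean_gene_len_bp: float
    coding_density_pct: float
    pseudo_count: int
    trna_count: int
    rrna_operon_count: int


# ---------------------------------------------------------------------------
# coordinate conversion — the single place 1-based inclusive becomes
# 0-based half-open


def to_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def from_interval(lo: int, hi: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return lo + 1, hi


def feature_interval(f: Feature, replicon_len: int) -> list[tuple[int, int]]:
    """0-based half-open interval(s) of a feature.

    An origin-wrapping feature of a circular replicon is split into two
    intervals for interval arithmetic; it still counts as one ORF.
    """
    if not f.wraps_origin:
        return [to_interval(f.start, f.end)]
    return [to_interval(f.start, replicon_len), to_interval(1, f.end)]


# ---------------------------------------------------------------------------
# readers


def _parse_genbank(path: Path, genome_id: str | None) -> GenomeRecord:
    try:
        rec = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise GenomeValidationError(f"{path}: no GenBank record found") from None
    feats: list[Feature] = []
    n = len(rec.seq)
    for fi, f in enumerate(rec.features):
        if f.type not in ("CDS", "tRNA", "rRNA"):
            continue
        q = f.qualifiers
        tag = q.get("locus_tag", [f"feat{fi}"])[0]
        start = int(f.location.start) + 1
        end = int(f.location.end)
        strand = "-" if f.location.strand == -1 else "+"
        pseudo = "pseudo" in q or "pseudogene" in q
        kind: FeatureKind
        if f.type == "CDS":
            kind = "pseudogene" if pseudo else "CDS"
        else:
            kind = f.type  # type: ignore[assignment]
        feats.append(
            Feature(
                kind=kind,
                locus_tag=tag,
                start=start,
                end=end,
                strand=strand,
                product=q.get("product", [""])[0],
                translation=q.get("translation", [None])[0],
                is_pseudo=pseudo,
            )
        )
    topology = "circular" if rec.annotations.get("topology") == "circular" else "linear"
    return GenomeRecord(
        genome_id=genome_id or rec.name,
        replicon_id=rec.name or rec.id,
        sequence=str(rec.seq),
        features=feats,
        topology=topology,
    )


def _parse_fasta_gff3(fasta: Path, gff3: Path, genome_id: str | None) -> GenomeRecord:
    import gffutils

    try:
        rec = next(SeqIO.parse(str(fasta), "fasta"))
    except StopIteration:
        raise GenomeValidationError(f"{fasta}: no FASTA record found") from None
    db = gffutils.create_db(
        str(gff3),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    feats: list[Feature] = []
    for f in db.all_features(order_by=("start",)):
        if f.featuretype not in ("CDS", "pseudogene", "tRNA", "rRNA"):
            continue
        tag = f.attributes.get("locus_tag", f.attributes.get("ID", ["?"]))[0]
        pseudo = (
            f.featuretype == "pseudogene"
            or f.attributes.get("pseudo", ["false"])[0].lower() == "true"
        )
        kind: FeatureKind
        if f.featuretype in ("CDS", "pseudogene"):
            kind = "pseudogene" if pseudo else "CDS"
        else:
            kind = f.featuretype  # type: ignore[assignment]
        translation = f.attributes.get("translation", [None])[0]
        feats.append(
            Feature(
                kind=kind,
                locus_tag=tag,
                start=f.start,
                end=f.end,
                strand="-" if f.strand == "-" else "+",
                product=f.attributes.get("product", [""])[0],
                translation=translation,
                is_pseudo=pseudo,
            )
        )
    return GenomeRecord(
        genome_id=genome_id or rec.id,
        replicon_id=rec.id,
        sequence=str(rec.seq),
        features=feats,
    )


def read_genome(
    path: str | Path,
    format: str = "genbank",
    gff3: str | Path | None = None,
    genome_id: str | None = None,
) -> GenomeRecord:
    """Read one replicon.

    Parameters
    ----------
    path:
        GenBank flat file, or the FASTA file when ``format="fasta+gff3"``.
    format:
        ``"genbank"`` or ``"fasta+gff3"``.
    gff3:
        Annotation file, required for ``fasta+gff3``.
    genome_id:
        Overrides the genome identifier (defaults to the record name).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "genbank":
        return _parse_genbank(path, genome_id)
    if format == "fasta+gff3":
        if gff3 is None:
            raise ValueError("fasta+gff3 format requires the gff3= argument")
        return _parse_fasta_gff3(path, Path(gff3), genome_id)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# statistics (deposited-annotation genome table)


def _gc_pct(seq: str) -> float:
    acgt = sum(seq.count(c) for c in "ACGT")
    if acgt == 0:
        return 0.0
    return 100.0 * (seq.count("G") + seq.count("C")) / acgt


def genome_stats(genome: GenomeRecord, rrna_gap_bp: int = 2000) -> GenomeStats:
    """Summary statistics of one replicon from its deposited annotation.

    ORFs are CDS plus pseudogene features.  Coding density is the *sum*
    of ORF lengths over the replicon length (overlapping ORFs counted
    twice), matching the usual genome-table arithmetic of
    mean-gene-length x ORF-count / genome-length.  rRNA genes whose
    inter-feature gap is at most ``rrna_gap_bp`` are clustered into one
    operon (the 16S-23S-5S unit spans a few kb).
    """
    if rrna_gap_bp <= 0:
        raise ValueError("rrna_gap_bp must be positive")
    n = len(genome)
    orfs = [f for f in genome.features if f.kind in ("CDS", "pseudogene")]
    orf_len = sum(f.length(n) for f in orfs)
    orfeome_nt = "".join(genome.feature_seq(f) for f in orfs)
    rrnas = sorted(
        (f for f in genome.features if f.kind == "rRNA"), key=lambda f: f.start
    )
    operons = 0
    prev_end = None
    for f in rrnas:
        if prev_end is None or f.start - prev_end - 1 > rrna_gap_bp:
            operons += 1
        prev_end = max(prev_end or 0, f.end)
    return GenomeStats(
        length_bp=n,
        gc_pct=_gc_pct(genome.sequence),
        orf_count=len(orfs),
        orfeome_gc_pct=_gc_pct(orfeome_nt) if orfs else 0.0,
        mean_gene_len_bp=orf_len / len(orfs) if orfs else 0.0,
        coding_density_pct=100.0 * orf_len / n,
        pseudo_count=sum(1 for f in orfs if f.is_pseudo),
        trna_count=sum(1 for f in genome.features if f.kind == "tRNA"),
        rrna_operon_count=operons,
    )


# ---------------------------------------------------------------------------
# ORFeome extraction


def translate_cds(nt: str) -> str:
    """Translate a CDS with the bacterial code, stripping the stop."""
    rem = len(nt) % 3
    if rem:
        nt = nt[: len(nt) - rem]
    aa = str(Seq(nt).translate(table=BACTERIAL_TABLE))
    return aa.rstrip("*")


def extract_orfeome(
    genome: GenomeRecord, include_pseudo: bool = True
) -> list[tuple[str, str]]:
    """(locus_tag, protein) pairs ordered by start coordinate.

    One entry per CDS; pseudogenes are included when ``include_pseudo``
    and a deposited translation exists (their reading frames are broken,
    so we never re-translate them).  Deposited translations are
    preferred; otherwise the CDS is translated with the bacterial code.
    """
    out: list[tuple[str, str]] = []
    for f in sorted(genome.features, key=lambda f: (f.start, f.locus_tag)):
        if f.kind == "CDS" and not f.is_pseudo:
            if f.translation:
                aa = f.translation.rstrip("*")
            else:
                nt = genome.feature_seq(f)
                if len(nt) % 3 != 0:
                    warnings.warn(
                        f"{f.locus_tag}: CDS length {len(nt)} not divisible by 3; "
                        "best-effort translation",
                        stacklevel=2,
                    )
                aa = translate_cds(nt)
            if aa:
                out.append((f.locus_tag, aa))
        elif f.kind == "pseudogene" and include_pseudo and f.translation:
            aa = f.translation.rstrip("*")
            if aa:
                out.append((f.locus_tag, aa))
    return out


# ---------------------------------------------------------------------------
# writers


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(r.description, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_tsv(rows: Sequence[dict], path: str | Path) -> None:
    path = Path(path)
    rows = list(rows)
    with path.open("w", newline="") as fh:
        if not rows:
            return
        w = csv.DictWriter(fh, fieldnames=list(rows[0].keys()), delimiter="\t")
        w.writeheader()
        w.writerows(rows)


def write_bed(
    intervals: Iterable[tuple[str, int, int, str]], path: str | Path
) -> None:
    """Write (chrom, start_1based, end_1based, name) as 0-based half-open BED."""
    path = Path(path)
    with path.open("w") as fh:
        for chrom, start, end, name in intervals:
            lo, hi = to_interval(start, end)
            fh.write(f"{chrom}\t{lo}\t{hi}\t{name}\n")


def rotate_genome(genome: GenomeRecord, offset: int) -> GenomeRecord:
    """Rotate a circular replicon so position ``offset`` (0-based) becomes base 1.

    Features crossing the new origin get start > end (wrap convention).
    """
    if genome.topology != "circular":
        raise GenomeValidationError("rotation only defined for circular replicons")
    n = len(genome)
    offset %= n
    seq = genome.sequence[offset:] + genome.sequence[:offset]

    def shift(pos: int) -> int:
        return (pos - 1 - offset) % n + 1

    feats = [replace(f, start=shift(f.start), end=shift(f.end)) for f in genome.features]
    return GenomeRecord(
        genome_id=genome.genome_id,
        replicon_id=genome.replicon_id,
        sequence=seq,
        features=feats,
        topology="circular",
    )
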