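"""Strain-specific region detection from whole-genome nucleotide comparison.

A reference replicon is aligned against each query genome with a
megablast-like strategy (exact word anchors, ungapped X-drop extension,
greedy redundancy filtering).  Reference stretches longer than
``min_region_len`` with no aligned counterpart are *specific regions*;
regions absent from several queries are intersected, annotated ORFs are
mapped into them, nearby regions are grouped into chromosomal loci, and
loci bordered by transposase genes are flagged as candidate IS-driven
islands.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._kernels import xdrop_extend
from .genome_io import Feature, GenomeRecord, feature_interval, to_interval
from .pairwise import ScoringScheme

DEFAULT_WORD_LEN = 16
DEFAULT_XDROP = 100
MIN_REGION_LEN = 50  # regions must be strictly longer than this

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class AlignedBlock:
    ref_start: int  # 1-based inclusive
    ref_end: int
    qry_start: int
    qry_end: int
    strand: str
    pct_identity: float
    score: int

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start + 1


@dataclass
class SpecificRegion:
    ref_id: str
    start: int  # 1-based inclusive
    end: int
    absent_from: set[str] = field(default_factory=set)
    orfs: list[str] = field(default_factory=list)
    locus_id: int | None = None
    transposase_flanked: bool = False

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# anchored nucleotide alignment


def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed 2-bit k-mer integers and a validity mask (no N) per position."""
    lut = np.full(128, -1, dtype=np.int64)
    for i, c in enumerate("ACGT"):
        lut[ord(c)] = i
    codes = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    km = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(k):
        c = codes[i : n + i]
        km = (km << 2) | np.where(c < 0, 0, c)
        valid &= c >= 0
    return km, valid


def _scan_strand(
    ref_u8: np.ndarray,
    qry_seq: str,
    index: dict[int, list[int]],
    word_len: int,
    match: int,
    mismatch: int,
    xdrop: int,
) -> list[tuple[int, int, int, int, int, int]]:
    """Anchor-and-extend one query strand; spans are 0-based half-open."""
    qry_u8 = np.frombuffer(qry_seq.encode("ascii"), dtype=np.uint8)
    km, valid = _kmer_codes(qry_seq, word_len)
    covered: dict[int, int] = {}  # diagonal (r - q) -> qry end already extended
    out = []
    for q0 in range(len(km)):
        if not valid[q0]:
            continue
        positions = index.get(int(km[q0]))
        if not positions:
            continue
        for r0 in positions:
            diag = r0 - q0
            if covered.get(diag, -1) >= q0 + word_len:
                continue
            rs, re_, qs, qe, score, matches = xdrop_extend(
                ref_u8, qry_u8, r0, q0, word_len, match, mismatch, xdrop
            )
            covered[diag] = qe
            out.append((rs, re_, qs, qe, score, matches))
    return out


def nucleotide_align(
    ref: GenomeRecord,
    qry: GenomeRecord,
    s: ScoringScheme | None = None,
    word_len: int = DEFAULT_WORD_LEN,
    xdrop: int = DEFAULT_XDROP,
    max_kmer_hits: int = 50,
    containment_frac: float = 0.9,
    e_max: float = 1e-3,
) -> list[AlignedBlock]:
    """Megablast-like anchored comparison of two replicons.

    Both query strands are searched.  Blocks must reach Karlin-Altschul
    E-value <= ``e_max`` for the two-replicon search space (a bare word
    hit is expected by chance in genome-scale comparisons and would
    otherwise shred the coverage complement).  Blocks whose reference
    interval is at least ``containment_frac`` contained in a
    higher-scoring kept block are dropped (greedy non-redundancy), and
    word anchors occurring more than ``max_kmer_hits`` times in the
    reference are skipped as repeats.
    """
    if s is None:
        s = ScoringScheme.nucleotide_default()
    match = int(s.matrix[0, 0])
    mismatch = int(s.matrix[0, 1])
    # smallest raw score with E <= e_max in an m*n search space
    mn = float(len(ref.sequence)) * float(len(qry.sequence))
    min_bits = math.log2(mn / e_max) if e_max > 0 else 0.0
    min_score = (min_bits * math.log(2.0) + math.log(s.K)) / s.lam
    ref_u8 = np.frombuffer(ref.sequence.encode("ascii"), dtype=np.uint8)
    km, valid = _kmer_codes(ref.sequence, word_len)
    index: dict[int, list[int]] = {}
    for pos in np.flatnonzero(valid):
        index.setdefault(int(km[pos]), []).append(int(pos))
    index = {k: v for k, v in index.items() if len(v) <= max_kmer_hits}

    raw: list[AlignedBlock] = []
    for strand, qseq in (("+", qry.sequence), ("-", revcomp(qry.sequence))):
        nq = len(qseq)
        for rs, re_, qs, qe, score, matches in _scan_strand(
            ref_u8, qseq, index, word_len, match, mismatch, xdrop
        ):
            if score < min_score:
                continue
            length = re_ - rs
            if strand == "+":
                q1, q2 = qs + 1, qe
            else:  # map back to forward query coordinates
                q1, q2 = nq - qe + 1, nq - qs
            raw.append(
                AlignedBlock(
                    ref_start=rs + 1,
                    ref_end=re_,
                    qry_start=q1,
                    qry_end=q2,
                    strand=strand,
                    pct_identity=100.0 * matches / length if length else 0.0,
                    score=int(score),
                )
            )
    raw.sort(key=lambda b: (-b.score, b.ref_start, b.qry_start, b.strand))
    kept: list[AlignedBlock] = []
    for b in raw:
        redundant = False
        for k in kept:
            lo = max(b.ref_start, k.ref_start)
            hi = min(b.ref_end, k.ref_end)
            if hi >= lo and (hi - lo + 1) >= containment_frac * b.ref_len:
                redundant = True
                break
        if not redundant:
            kept.append(b)
    kept.sort(key=lambda b: (b.ref_start, b.ref_end))
    return kept


# ---------------------------------------------------------------------------
# specific regions


def _coverage_mask(length: int, blocks: list[AlignedBlock]) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for b in blocks:
        lo, hi = to_interval(b.ref_start, b.ref_end)
        mask[lo:hi] = True
    return mask


def _mask_to_regions(
    mask_absent: np.ndarray,
    ref_id: str,
    absent_from: set[str],
    min_region_len: int,
) -> list[SpecificRegion]:
    regions: list[SpecificRegion] = []
    padded = np.concatenate(([False], mask_absent, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for lo, hi in zip(edges[::2], edges[1::2]):
        if hi - lo > min_region_len:  # strictly longer
            regions.append(
                SpecificRegion(ref_id, int(lo) + 1, int(hi), set(absent_from))
            )
    return regions


def specific_regions(
    ref: GenomeRecord,
    blocks: list[AlignedBlock],
    min_region_len: int = MIN_REGION_LEN,
    query_id: str = "query",
) -> list[SpecificRegion]:
    """Complement of the aligned-block union, filtered to > min length."""
    mask = _coverage_mask(len(ref), blocks)
    return _mask_to_regions(~mask, ref.replicon_id, {query_id}, min_region_len)


def multi_query_specific(
    ref: GenomeRecord,
    per_query_regions: list[list[SpecificRegion]],
    min_region_len: int = MIN_REGION_LEN,
) -> list[SpecificRegion]:
    """Reference stretches specific with respect to *every* query."""
    if not per_query_regions:
        raise ValueError("need at least one query region list")
    if len(per_query_regions) == 1:
        return list(per_query_regions[0])
    mask = np.ones(len(ref), dtype=bool)
    absent: set[str] = set()
    for regions in per_query_regions:
        qmask = np.zeros(len(ref), dtype=bool)
        for r in regions:
            lo, hi = to_interval(r.start, r.end)
            qmask[lo:hi] = True
            absent |= r.absent_from
        mask &= qmask
    return _mask_to_regions(mask, ref.replicon_id, absent, min_region_len)


def coverage_accounting(
    ref: GenomeRecord,
    blocks: list[AlignedBlock],
    min_region_len: int = MIN_REGION_LEN,
) -> dict[str, int]:
    """covered + specific + sub-threshold gap bp partition of the reference."""
    mask = _coverage_mask(len(ref), blocks)
    regions = specific_regions(ref, blocks, min_region_len)
    specific_bp = sum(r.length_bp for r in regions)
    covered_bp = int(mask.sum())
    return {
        "covered_bp": covered_bp,
        "specific_bp": specific_bp,
        "subthreshold_gap_bp": len(ref) - covered_bp - specific_bp,
        "total_bp": len(ref),
    }


# ---------------------------------------------------------------------------
# ORF mapping, locus grouping, transposase flags


def map_orfs_and_loci(
    regions: list[SpecificRegion],
    genome: GenomeRecord,
    min_overlap_frac: float = 0.5,
    locus_gap_bp: int = 5000,
) -> list[SpecificRegion]:
    """Assign ORFs into regions and group nearby regions into loci.

    An ORF belongs to a region when the overlap covers at least
    ``min_overlap_frac`` of the ORF's length.  Consecutive regions whose
    gap is at most ``locus_gap_bp`` share a locus id (1-based, in
    coordinate order).  Headline ORF/locus counts are sensitive to both
    knobs.
    """
    if not 0 < min_overlap_frac <= 1:
        raise ValueError("min_overlap_frac must be in (0, 1]")
    n = len(genome)
    orfs = [f for f in genome.features if f.kind in ("CDS", "pseudogene")]
    regions = sorted(regions, key=lambda r: (r.start, r.end))
    for r in regions:
        rlo, rhi = to_interval(r.start, r.end)
        members = []
        for f in orfs:
            flen = f.length(n)
            overlap = 0
            for lo, hi in feature_interval(f, n):
                overlap += max(0, min(hi, rhi) - max(lo, rlo))
            if overlap >= min_overlap_frac * flen:
                members.append(f.locus_tag)
        r.orfs = members
    locus = 0
    prev_end: int | None = None
    for r in regions:
        if prev_end is None or r.start - prev_end - 1 > locus_gap_bp:
            locus += 1
        r.locus_id = locus
        prev_end = max(prev_end or 0, r.end)
    return regions


def flag_transposase_flanks(
    regions: list[SpecificRegion],
    genome: GenomeRecord,
    window_bp: int = 1000,
    lexicon: tuple[str, ...] = ("transposase",),
    level: str = "locus",
) -> list[SpecificRegion]:
    """Flag loci bordered by (possibly truncated/pseudo) transposase genes.

    A locus is flagged when a feature whose product matches the lexicon
    (case-insensitive substring, pseudogenes included) lies within
    ``window_bp`` of either locus boundary, inside or outside the locus.
    With ``level="region"`` each region is flagged from its own
    boundaries instead of the locus extent.
    """
    pattern = re.compile("|".join(re.escape(w) for w in lexicon), re.IGNORECASE)
    transposases = [
        f for f in genome.features if f.product and pattern.search(f.product)
    ]

    def near_boundary(start: int, end: int) -> bool:
        for f in transposases:
            for b in (start, end):
                if f.start <= b + window_bp and f.end >= b - window_bp:
                    return True
        return False

    if level == "region":
        for r in regions:
            r.transposase_flanked = near_boundary(r.start, r.end)
        return regions
    by_locus: dict[int, list[SpecificRegion]] = {}
    for r in regions:
        if r.locus_id is not None:
            by_locus.setdefault(r.locus_id, []).append(r)
    for rs in by_locus.values():
        flagged = near_boundary(min(r.start for r in rs), max(r.end for r in rs))
        for r in rs:
            r.transposase_flanked = flagged
    return regions


# ---------------------------------------------------------------------------
# serialization


def regions_to_bed(regions: list[SpecificRegion], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for i, r in enumerate(sorted(regions, key=lambda r: r.start), 1):
            lo, hi = to_interval(r.start, r.end)
            fh.write(f"{r.ref_id}\t{lo}\t{hi}\tregion_{i}\n")


def regions_to_tsv(regions: list[SpecificRegion], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(
            "ref_id\tstart\tend\tlength_bp\tabsent_from\tlocus_id\t"
            "transposase_flanked\torfs\n"
        )
        for r in sorted(regions, key=lambda r: r.start):
            fh.write(
                f"{r.ref_id}\t{r.start}\t{r.end}\t{r.length_bp}\t"
                f"{','.join(sorted(r.absent_from))}\t{r.locus_id}\t"
                f"{r.transposase_flanked}\t{','.join(r.orfs)}\n"
            )


def blocks_to_tsv(blocks: list[AlignedBlock], path: str | Path) -> None:
    """GenomeComp-like paired-coordinates table."""
    with Path(path).open("w") as fh:
        fh.write("ref_start\tref_end\tqry_start\tqry_end\tstrand\tpct_identity\tscore\n")
        for b in blocks:
            fh.write(
                f"{b.ref_start}\t{b.ref_end}\t{b.qry_start}\t{b.qry_end}\t"
                f"{b.strand}\t{b.pct_identity:.2f}\t{b.score}\n"
            )
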