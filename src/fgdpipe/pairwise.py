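"""Local protein/nucleotide alignment with bit-score and E-value statistics.

The exact aligner is plain Smith-Waterman with affine gaps; the
all-vs-all search uses exact k-mer seeding followed by banded gapped
extension around each seeded diagonal, so every reported score is a
lower bound on — and on high-identity pairs equal to — the exact score.
Raw scores are converted to bits and E-values with the Karlin-Altschul
formulae; the search space m*n uses unadjusted sequence lengths (no
BLAST length adjustment), so absolute E-values run slightly high but
cutoff behaviour is preserved.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

from ._kernels import sw_affine

log = logging.getLogger(__name__)

LN2 = math.log(2.0)

_B62 = substitution_matrices.load("BLOSUM62")
PROTEIN_ALPHABET = str(_B62.alphabet)  # 'ARNDCQEGHILKMFPSTWYVBZX*'
_B62_ARR = np.array(_B62, dtype=np.int32)

NT_ALPHABET = "ACGTN"


def _nt_matrix(match: int, mismatch: int) -> np.ndarray:
    m = np.full((5, 5), mismatch, dtype=np.int32)
    np.fill_diagonal(m, match)
    m[4, :] = mismatch  # N never matches
    m[:, 4] = mismatch
    return m


def karlin_lambda(match: int, mismatch: int, p: float = 0.25) -> float:
    """Ungapped Karlin-Altschul lambda for a match/mismatch scheme.

    Solves sum_ij p_i p_j exp(lambda * s_ij) = 1 for uniform base
    frequencies ``p``.
    """
    if match <= 0 or mismatch >= 0:
        raise ValueError("need match > 0 and mismatch < 0")

    def f(lam: float) -> float:
        return p * math.exp(lam * match) + (1 - p) * math.exp(lam * mismatch) - 1.0

    return brentq(f, 1e-6, 10.0)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution scores, affine gap penalties and KA parameters."""

    name: str
    alphabet: str
    matrix: np.ndarray
    gap_open: int
    gap_extend: int
    lam: float
    K: float

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if not (self.lam > 0 and self.K > 0 and math.isfinite(self.lam)):
            raise ValueError("lambda and K must be positive and finite")

    @classmethod
    def protein_default(cls) -> "ScoringScheme":
        # BLOSUM62 11/1 with the published gapped parameters
        return cls(
            name="blosum62-11-1",
            alphabet=PROTEIN_ALPHABET,
            matrix=_B62_ARR,
            gap_open=11,
            gap_extend=1,
            lam=0.267,
            K=0.041,
        )

    @classmethod
    def nucleotide_default(cls, match: int = 1, mismatch: int = -2) -> "ScoringScheme":
        # megablast-like +1/-2; published ungapped values lambda 1.28, K 0.46
        return cls(
            name=f"nt-{match}-{mismatch}",
            alphabet=NT_ALPHABET,
            matrix=_nt_matrix(match, mismatch),
            gap_open=0,
            gap_extend=0,
            lam=1.28,
            K=0.46,
        )

    def encode(self, seq: str) -> np.ndarray:
        lut = _encoder_for(self.alphabet)
        arr = lut[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
        return arr

    def self_score(self, seq: str) -> int:
        a = self.encode(seq)
        return int(self.matrix[a, a].sum())


_ENCODERS: dict[str, np.ndarray] = {}


def _encoder_for(alphabet: str) -> np.ndarray:
    lut = _ENCODERS.get(alphabet)
    if lut is None:
        # unknown characters map to the wildcard symbol (X or N)
        wildcard = alphabet.index("X") if "X" in alphabet else alphabet.index("N")
        lut = np.full(128, wildcard, dtype=np.uint8)
        for i, c in enumerate(alphabet):
            lut[ord(c)] = i
        _ENCODERS[alphabet] = lut
    return lut


@dataclass
class Hit:
    """One query-vs-subject local alignment."""

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    pct_identity: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    aln_len: int = 0


def bits_and_evalue(
    raw_score: int, s: ScoringScheme, m: int, n: int
) -> tuple[float, float]:
    """Karlin-Altschul normalised score and expectation.

    bits = (lambda * raw - ln K) / ln 2 ; E = m * n * 2**(-bits).
    """
    if m <= 0 or n <= 0:
        raise ValueError("search space dimensions must be positive")
    bits = (s.lam * raw_score - math.log(s.K)) / LN2
    evalue = float(m) * float(n) * math.pow(2.0, -bits)
    return bits, evalue


def smith_waterman(a: str, b: str, s: ScoringScheme | None = None) -> Hit:
    """Optimal local alignment of ``a`` (query) vs ``b`` (subject).

    Deterministic traceback (diagonal > up > left).  Empty input yields
    a zero-score hit with an empty span.
    """
    if s is None:
        s = ScoringScheme.protein_default()
    if len(a) == 0 or len(b) == 0:
        return Hit("query", "subject", 0, 0.0, math.inf, 0.0, 0, 0, 0, 0, 0)
    ea, eb = s.encode(a), s.encode(b)
    raw, qs, qe, ss, se, ident, alen = sw_affine(
        ea, eb, s.matrix, s.gap_open, s.gap_extend, -len(b), len(a)
    )
    bits, ev = bits_and_evalue(raw, s, len(a), len(b)) if raw else (0.0, math.inf)
    pid = 100.0 * ident / alen if alen else 0.0
    return Hit("query", "subject", int(raw), bits, ev, pid, qs, qe, ss, se, alen)


# ---------------------------------------------------------------------------
# seeded heuristic search


class OrfeomeIndex:
    """Exact k-mer index over one genome's ORFeome."""

    def __init__(
        self,
        orfeome: list[tuple[str, str]],
        scheme: ScoringScheme,
        word_len: int = 4,
    ) -> None:
        if word_len < 2:
            raise ValueError("word_len must be >= 2")
        self.word_len = word_len
        self.scheme = scheme
        self.tags = [t for t, _ in orfeome]
        self.seqs = [s for _, s in orfeome]
        self.encoded = [scheme.encode(s) for s in self.seqs]
        self.db_len = sum(len(s) for s in self.seqs)
        self.kmers: dict[str, list[tuple[int, int]]] = {}
        for idx, seq in enumerate(self.seqs):
            for pos in range(len(seq) - word_len + 1):
                self.kmers.setdefault(seq[pos : pos + word_len], []).append((idx, pos))


def seeded_search(
    query_tag: str,
    query: str,
    index: OrfeomeIndex,
    e_ceiling: float = 10.0,
    band: int = 40,
) -> list[Hit]:
    """Best gapped hit per subject ORF, k-mer seeded, banded extension.

    Subjects sharing no exact ``word_len``-mer with the query are never
    aligned.  Per subject, seed diagonals are clustered and a banded
    Smith-Waterman of half-width ``band`` is run around each cluster,
    keeping the best score; this is always <= the exact score and equal
    whenever the optimal alignment stays within the band of a seed.
    Hits are sorted by bit score descending, then subject tag.
    """
    s = index.scheme
    w = index.word_len
    if len(query) < w:
        log.warning("query %s shorter than word length %d", query_tag, w)
        return []
    diags: dict[int, set[int]] = {}
    for pos in range(len(query) - w + 1):
        for idx, spos in index.kmers.get(query[pos : pos + w], ()):
            diags.setdefault(idx, set()).add(pos - spos)
    eq = s.encode(query)
    m = len(query)
    hits: list[Hit] = []
    for idx, dset in diags.items():
        ds = sorted(dset)
        clusters: list[list[int]] = [[ds[0]]]
        for d in ds[1:]:
            if d - clusters[-1][-1] <= band:
                clusters[-1].append(d)
            else:
                clusters.append([d])
        best = None
        for cl in clusters:
            lo = cl[0] - band
            hi = cl[-1] + band
            res = sw_affine(
                eq, index.encoded[idx], s.matrix, s.gap_open, s.gap_extend, lo, hi
            )
            if best is None or res[0] > best[0]:
                best = res
        assert best is not None
        raw, qs, qe, ss, se, ident, alen = best
        if raw == 0:
            continue
        bits, ev = bits_and_evalue(raw, s, m, index.db_len)
        if ev > e_ceiling:
            continue
        pid = 100.0 * ident / alen if alen else 0.0
        hits.append(
            Hit(query_tag, index.tags[idx], int(raw), bits, ev, pid, qs, qe, ss, se, alen)
        )
    hits.sort(key=lambda h: (-h.bit_score, h.subject_id))
    return hits


# ---------------------------------------------------------------------------
# all-vs-all


@dataclass
class HitTable:
    """All-vs-all search result over a set of genomes.

    ``hits[(query_genome, subject_genome)]`` holds the best hit per
    (query ORF, subject ORF) pair that passed the recording ceiling;
    ``self_bits`` maps every ORF to the bit score of its self-alignment.
    """

    genome_ids: list[str]
    orfeomes: dict[str, list[tuple[str, str]]]
    hits: dict[tuple[str, str], list[Hit]] = field(default_factory=dict)
    self_bits: dict[str, float] = field(default_factory=dict)
    search_space: dict[tuple[str, str], int] = field(default_factory=dict)
    tag_genome: dict[str, str] = field(default_factory=dict)

    def tags(self, genome_id: str) -> list[str]:
        return [t for t, _ in self.orfeomes[genome_id]]

    def best_hits(self, query_tag: str, subject_genome: str) -> list[Hit]:
        qg = self.tag_genome[query_tag]
        return [
            h for h in self.hits.get((qg, subject_genome), []) if h.query_id == query_tag
        ]

    def best_bits(self, query_tag: str, subject_genome: str) -> float:
        hs = self.best_hits(query_tag, subject_genome)
        return max((h.bit_score for h in hs), default=0.0)

    def best_evalue(self, query_tag: str, subject_genome: str) -> float:
        hs = self.best_hits(query_tag, subject_genome)
        return min((h.evalue for h in hs), default=math.inf)

    # -- serialization (BLAST outfmt-6-style TSV + JSON sidecar) ----------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with (directory / "hits.tsv").open("w") as fh:
            for (qg, sg), hs in sorted(self.hits.items()):
                for h in hs:
                    mism = round(h.aln_len * (1 - h.pct_identity / 100.0))
                    fh.write(
                        f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.2f}\t"
                        f"{h.aln_len}\t{mism}\t0\t{h.q_start}\t{h.q_end}\t"
                        f"{h.s_start}\t{h.s_end}\t{h.evalue:.3e}\t{h.bit_score:.1f}\t"
                        f"{qg}\t{sg}\t{h.raw_score}\n"
                    )
        meta = {
            "genome_ids": self.genome_ids,
            "orfeomes": self.orfeomes,
            "self_bits": self.self_bits,
            "search_space": {f"{a}|{b}": v for (a, b), v in self.search_space.items()},
        }
        (directory / "table.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory: str | Path) -> "HitTable":
        directory = Path(directory)
        meta = json.loads((directory / "table.json").read_text())
        orfeomes = {g: [(t, s) for t, s in o] for g, o in meta["orfeomes"].items()}
        table = cls(
            genome_ids=meta["genome_ids"],
            orfeomes=orfeomes,
            self_bits=meta["self_bits"],
            search_space={
                tuple(k.split("|")): v for k, v in meta["search_space"].items()
            },
        )
        table.tag_genome = {
            t: g for g, orfeome in orfeomes.items() for t, _ in orfeome
        }
        with (directory / "hits.tsv").open() as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                h = Hit(
                    f[0], f[1], int(f[14]), float(f[11]), float(f[10]), float(f[2]),
                    int(f[6]), int(f[7]), int(f[8]), int(f[9]), int(f[3]),
                )
                table.hits.setdefault((f[12], f[13]), []).append(h)
        for pair in table.hits.values():
            pair.sort(key=lambda h: (-h.bit_score, h.query_id, h.subject_id))
        return table


def all_vs_all(
    orfeomes: dict[str, list[tuple[str, str]]],
    scheme: ScoringScheme | None = None,
    word_len: int = 4,
    band: int = 40,
    e_ceiling: float = 10.0,
) -> HitTable:
    """All-vs-all ORFeome search over every ordered genome pair.

    Locus tags must be unique across genomes (namespace them by genome
    when they are not).  Deterministic given inputs and parameters.
    """
    if len(orfeomes) < 2:
        raise ValueError("all_vs_all requires at least 2 genomes")
    if scheme is None:
        scheme = ScoringScheme.protein_default()
    tag_genome: dict[str, str] = {}
    for g, orfeome in orfeomes.items():
        for t, _ in orfeome:
            if t in tag_genome:
                raise ValueError(
                    f"duplicate locus_tag {t!r} in {g} and {tag_genome[t]}"
                )
            tag_genome[t] = g
    genome_ids = sorted(orfeomes)
    table = HitTable(genome_ids=genome_ids, orfeomes=orfeomes, tag_genome=tag_genome)
    for g, orfeome in orfeomes.items():
        for t, seq in orfeome:
            raw = scheme.self_score(seq)
            table.self_bits[t], _ = bits_and_evalue(raw, scheme, len(seq), len(seq))
    indexes = {
        g: OrfeomeIndex(orfeome, scheme, word_len) for g, orfeome in orfeomes.items()
    }
    for qg in genome_ids:
        for sg in genome_ids:
            if qg == sg:
                continue
            idx = indexes[sg]
            pair_hits: list[Hit] = []
            for t, seq in orfeomes[qg]:
                pair_hits.extend(seeded_search(t, seq, idx, e_ceiling, band))
            pair_hits.sort(key=lambda h: (-h.bit_score, h.query_id, h.subject_id))
            table.hits[(qg, sg)] = pair_hits
            table.search_space[(qg, sg)] = (
                sum(len(s) for _, s in orfeomes[qg]) * idx.db_len
            )
    return table
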