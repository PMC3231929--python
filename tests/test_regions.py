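"""Nucleotide comparison, specific regions, loci and transposase flags."""

from __future__ import annotations

import numpy as np
import pytest

from fgdpipe.genome_io import Feature, GenomeRecord
from fgdpipe.regions import (
    SpecificRegion,
    coverage_accounting,
    flag_transposase_flanks,
    map_orfs_and_loci,
    multi_query_specific,
    nucleotide_align,
    specific_regions,
)

WORD_LEN = 16


def _random_dna(n, rng):
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


def _rec(gid, seq, feats=None):
    return GenomeRecord(gid, gid, seq, feats or [])


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(2024)


class TestNucleotideAlign:
    def test_self_alignment_covers_genome(self, rng):
        seq = _random_dna(10_000, rng)
        blocks = nucleotide_align(_rec("r", seq), _rec("q", seq))
        acc = coverage_accounting(_rec("r", seq), blocks)
        assert acc["covered_bp"] >= 0.999 * len(seq)

    def test_planted_insert_splits_coverage(self, rng):
        base = _random_dna(12_000, rng)
        insert = _random_dna(500, rng)
        ref_seq = base[:4000] + insert + base[4000:]
        ref = _rec("r", ref_seq)
        blocks = nucleotide_align(ref, _rec("q", base))
        regs = specific_regions(ref, blocks, query_id="q")
        assert len(regs) == 1
        r = regs[0]
        assert abs(r.start - 4001) <= WORD_LEN
        assert abs(r.end - 4500) <= WORD_LEN

    def test_reverse_strand_detected(self, rng):
        seq = _random_dna(5_000, rng)
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        blocks = nucleotide_align(_rec("r", seq), _rec("q", rc))
        best = max(blocks, key=lambda b: b.score)
        assert best.strand == "-"
        assert best.ref_len >= 0.999 * len(seq)

    def test_unrelated_sequences_little_coverage(self, rng):
        a, b = _random_dna(10_000, rng), _random_dna(10_000, rng)
        blocks = nucleotide_align(_rec("r", a), _rec("q", b))
        covered = coverage_accounting(_rec("r", a), blocks)["covered_bp"]
        assert covered < 0.05 * len(a)

    def test_conservation_invariant(self, rng):
        """covered + specific + sub-threshold gaps == reference length."""
        base = _random_dna(8_000, rng)
        ref_seq = base[:2000] + _random_dna(300, rng) + base[2000:]
        ref = _rec("r", ref_seq)
        blocks = nucleotide_align(ref, _rec("q", base))
        acc = coverage_accounting(ref, blocks)
        assert (
            acc["covered_bp"] + acc["specific_bp"] + acc["subthreshold_gap_bp"]
            == acc["total_bp"]
        )

    def test_symmetric_insert_recovery(self, rng):
        """An insert in A is A-specific vs B; an insert in B is B-specific
        vs A — each direction of comparison recovers its own insert."""
        core = _random_dna(9_000, rng)
        ins_a, ins_b = _random_dna(400, rng), _random_dna(350, rng)
        a = _rec("A", core[:3000] + ins_a + core[3000:])
        b = _rec("B", core[:6000] + ins_b + core[6000:])
        regs_a = specific_regions(a, nucleotide_align(a, b), query_id="B")
        regs_b = specific_regions(b, nucleotide_align(b, a), query_id="A")
        assert len(regs_a) == 1 and abs(regs_a[0].length_bp - 400) <= 2 * WORD_LEN
        assert len(regs_b) == 1 and abs(regs_b[0].length_bp - 350) <= 2 * WORD_LEN


class TestSpecificRegions:
    def test_full_coverage_no_regions(self, rng):
        seq = _random_dna(5_000, rng)
        ref = _rec("r", seq)
        assert specific_regions(ref, nucleotide_align(ref, _rec("q", seq))) == []

    def test_strict_length_threshold(self):
        from fgdpipe.regions import AlignedBlock, _coverage_mask, _mask_to_regions

        # absent run of exactly 50 bp is NOT reported (> 50 required)
        mask = np.zeros(1000, dtype=bool)
        mask[100:150] = True  # 50-bp absent run
        mask[300:351] = True  # 51-bp absent run
        regs = _mask_to_regions(mask, "r", {"q"}, 50)
        assert [(r.start, r.end) for r in regs] == [(301, 351)]

    def test_no_merging_across_covered_gaps(self):
        from fgdpipe.regions import _mask_to_regions

        mask = np.zeros(1000, dtype=bool)
        mask[100:200] = True
        mask[205:305] = True  # separated by 5 covered bp
        regs = _mask_to_regions(mask, "r", {"q"}, 50)
        assert len(regs) == 2

    def test_multi_query_intersection(self, rng):
        core = _random_dna(10_000, rng)
        ins_both = _random_dna(400, rng)  # absent from B and C
        ins_b_only = _random_dna(300, rng)  # absent from B only
        ref_seq = core[:3000] + ins_both + core[3000:7000] + ins_b_only + core[7000:]
        ref = _rec("A", ref_seq)
        qb = _rec("B", core)
        qc = _rec("C", core[:7000] + ins_b_only + core[7000:])
        regs_b = specific_regions(ref, nucleotide_align(ref, qb), query_id="B")
        regs_c = specific_regions(ref, nucleotide_align(ref, qc), query_id="C")
        assert len(regs_b) == 2 and len(regs_c) == 1
        inter = multi_query_specific(ref, [regs_b, regs_c])
        assert len(inter) == 1
        assert abs(inter[0].start - 3001) <= WORD_LEN
        assert inter[0].absent_from == {"B", "C"}

    def test_single_query_identity(self, rng):
        regs = [SpecificRegion("r", 10, 100, {"q"})]
        out = multi_query_specific(_rec("r", "ACGT" * 100), [regs])
        assert out == regs

    def test_intersection_subset_of_inputs(self, rng):
        seq = _rec("r", _random_dna(2000, rng))
        r1 = [SpecificRegion("r", 101, 400, {"q1"})]
        r2 = [SpecificRegion("r", 301, 700, {"q2"})]
        inter = multi_query_specific(seq, [r1, r2])
        assert [(r.start, r.end) for r in inter] == [(301, 400)]


class TestOrfMapping:
    def _genome(self):
        feats = [
            Feature("CDS", "g1", 150, 249, "+"),  # fully inside region
            Feature("CDS", "g2", 360, 459, "+"),  # 40% overlap
            Feature("CDS", "g3", 2000, 2099, "+"),  # outside
        ]
        return GenomeRecord("G", "G", "ACGT" * 1000, feats)

    def test_overlap_threshold(self):
        g = self._genome()
        regions = [SpecificRegion("G", 100, 399, {"q"})]
        out = map_orfs_and_loci(regions, g, min_overlap_frac=0.5)
        assert out[0].orfs == ["g1"]
        out = map_orfs_and_loci(regions, g, min_overlap_frac=0.3)
        assert out[0].orfs == ["g1", "g2"]

    def test_locus_grouping_by_gap(self):
        g = GenomeRecord("G", "G", "ACGT" * 10_000)
        regions = [
            SpecificRegion("G", 1000, 1500, {"q"}),
            SpecificRegion("G", 2000, 2500, {"q"}),  # gap 499
            SpecificRegion("G", 9000, 9500, {"q"}),  # gap 6499
        ]
        out = map_orfs_and_loci(regions, g, locus_gap_bp=5000)
        assert [r.locus_id for r in out] == [1, 1, 2]
        out = map_orfs_and_loci(regions, g, locus_gap_bp=100)
        assert [r.locus_id for r in out] == [1, 2, 3]

    def test_planted_islands_map_to_three_loci(self, rng):
        feats = []
        for i, start in enumerate((1000, 20_000, 35_000)):
            for k in range(4):
                s = start + k * 500
                feats.append(Feature("CDS", f"isl{i}_{k}", s, s + 399, "+"))
        g = GenomeRecord("G", "G", "ACGT" * 10_000, feats)
        regions = [
            SpecificRegion("G", 1000, 2900, {"q"}),
            SpecificRegion("G", 20_000, 21_900, {"q"}),
            SpecificRegion("G", 35_000, 36_900, {"q"}),
        ]
        out = map_orfs_and_loci(regions, g, locus_gap_bp=5000)
        assert sum(len(r.orfs) for r in out) == 12
        assert sorted({r.locus_id for r in out}) == [1, 2, 3]


class TestTransposaseFlags:
    def _genome(self, products):
        feats = [
            Feature("CDS", f"t{i}", s, s + 99, "+", product=p)
            for i, (s, p) in enumerate(products)
        ]
        return GenomeRecord("G", "G", "ACGT" * 5000, feats)

    def test_no_transposases_all_false(self):
        g = self._genome([(100, "hypothetical protein")])
        regs = [SpecificRegion("G", 500, 1500, {"q"}, locus_id=1)]
        out = flag_transposase_flanks(regs, g)
        assert not out[0].transposase_flanked

    def test_flanking_transposases_flagged(self):
        g = self._genome(
            [(350, "IS1191 transposase"), (1600, "Transposase, truncated")]
        )
        regs = [SpecificRegion("G", 500, 1500, {"q"}, locus_id=1)]
        assert flag_transposase_flanks(regs, g, window_bp=200)[0].transposase_flanked

    def test_window_boundary_exclusive(self):
        # transposase spans 199..298; gap to the region start at 500 is 202
        g = self._genome([(199, "transposase")])
        regs = [SpecificRegion("G", 500, 1500, {"q"}, locus_id=1)]
        assert flag_transposase_flanks(regs, g, window_bp=202)[0].transposase_flanked
        assert not flag_transposase_flanks(regs, g, window_bp=201)[
            0
        ].transposase_flanked

    def test_pseudo_transposase_counts(self):
        g = GenomeRecord(
            "G", "G", "ACGT" * 5000,
            [Feature("pseudogene", "p1", 400, 480, "+",
                     product="transposase, truncated")],
        )
        regs = [SpecificRegion("G", 500, 1500, {"q"}, locus_id=1)]
        assert flag_transposase_flanks(regs, g, window_bp=100)[0].transposase_flanked


class TestEndToEndIslands:
    def test_planted_island_recovery(self, demo_sim, demo_genome_map):
        """>= 95% of each planted island recovered with boundary error
        <= the anchor word length, and flank flags exact per island."""
        _, _, _, truth = demo_sim
        for gid, islands in truth.island_table.items():
            if not islands:
                continue
            ref = demo_genome_map[gid]
            others = [demo_genome_map[q] for q in demo_genome_map if q != gid]
            per_query = [
                specific_regions(ref, nucleotide_align(ref, q), query_id=q.genome_id)
                for q in others
            ]
            inter = multi_query_specific(ref, per_query)
            inter = map_orfs_and_loci(inter, ref)
            inter = flag_transposase_flanks(inter, ref, level="region")
            for isl in islands:
                overlapping = [
                    r for r in inter if r.end >= isl.start and r.start <= isl.end
                ]
                recovered = sum(
                    min(r.end, isl.end) - max(r.start, isl.start) + 1
                    for r in overlapping
                )
                assert recovered >= 0.95 * (isl.end - isl.start + 1)
                best = max(overlapping, key=lambda r: r.length_bp)
                assert abs(best.start - isl.start) <= WORD_LEN
                assert abs(best.end - isl.end) <= WORD_LEN
                assert best.transposase_flanked == isl.flanked
                got_orfs = set().union(*(set(r.orfs) for r in overlapping))
                assert set(isl.member_tags) <= got_orfs
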