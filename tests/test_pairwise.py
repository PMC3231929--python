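"""Local alignment, E-value statistics and the seeded all-vs-all search."""

from __future__ import annotations

import math

import numpy as np
import pytest
from helpers import brute_force_local_score, protein_identity

from fgdpipe.pairwise import (
    OrfeomeIndex,
    ScoringScheme,
    all_vs_all,
    bits_and_evalue,
    karlin_lambda,
    seeded_search,
    smith_waterman,
)
from fgdpipe.simulate import evolve_protein, random_protein

AAS = "ARNDCQEGHILKMFPSTWYV"


@pytest.fixture(scope="module")
def scheme():
    return ScoringScheme.protein_default()


class TestSmithWaterman:
    def test_self_alignment_is_diagonal_sum(self, scheme):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        hit = smith_waterman(seq, seq, scheme)
        assert hit.raw_score == scheme.self_score(seq)
        assert hit.pct_identity == 100.0
        assert (hit.q_start, hit.q_end) == (1, len(seq))

    def test_classic_pair_matches_brute_force(self, scheme):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        expected = brute_force_local_score(a, b, scheme)
        assert smith_waterman(a, b, scheme).raw_score == expected

    def test_empty_sequence(self, scheme):
        hit = smith_waterman("MKL", "", scheme)
        assert hit.raw_score == 0
        assert (hit.q_start, hit.q_end, hit.s_start, hit.s_end) == (0, 0, 0, 0)

    def test_matches_brute_force_on_random_pairs(self, scheme):
        rng = np.random.default_rng(42)
        for _ in range(60):
            a = "".join(rng.choice(list(AAS), rng.integers(3, 30)))
            b = "".join(rng.choice(list(AAS), rng.integers(3, 30)))
            assert smith_waterman(a, b, scheme).raw_score == brute_force_local_score(
                a, b, scheme
            )

    def test_symmetric_in_arguments(self, scheme):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = "".join(rng.choice(list(AAS), 40))
            b = "".join(rng.choice(list(AAS), 35))
            assert (
                smith_waterman(a, b, scheme).raw_score
                == smith_waterman(b, a, scheme).raw_score
            )

    def test_gapped_alignment_found(self, scheme):
        # a 5-residue deletion: optimal alignment must open one gap
        a = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQ"
        b = a[:20] + a[25:]
        hit = smith_waterman(a, b, scheme)
        assert hit.raw_score == brute_force_local_score(a, b, scheme)
        assert hit.aln_len >= len(b)


class TestKarlinAltschul:
    def test_evalue_is_mn_at_zero_bits(self, scheme):
        # E = m*n*2^(-bits): at bits == 0 the expectation is exactly m*n
        for raw in (0, 50, 137):
            bits, ev = bits_and_evalue(raw, scheme, 100, 1000)
            assert ev == pytest.approx(100 * 1000 * 2.0 ** (-bits))

    def test_published_example_value(self, scheme):
        bits, _ = bits_and_evalue(100, scheme, 1, 1)
        assert bits == pytest.approx(43.13, abs=0.01)

    def test_search_space_linearity(self, scheme):
        _, e1 = bits_and_evalue(80, scheme, 100, 500)
        _, e2 = bits_and_evalue(80, scheme, 100, 1000)
        assert e2 == pytest.approx(2 * e1)

    def test_evalue_decreasing_in_score(self, scheme):
        evs = [bits_and_evalue(r, scheme, 100, 1000)[1] for r in range(0, 200, 10)]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_nucleotide_lambda_solver_matches_published(self):
        # +1/-3 ungapped: published lambda = 1.374
        lam = karlin_lambda(1, -3)
        assert lam == pytest.approx(1.374, abs=0.002)
        # defining identity: sum_ij p_i p_j exp(lambda s_ij) == 1
        ident = 0.25 * math.exp(lam * 1) + 0.75 * math.exp(lam * -3)
        assert ident == pytest.approx(1.0, abs=1e-9)

    def test_invalid_search_space(self, scheme):
        with pytest.raises(ValueError):
            bits_and_evalue(10, scheme, 0, 10)


class TestSeededSearch:
    def test_exact_match_recall(self, scheme):
        rng = np.random.default_rng(3)
        db = [(f"p{i}", random_protein(120, rng)) for i in range(20)]
        idx = OrfeomeIndex(db, scheme, word_len=4)
        tag, seq = db[7]
        hits = seeded_search("q", seq, idx)
        assert hits[0].subject_id == tag
        assert hits[0].raw_score == scheme.self_score(seq)

    def test_never_exceeds_exact_score(self, scheme):
        rng = np.random.default_rng(11)
        db = [(f"p{i}", random_protein(100, rng)) for i in range(10)]
        idx = OrfeomeIndex(db, scheme, word_len=4)
        for _ in range(15):
            anc = db[int(rng.integers(10))][1]
            q = evolve_protein(anc, 0.4, rng)
            for h in seeded_search("q", q, idx):
                exact = smith_waterman(q, dict(db)[h.subject_id], scheme).raw_score
                assert h.raw_score <= exact

    def test_equals_exact_on_strong_pairs(self, scheme):
        """Seeded score equals the exact score whenever the exact hit is
        strong (>= 50 bits), over a divergence sweep."""
        rng = np.random.default_rng(19)
        for _ in range(50):
            anc = random_protein(200, rng)
            q = evolve_protein(anc, float(rng.uniform(0.0, 0.8)), rng)
            idx = OrfeomeIndex([("s", anc)], scheme, word_len=4)
            exact = smith_waterman(q, anc, scheme)
            ebits, _ = bits_and_evalue(exact.raw_score, scheme, len(q), len(anc))
            if ebits < 50:
                continue
            hits = seeded_search("q", q, idx)
            assert hits and hits[0].raw_score == exact.raw_score

    def test_random_queries_rarely_hit(self, scheme):
        """Unrelated random queries score below the 1e-5 ceiling in
        >= 95% of trials (E-value calibration)."""
        rng = np.random.default_rng(23)
        db = [(f"p{i}", random_protein(150, rng)) for i in range(20)]
        idx = OrfeomeIndex(db, scheme, word_len=4)
        n_hit = sum(
            bool(seeded_search("q", random_protein(150, rng), idx, e_ceiling=1e-5))
            for _ in range(100)
        )
        assert n_hit <= 5

    def test_short_query_logged_empty(self, scheme):
        idx = OrfeomeIndex([("s", "MKLVVLGSDG")], scheme, word_len=4)
        assert seeded_search("q", "MK", idx) == []


class TestAllVsAll:
    def test_identical_genomes_cross_equals_self(self, scheme):
        rng = np.random.default_rng(5)
        prot = random_protein(150, rng)
        table = all_vs_all({"g1": [("g1_a", prot)], "g2": [("g2_a", prot)]}, scheme)
        assert table.best_bits("g1_a", "g2") == pytest.approx(
            table.self_bits["g1_a"]
        )

    def test_single_genome_rejected(self, scheme):
        with pytest.raises(ValueError):
            all_vs_all({"g1": [("a", "MKLV")]}, scheme)

    def test_duplicate_tags_rejected(self, scheme):
        with pytest.raises(ValueError, match="duplicate"):
            all_vs_all({"g1": [("a", "MKLV")], "g2": [("a", "MKLV")]}, scheme)

    def test_planted_orthologs_are_reciprocal_best_hits(self, demo_sim, demo_table):
        _, _, _, truth = demo_sim
        table = demo_table
        pseudo = set(truth.pseudo_list)
        checked = 0
        for fid in truth.families_of_kind("core"):
            members = truth.family_table[fid]
            for ga, ta in members.items():
                for gb, tb in members.items():
                    if ga >= gb or ta in pseudo or tb in pseudo:
                        continue
                    fwd = table.best_hits(ta, gb)
                    rev = table.best_hits(tb, ga)
                    assert fwd and fwd[0].subject_id == tb
                    assert rev and rev[0].subject_id == ta
                    checked += 1
        assert checked > 100

    def test_save_load_round_trip(self, tmp_path, scheme):
        rng = np.random.default_rng(9)
        orfeomes = {
            g: [(f"{g}_{i}", random_protein(80, rng)) for i in range(3)]
            for g in ("x", "y")
        }
        table = all_vs_all(orfeomes, scheme)
        table.save(tmp_path / "t")
        loaded = type(table).load(tmp_path / "t")
        assert loaded.genome_ids == table.genome_ids
        assert loaded.self_bits == pytest.approx(table.self_bits)
        for key, hits in table.hits.items():
            got = loaded.hits[key]
            assert [(h.query_id, h.subject_id, h.raw_score) for h in got] == [
                (h.query_id, h.subject_id, h.raw_score) for h in hits
            ]


class TestStatisticsProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        raw=st.integers(min_value=0, max_value=800),
        m=st.integers(min_value=1, max_value=10**6),
        n=st.integers(min_value=1, max_value=10**9),
    )
    @settings(derandomize=True, max_examples=60)
    def test_evalue_monotone_and_linear(self, raw, m, n):
        s = ScoringScheme.protein_default()
        bits, ev = bits_and_evalue(raw, s, m, n)
        bits2, ev2 = bits_and_evalue(raw + 1, s, m, n)
        assert bits2 > bits and ev2 < ev
        _, ev_double = bits_and_evalue(raw, s, m, 2 * n)
        assert ev_double == pytest.approx(2 * ev)

    @given(st.text(alphabet=AAS, min_size=1, max_size=25))
    @settings(derandomize=True, max_examples=40)
    def test_self_alignment_recovers_full_span(self, seq):
        s = ScoringScheme.protein_default()
        hit = smith_waterman(seq, seq, s)
        assert hit.raw_score == s.self_score(seq)
        assert hit.pct_identity == 100.0


class TestDivergenceSensitivity:
    def test_identity_tracks_divergence(self):
        rng = np.random.default_rng(31)
        anc = random_protein(300, rng)
        idents = [
            protein_identity(anc, evolve_protein(anc, t, rng))
            for t in (0.05, 0.3, 0.8)
        ]
        assert idents[0] > idents[1] > idents[2]
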