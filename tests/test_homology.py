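import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tctransfer.homology import (
    HitRecord,
    ScoringScheme,
    SearchContext,
    SearchParams,
    estimate_ungapped_lambda,
    karlin_altschul_evalue,
    needleman_wunsch,
    normalize_per_hit,
    normalize_per_residue,
    parse_alignment_tabular,
    parse_probabilistic_tabular,
    read_hits_tsv,
    search_all_vs_all,
    shuffle_pvalue,
    smith_waterman,
    write_hits_tsv,
)

from conftest import make_dataset
from oracles import brute_global, brute_local


class TestAlignmentScores:
    def test_identical_tryptophans_score_diagonal_sum(self, blosum):
        # BLOSUM62 W/W = 11
        score, intervals = smith_waterman("WWW", "WWW", blosum)
        assert score == 33
        assert intervals == ((0, 3), (0, 3))
        assert needleman_wunsch("WWW", "WWW", blosum) == 33

    def test_unrelated_single_residues_floor_at_zero(self, blosum):
        score, intervals = smith_waterman("W", "P", blosum)  # W/P = -4
        assert score == 0
        assert intervals == ((0, 0), (0, 0))

    def test_single_residue_global_score_is_matrix_entry(self, blosum):
        assert needleman_wunsch("W", "P", blosum) == -4

    def test_empty_sequence_rejected(self, blosum):
        with pytest.raises(ValueError):
            smith_waterman("", "WWW", blosum)
        with pytest.raises(ValueError):
            needleman_wunsch("A", "", blosum)

    def test_residue_outside_alphabet_rejected(self, tiny_scheme):
        with pytest.raises(ValueError, match="outside scoring alphabet"):
            smith_waterman("ACW", "ACD", tiny_scheme)

    def test_local_interval_covers_the_matching_block(self, blosum):
        score, ((a0, a1), (b0, b1)) = smith_waterman(
            "PPPPWWWWWPPPP", "GGWWWWWGG", blosum
        )
        assert score == 55
        assert (a1 - a0, b1 - b0) == (5, 5)
        assert "PPPPWWWWWPPPP"[a0:a1] == "WWWWW"
        assert "GGWWWWWGG"[b0:b1] == "WWWWW"

    @pytest.mark.parametrize("case", range(4))
    def test_gapped_alignment_matches_oracle_hand_case(self, tiny_scheme, case):
        pairs = [("ACDE", "ADE"), ("AACC", "ACAC"), ("EDCA", "ACDE"), ("AC", "CA")]
        a, b = pairs[case]
        enc = tiny_scheme.encode
        sub = tiny_scheme.matrix
        go, ge = tiny_scheme.gap_open, tiny_scheme.gap_extend
        assert needleman_wunsch(a, b, tiny_scheme) == brute_global(
            list(enc(a)), list(enc(b)), sub, go, ge
        )
        assert smith_waterman(a, b, tiny_scheme)[0] == brute_local(
            list(enc(a)), list(enc(b)), sub, go, ge
        )

    def test_both_dps_match_exhaustive_enumeration(self, tiny_scheme):
        """Oracle equivalence on >=200 random short pairs (lengths <= 6)."""
        rng = np.random.default_rng(1234)
        sub = tiny_scheme.matrix
        go, ge = tiny_scheme.gap_open, tiny_scheme.gap_extend
        letters = list(tiny_scheme.alphabet)
        for _ in range(200):
            la, lb = rng.integers(1, 7, size=2)
            a = "".join(rng.choice(letters, la))
            b = "".join(rng.choice(letters, lb))
            ia, ib = list(tiny_scheme.encode(a)), list(tiny_scheme.encode(b))
            assert needleman_wunsch(a, b, tiny_scheme) == brute_global(ia, ib, sub, go, ge)
            assert smith_waterman(a, b, tiny_scheme)[0] == brute_local(ia, ib, sub, go, ge)

    def test_agrees_with_biopython_pairwise_aligner(self, blosum):
        """Independent cross-check of both DPs against Bio.Align."""
        from Bio import Align

        rng = np.random.default_rng(7)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        for mode in ("local", "global"):
            aligner = Align.PairwiseAligner()
            aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
            aligner.open_gap_score = blosum.gap_open + blosum.gap_extend
            aligner.extend_gap_score = blosum.gap_extend
            aligner.mode = mode
            for _ in range(15):
                a = "".join(rng.choice(letters, rng.integers(10, 40)))
                b = "".join(rng.choice(letters, rng.integers(10, 40)))
                if mode == "local":
                    assert smith_waterman(a, b, blosum)[0] == aligner.score(a, b)
                else:
                    assert needleman_wunsch(a, b, blosum) == aligner.score(a, b)

    @given(st.integers(0, 500))
    def test_symmetry_and_local_dominates_global(self, seed):
        rng = np.random.default_rng(seed)
        scheme = _small_scheme()
        letters = list(scheme.alphabet)
        a = "".join(rng.choice(letters, rng.integers(1, 12)))
        b = "".join(rng.choice(letters, rng.integers(1, 12)))
        sab, _ = smith_waterman(a, b, scheme)
        sba, _ = smith_waterman(b, a, scheme)
        assert sab == sba
        assert sab >= max(0, needleman_wunsch(a, b, scheme))


def _small_scheme():
    matrix = np.full((4, 4), -2, dtype=np.int64)
    np.fill_diagonal(matrix, 4)
    return ScoringScheme(matrix=matrix, alphabet="ACDE", gap_open=-4,
                         gap_extend=-1, lam=0.5, K=0.1)


class TestKarlinAltschul:
    def test_worked_value(self, blosum):
        # K*m*n*exp(-lambda*S) = 0.041 * 100 * 1000 * exp(-0.267*50) ~ 6.53e-3
        ctx = SearchContext(db_residues=1000, db_sequences=10, query_length=100)
        e = karlin_altschul_evalue(50, ctx, blosum)
        assert e == pytest.approx(6.531e-3, rel=1e-3)

    def test_linear_in_database_size(self, blosum):
        small = SearchContext(db_residues=1000, db_sequences=10, query_length=100)
        big = SearchContext(db_residues=2000, db_sequences=10, query_length=100)
        assert karlin_altschul_evalue(30, big, blosum) == pytest.approx(
            2 * karlin_altschul_evalue(30, small, blosum)
        )

    def test_strictly_decreasing_in_score(self, blosum):
        ctx = SearchContext(db_residues=1000, db_sequences=10, query_length=100)
        evalues = [karlin_altschul_evalue(s, ctx, blosum) for s in range(0, 300, 10)]
        assert all(b < a for a, b in zip(evalues, evalues[1:]))
        assert evalues[-1] < 1e-25

    def test_negative_score_rejected(self, blosum):
        ctx = SearchContext(db_residues=1000, db_sequences=10, query_length=100)
        with pytest.raises(ValueError):
            karlin_altschul_evalue(-1, ctx, blosum)

    def test_context_validation(self):
        with pytest.raises(ValueError):
            SearchContext(db_residues=5, db_sequences=10, query_length=100)


class TestUngappedLambda:
    def test_match_mismatch_uniform_four_letters_gives_ln3(self):
        # (1/4)e^lam + (3/4)e^-lam = 1  =>  e^lam = 3
        matrix = np.where(np.eye(4, dtype=bool), 1, -1)
        lam = estimate_ungapped_lambda(matrix, np.full(4, 0.25))
        assert lam == pytest.approx(math.log(3), abs=1e-6)

    def test_scaling_matrix_by_two_halves_lambda(self):
        matrix = np.where(np.eye(4, dtype=bool), 1, -1)
        lam1 = estimate_ungapped_lambda(matrix, np.full(4, 0.25))
        lam2 = estimate_ungapped_lambda(2 * matrix, np.full(4, 0.25))
        assert lam2 == pytest.approx(lam1 / 2, rel=1e-6)

    def test_blosum62_has_positive_finite_lambda(self, blosum):
        lam = estimate_ungapped_lambda(blosum.matrix[:20, :20], np.full(20, 0.05))
        assert 0 < lam < 2

    def test_nonnegative_expected_score_rejected(self):
        with pytest.raises(ValueError, match="expected score"):
            estimate_ungapped_lambda(np.ones((4, 4)), np.full(4, 0.25))


class TestShufflePvalue:
    def test_related_pair_is_significant(self, blosum):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 120))
        p, z = shuffle_pvalue(seq, seq, blosum, n_shuffles=60, seed=1)
        assert p < 1e-6 and z > 5

    def test_deterministic_given_seed(self, blosum):
        a, b = "MKVLAWAGLVSTQWERTY", "GGHHPPLLIKNNMMQQRR"
        assert shuffle_pvalue(a, b, blosum, seed=4) == shuffle_pvalue(a, b, blosum, seed=4)

    def test_unrelated_pairs_have_uniformish_p(self, blosum):
        rng = np.random.default_rng(2)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        ps = []
        for seed in range(20):
            a = "".join(rng.choice(letters, 60))
            b = "".join(rng.choice(letters, 60))
            p, _ = shuffle_pvalue(a, b, blosum, n_shuffles=40, seed=seed)
            ps.append(p)
        assert 0.3 < np.mean(ps) < 0.7

    def test_degenerate_shuffle_distribution_warns(self, blosum):
        with pytest.warns(UserWarning, match="degenerate"):
            p, z = shuffle_pvalue("AAAA", "AAAA", blosum, n_shuffles=30, seed=0)
        assert p == 1.0

    def test_too_few_shuffles_rejected(self, blosum):
        with pytest.raises(ValueError):
            shuffle_pvalue("MKV", "MKV", blosum, n_shuffles=10)


class TestNormalization:
    def test_per_residue_worked_example(self):
        # E=1e-58 against a 23,567-residue dataset
        assert normalize_per_residue(1e-58, 23567) == pytest.approx(4.243e-63, rel=1e-3)

    def test_database_size_rescaling_connects_the_two_searches(self):
        # the same hit reported at 1e-58 (23,567 residues) and 1e-53
        # (3,877,139,759 residues): normalized values agree within 2x
        n_small = normalize_per_residue(1e-58, 23567)
        n_big = normalize_per_residue(1e-53, 3877139759)
        assert 0.5 < n_small / n_big < 2.0

    def test_per_residue_edge_cases(self):
        assert normalize_per_residue(0.0, 100) == 0.0
        with pytest.raises(ValueError):
            normalize_per_residue(1e-5, 0)

    def test_per_hit_rule(self):
        assert normalize_per_hit(1e-6, 10) == pytest.approx(1e-7)
        assert normalize_per_hit(3e-4, 1) == 3e-4
        values = [normalize_per_hit(1e-6, n) for n in (1, 2, 5, 10)]
        assert all(b < a for a, b in zip(values, values[1:]))
        with pytest.raises(ValueError, match="no hits"):
            normalize_per_hit(1e-6, 0)


class TestSearchAllVsAll:
    def _pair(self):
        rng = np.random.default_rng(8)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        target = "".join(rng.choice(letters, 300))
        queries = make_dataset("Ec", [("q1", target, "2.A.1", [])])
        reference = make_dataset("At", [
            ("t_same", target, "2.A.1", []),
            ("t_bg1", "".join(rng.choice(letters, 300)), "2.A.1", []),
            ("t_bg2", "".join(rng.choice(letters, 300)), "3.A.1", []),
        ])
        return queries, reference

    def test_hits_sorted_and_bounded_by_reference_size(self):
        queries, reference = self._pair()
        hits = search_all_vs_all(queries, reference)
        assert len(hits) <= 3
        keys = [(h.normalized_evalue, -h.raw_score, h.target_id) for h in hits]
        assert keys == sorted(keys)

    def test_identical_target_ranks_first(self):
        queries, reference = self._pair()
        hits = search_all_vs_all(queries, reference)
        assert hits[0].target_id == "t_same"
        assert hits[0].normalized_evalue < 1e-20

    def test_reference_order_does_not_change_results(self):
        queries, reference = self._pair()
        shuffled = make_dataset("At", [
            (r.id, r.sequence, r.tc_family, r.substrates)
            for r in reversed(reference.records)
        ])
        one = search_all_vs_all(queries, reference)
        two = search_all_vs_all(queries, shuffled)
        assert [(h.target_id, h.normalized_evalue) for h in one] == [
            (h.target_id, h.normalized_evalue) for h in two
        ]

    def test_normalized_ordering_equals_raw_ordering_within_context(self):
        queries, reference = self._pair()
        hits = search_all_vs_all(queries, reference)
        by_raw = sorted(hits, key=lambda h: h.raw_evalue)
        by_norm = sorted(hits, key=lambda h: h.normalized_evalue)
        assert [h.target_id for h in by_raw] == [h.target_id for h in by_norm]
        for h in hits:
            assert h.normalized_evalue <= h.raw_evalue

    def test_global_engine_applies_per_hit_normalization(self):
        queries, reference = self._pair()
        hits = search_all_vs_all(
            queries, reference, engine="builtin_global",
            params=SearchParams(report_ceiling=50.0, n_shuffles=30),
        )
        n = len([h for h in hits if h.query_id == "q1"])
        for h in hits:
            assert h.backend == "builtin_global"
            assert h.normalized_evalue == pytest.approx(h.raw_evalue / n)

    def test_empty_reference_rejected(self, blosum):
        queries, _ = self._pair()
        empty = make_dataset("At", [])
        with pytest.raises(ValueError, match="empty"):
            search_all_vs_all(queries, empty)

    def test_null_calibration_is_conservative(self, blosum):
        """For unrelated background pairs, P(raw E <= t) <= c*t at small t."""
        rng = np.random.default_rng(99)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        queries = make_dataset("Ec", [
            (f"q{i}", "".join(rng.choice(letters, 150)), "2.A.1", [])
            for i in range(15)
        ])
        reference = make_dataset("At", [
            (f"t{i}", "".join(rng.choice(letters, 150)), "2.A.1", [])
            for i in range(20)
        ])
        hits = search_all_vs_all(queries, reference)
        n_pairs = 15 * 20
        for t in (0.1, 0.01):
            frac = sum(1 for h in hits if h.raw_evalue <= t) / n_pairs
            assert frac <= 3 * t + 2 / n_pairs


class TestTabularParsers:
    def _row(self, q="q1", t="t1", e="1e-58", bits="210.5"):
        return "\t".join([q, t, "97.5", "300", "7", "0", "1", "300", "1", "300", e, bits])

    def test_alignment_row_normalized_per_residue(self, tmp_path):
        p = tmp_path / "hits.tab"
        p.write_text(self._row() + "\n")
        (hit,) = parse_alignment_tabular(p, db_residues=23567)
        assert hit.backend == "external_alignment"
        assert hit.normalized_evalue == pytest.approx(4.243e-63, rel=1e-3)
        assert hit.raw_score == 210.5

    def test_alignment_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "hits.tab"
        p.write_text("")
        assert parse_alignment_tabular(p, db_residues=100) == []

    @pytest.mark.parametrize(
        "content, match",
        [
            ("q1\tt1\tonly_three\n", "expected 12 columns"),
            (None, "line 1"),  # NA evalue, filled in below
        ],
    )
    def test_alignment_malformed_rows_report_line(self, tmp_path, content, match):
        p = tmp_path / "hits.tab"
        if content is None:
            content = self._row(e="NA") + "\n"
        p.write_text(content)
        with pytest.raises(ValueError, match=match):
            parse_alignment_tabular(p, db_residues=100)

    def test_probabilistic_comment_only_file_is_empty(self, tmp_path):
        p = tmp_path / "tbl.txt"
        p.write_text("# comment\n#\n")
        assert parse_probabilistic_tabular(p) == []

    def test_probabilistic_per_query_hit_counts(self, tmp_path):
        # two queries interleaved: q1 has 4 hits, q2 has 2
        lines = []
        for i in range(4):
            lines.append(f"t{i} - q1 - 1e-8 55.0 extra fields here")
            if i < 2:
                lines.append(f"s{i} - q2 - 1e-6 40.0 extra fields here")
        p = tmp_path / "tbl.txt"
        p.write_text("# header\n" + "\n".join(lines) + "\n")
        hits = parse_probabilistic_tabular(p)
        assert len(hits) == 6
        for h in hits:
            expected = 4 if h.query_id == "q1" else 2
            assert h.normalized_evalue == pytest.approx(h.raw_evalue / expected)
            assert h.backend == "external_probabilistic"


def test_hits_tsv_round_trip(tmp_path):
    hits = [
        HitRecord(query_id="q1", target_id="t1", raw_score=120.0,
                  raw_evalue=1e-30, normalized_evalue=1e-34, backend="builtin_local"),
        HitRecord(query_id="q2", target_id="t2", raw_score=80.0,
                  raw_evalue=2e-10, normalized_evalue=5e-14, backend="builtin_local"),
    ]
    path = tmp_path / "hits.tsv"
    write_hits_tsv(path, hits)
    assert read_hits_tsv(path) == hits
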