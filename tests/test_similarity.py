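"""Similarity engine: alignment scores, Karlin-Altschul statistics,
classification, NS counting, and BLAST tabular I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import DNA, simple_matrix, uniform_background
from oracles import bisect_lambda, brute_force_local_score
from targetprofiler.similarity import (
    AMINO_ACIDS,
    ROBINSON_FREQUENCIES,
    EvalueParams,
    SimilarityLevel,
    SimilarityThresholds,
    _score_distribution,
    best_hit_evalue,
    classify_similarity,
    count_similarity_proteins,
    evalue,
    karlin_k,
    read_blast_tabular,
    smith_waterman,
    solve_lambda,
    write_blast_tabular,
)


class TestSmithWaterman:
    def test_self_alignment_equals_diagonal_sum(self, blosum_params):
        seq = "MKTAYIAKQRQISFVK"
        pairs = blosum_params.pair_scores
        expected = sum(pairs[(c, c)] for c in seq)
        res = smith_waterman(seq, seq, blosum_params)
        assert res.score == expected

    def test_no_positive_pair_scores_zero(self, simple_params):
        res = smith_waterman("AAAA", "CCCC", simple_params)
        assert res.score == 0.0

    def test_empty_sequence_rejected(self, simple_params):
        with pytest.raises(ValueError):
            smith_waterman("", "ACGT", simple_params)

    def test_unknown_residue_strict_vs_lenient(self):
        strict = EvalueParams()
        with pytest.raises(ValueError, match="residue"):
            smith_waterman("MKTA", "MK1A", strict)
        lenient = EvalueParams(strict_residues=False)
        res = smith_waterman("MKTA", "MKOA", lenient)
        assert res.score >= 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_on_random_8mers(self, seed, simple_params):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list(DNA), size=8))
        b = "".join(rng.choice(list(DNA), size=8))
        expected = brute_force_local_score(
            a, b, simple_params.pair_scores,
            simple_params.gap_open, simple_params.gap_extend)
        assert smith_waterman(a, b, simple_params).score == expected

    def test_matches_biopython_on_proteins(self, blosum_params):
        """Cross-check against an independent mature implementation."""
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        # first gap residue costs open+extend, later residues extend
        aligner.open_gap_score = -(blosum_params.gap_open
                                   + blosum_params.gap_extend)
        aligner.extend_gap_score = -blosum_params.gap_extend
        rng = np.random.default_rng(42)
        for _ in range(20):
            a = "".join(rng.choice(list(AMINO_ACIDS), size=30))
            b = "".join(rng.choice(list(AMINO_ACIDS), size=30))
            assert smith_waterman(a, b, blosum_params).score == \
                pytest.approx(aligner.score(a, b))

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        a=st.text(alphabet=DNA, min_size=1, max_size=6),
        b=st.text(alphabet=DNA, min_size=1, max_size=6),
        gap_open=st.integers(0, 4),
        gap_extend=st.integers(1, 3),
    )
    def test_bruteforce_equality_property(self, a, b, gap_open, gap_extend):
        params = EvalueParams(
            matrix=simple_matrix(match=2, mismatch=-3),
            background=uniform_background(),
            gap_open=float(gap_open), gap_extend=float(gap_extend),
        )
        expected = brute_force_local_score(
            a, b, params.pair_scores, params.gap_open, params.gap_extend)
        assert smith_waterman(a, b, params).score == expected
        # symmetric matrix => symmetric score
        assert smith_waterman(b, a, params).score == expected


class TestKarlinAltschul:
    def test_lambda_ln3_for_plus1_minus1(self, simple_params):
        """+1/-1 over 4 uniform letters makes the root equation quadratic
        in e^lambda with solution e^lambda = 3."""
        lam = solve_lambda(simple_params.matrix, simple_params.background)
        assert lam == pytest.approx(math.log(3.0), rel=1e-10)

    def test_lambda_matches_bisection_for_2_minus3(self):
        matrix = simple_matrix(match=2, mismatch=-3)
        background = uniform_background()
        lam = solve_lambda(matrix, background)
        dist = _score_distribution(matrix, background)
        assert lam == pytest.approx(bisect_lambda(dist), abs=1e-10)

    def test_lambda_blosum62_matches_bisection(self, blosum_params):
        dist = _score_distribution(blosum_params.matrix, ROBINSON_FREQUENCIES)
        assert blosum_params.lambda_ == pytest.approx(
            bisect_lambda(dist), abs=1e-3)

    def test_all_positive_matrix_rejected(self):
        with pytest.raises(ValueError):
            solve_lambda(simple_matrix(match=1, mismatch=1),
                         uniform_background())

    def test_nonnegative_expected_score_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            solve_lambda(simple_matrix(match=3, mismatch=-1),
                         uniform_background())

    def test_k_reproduces_blast_ungapped_value(self, blosum_params):
        """BLOSUM62 with Robinson-Robinson frequencies has the standard
        ungapped parameters lambda = 0.3176, K = 0.134."""
        assert blosum_params.lambda_ == pytest.approx(0.3176, abs=5e-4)
        assert blosum_params.kappa == pytest.approx(0.134, abs=2e-3)


class TestEvalue:
    def test_zero_score_gives_kmn(self):
        params = EvalueParams()
        params._lambda, params._kappa = 0.318, 0.13
        assert evalue(0.0, 100, 200, params) == pytest.approx(0.13 * 100 * 200)

    def test_linear_in_subject_length(self):
        params = EvalueParams()
        params._lambda, params._kappa = 0.318, 0.13
        assert evalue(30, 100, 400, params) == pytest.approx(
            2 * evalue(30, 100, 200, params))

    def test_arithmetic_against_direct_evaluation(self):
        params = EvalueParams()
        params._lambda, params._kappa = 0.318, 0.13
        expected = 0.13 * 250 * 250 * math.exp(-0.318 * 50)
        assert evalue(50, 250, 250, params) == pytest.approx(expected, rel=1e-6)

    def test_strictly_decreasing_in_score(self, blosum_params):
        es = [evalue(s, 100, 100, blosum_params) for s in range(0, 100, 10)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_invalid_lengths(self, blosum_params):
        with pytest.raises(ValueError):
            evalue(10, 0, 100, blosum_params)


class TestClassification:
    @pytest.mark.parametrize("e,expected", [
        (1e-5, SimilarityLevel.VERY_SIMILAR),
        (1e-3, SimilarityLevel.VERY_SIMILAR),     # boundary inclusive
        (0.05, SimilarityLevel.MARGINALLY_SIMILAR),
        (0.1, SimilarityLevel.MARGINALLY_SIMILAR),  # boundary inclusive
        (0.5, SimilarityLevel.UNSIMILAR),
    ])
    def test_level_assignment(self, e, expected):
        assert classify_similarity(e) is expected

    def test_nonpositive_evalue_rejected(self):
        with pytest.raises(ValueError):
            classify_similarity(0.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-300, max_value=1e6))
    def test_partition_property(self, e):
        """Every positive E lands in exactly one class."""
        level = classify_similarity(e)
        assert level in set(SimilarityLevel)

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            SimilarityThresholds(very_similar_max=0.1, marginal_max=0.01)


class TestNSCount:
    @pytest.fixture()
    def three_families(self):
        from targetprofiler.synthetic import FamilySpec, generate_sequence_families

        spec = FamilySpec(n_families=3, members_per_family=3, seed_length=60,
                          within_family_identity=0.9, seed=7)
        return generate_sequence_families(spec)

    def test_own_family_only_gives_zero(self, three_families, blosum_params):
        sequences, family_map = three_families
        fam0 = {s: sequences[s] for s, f in family_map.items() if f == "FAM000"}
        ns = count_similarity_proteins(
            "FAM000_M00", fam0,
            {s: "FAM000" for s in fam0}, blosum_params)
        assert ns == 0

    def test_engineered_cross_family_homolog(self, three_families,
                                             blosum_params):
        """One cross-family copy of the target sequence is the only entry
        with E below the cutoff, confirmed by an independent all-pairs
        alignment oracle (Biopython)."""
        from Bio import Align
        from Bio.Align import substitution_matrices

        sequences, family_map = three_families
        target = "FAM000_M00"
        sequences = dict(sequences)
        family_map = dict(family_map)
        sequences["HOMOLOG"] = sequences[target]
        family_map["HOMOLOG"] = "FAM001"
        ns = count_similarity_proteins(target, sequences, family_map,
                                       blosum_params, ns_cutoff=1e-3)

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -12.0
        aligner.extend_gap_score = -1.0
        expected = 0
        for sid, seq in sequences.items():
            if sid == target or family_map[sid] == "FAM000":
                continue
            e = evalue(aligner.score(sequences[target], seq),
                       len(sequences[target]), len(seq), blosum_params)
            expected += e <= 1e-3
        assert ns == expected == 1

    def test_vanishing_cutoff_gives_zero(self, three_families, blosum_params):
        sequences, family_map = three_families
        ns = count_similarity_proteins("FAM000_M00", sequences, family_map,
                                       blosum_params, ns_cutoff=1e-300)
        assert ns == 0

    def test_monotone_in_cutoff_and_family_invariance(self, three_families,
                                                      blosum_params):
        sequences, family_map = three_families
        cutoffs = [1e-6, 1e-3, 1e-1, 10.0]
        counts = [count_similarity_proteins("FAM000_M00", sequences,
                                            family_map, blosum_params, c)
                  for c in cutoffs]
        assert counts == sorted(counts)
        # adding same-family sequences never changes NS
        augmented = dict(sequences)
        fam = dict(family_map)
        augmented["EXTRA"] = sequences["FAM000_M01"]
        fam["EXTRA"] = "FAM000"
        assert count_similarity_proteins(
            "FAM000_M00", augmented, fam, blosum_params, 10.0) == counts[-1]

    def test_missing_target_raises(self, three_families, blosum_params):
        sequences, family_map = three_families
        with pytest.raises(KeyError):
            count_similarity_proteins("NOPE", sequences, family_map,
                                      blosum_params)


class TestBlastTabular:
    GOOD = (
        "q1\ts1\t98.5\t100\t1\t0\t1\t100\t1\t100\t1e-50\t180.2\n"
        "q1\ts2\t50.0\t80\t40\t2\t1\t80\t5\t84\t0.002\t40.1\n"
        "q2\ts1\t30.0\t60\t42\t3\t1\t60\t1\t58\t1.5\t20.0\n"
    )

    def test_well_formed_rows(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self.GOOD)
        df = read_blast_tabular(p)
        assert len(df) == 3
        assert df.loc[1, "evalue"] == pytest.approx(0.002)

    def test_malformed_evalue_names_line(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self.GOOD.replace("1.5", "oops"))
        with pytest.raises(ValueError, match="line 3"):
            read_blast_tabular(p)

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\ts1\t98.5\n")
        with pytest.raises(ValueError, match="line 1"):
            read_blast_tabular(p)

    def test_round_trip(self, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        p1.write_text(self.GOOD)
        df = read_blast_tabular(p1)
        write_blast_tabular(df, p2)
        df2 = read_blast_tabular(p2)
        assert list(df2["qseqid"]) == list(df["qseqid"])
        assert list(df2["sseqid"]) == list(df["sseqid"])
        assert np.allclose(df2["evalue"], df["evalue"])


def test_best_hit_is_minimum_over_subjects(blosum_params):
    subjects = {"a": "MKTAYIAKQR", "b": "WWWWCCCWWW"}
    e = best_hit_evalue("MKTAYIAKQR", subjects, blosum_params)
    ea = smith_waterman("MKTAYIAKQR", subjects["a"], blosum_params).evalue
    assert e == ea
    with pytest.raises(ValueError):
        best_hit_evalue("MKTA", {}, blosum_params)
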