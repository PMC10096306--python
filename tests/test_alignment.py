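"""Smith-Waterman scoring against brute-force and third-party oracles."""

import itertools

import numpy as np
import pytest
from Bio import Align

from bicompdta.alignment import (
    ALPHABET,
    AlignmentScheme,
    AlphabetError,
    DegenerateSequenceError,
    MatrixKind,
    SimilarityMatrix,
    _sw_kernel_py,
    normalized_sw,
    sw_score,
    sw_similarity_matrix,
)
from bicompdta.records import ProteinRecord

from ._oracles import brute_sw


class TestSwScore:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("MKV", "MKV", 6.0),       # 3 matches x 2
            ("MKV", "WWW", 0.0),       # no positive-scoring local alignment
            ("MKVL", "MKV", 6.0),      # best local block ignores the overhang
        ],
    )
    def test_known_scores(self, a, b, expected, simple_scheme):
        assert sw_score(a, b, simple_scheme) == expected

    def test_symmetry(self, blosum_scheme, rng):
        aas = list(ALPHABET[:20])
        for _ in range(20):
            a = "".join(rng.choice(aas, size=rng.integers(3, 15)))
            b = "".join(rng.choice(aas, size=rng.integers(3, 15)))
            assert sw_score(a, b, blosum_scheme) == sw_score(b, a, blosum_scheme)

    def test_duplication_monotonicity(self, simple_scheme, rng):
        """Appending b to itself never lowers the local score against a."""
        aas = list("ACDE")
        for _ in range(20):
            a = "".join(rng.choice(aas, size=8))
            b = "".join(rng.choice(aas, size=5))
            assert sw_score(a, b + b, simple_scheme) >= sw_score(a, b, simple_scheme)

    def test_invalid_residue_raises(self, simple_scheme):
        with pytest.raises(AlphabetError):
            sw_score("MKB", "MKV", simple_scheme)

    def test_empty_sequence_raises(self, simple_scheme):
        with pytest.raises(ValueError):
            sw_score("", "MKV", simple_scheme)

    def test_matches_brute_force_exhaustive_short(self, simple_scheme):
        """DP equals exhaustive-recursion oracle on all short pairs (4-letter alphabet)."""
        seqs = ["".join(t) for n in (1, 2) for t in itertools.product("ACDE", repeat=n)]
        for a in seqs:
            for b in seqs:
                assert sw_score(a, b, simple_scheme) == brute_sw(a, b, simple_scheme)

    def test_matches_brute_force_random_longer(self, blosum_scheme, rng):
        aas = list("ACDE")
        for _ in range(60):
            a = "".join(rng.choice(aas, size=rng.integers(3, 7)))
            b = "".join(rng.choice(aas, size=rng.integers(3, 7)))
            assert sw_score(a, b, blosum_scheme) == pytest.approx(
                brute_sw(a, b, blosum_scheme), abs=1e-9
            )

    def test_matches_biopython_aligner(self, rng):
        """Cross-check against an independent third-party local aligner."""
        scheme = AlignmentScheme.blosum62(gap_open=10.0, gap_extend=0.5)
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        from Bio.Align import substitution_matrices
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        aas = list(ALPHABET[:20])
        for _ in range(25):
            a = "".join(rng.choice(aas, size=rng.integers(10, 40)))
            b = "".join(rng.choice(aas, size=rng.integers(10, 40)))
            assert sw_score(a, b, scheme) == pytest.approx(aligner.score(a, b))

    def test_numba_and_python_kernels_agree(self, blosum_scheme, rng):
        from bicompdta import alignment
        if alignment._sw_kernel_nb is None:
            pytest.skip("numba unavailable")
        aas = list(ALPHABET[:20])
        for _ in range(10):
            a = alignment.encode_sequence("".join(rng.choice(aas, size=30)))
            b = alignment.encode_sequence("".join(rng.choice(aas, size=25)))
            nb = alignment._sw_kernel_nb(a, b, blosum_scheme.matrix, 10.0, 0.5)
            py = _sw_kernel_py(a, b, blosum_scheme.matrix, 10.0, 0.5)
            assert nb == pytest.approx(py, abs=1e-9)


class TestNormalizedSw:
    def test_self_similarity_is_one(self, blosum_scheme):
        assert normalized_sw("MKVLHE", "MKVLHE", blosum_scheme) == 1.0

    def test_zero_numerator(self, simple_scheme):
        assert normalized_sw("MKV", "WWW", simple_scheme) == 0.0

    def test_geometric_mean_normalization(self, simple_scheme):
        # numerator 6, self-scores 8 and 6 under the +2 match scheme
        expected = 6.0 / np.sqrt(8.0 * 6.0)
        assert normalized_sw("MKVL", "MKV", simple_scheme) == pytest.approx(expected)

    def test_degenerate_self_score_raises(self, simple_scheme):
        with pytest.raises(DegenerateSequenceError):
            normalized_sw("X", "MKV", simple_scheme)


class TestSwMatrix:
    def test_identical_panel_all_ones(self, simple_scheme):
        panel = [ProteinRecord(f"p{i}", "MKVLHE") for i in range(3)]
        m = sw_similarity_matrix(panel, simple_scheme)
        assert np.allclose(m.values, 1.0)

    def test_postconditions_random_panel(self, blosum_scheme, rng):
        aas = list(ALPHABET[:20])
        panel = [
            ProteinRecord(f"p{i}", "".join(rng.choice(aas, size=30)))
            for i in range(10)
        ]
        m = sw_similarity_matrix(panel, blosum_scheme)
        assert np.allclose(m.values, m.values.T, atol=1e-9)
        assert np.array_equal(np.diag(m.values), np.ones(10))
        assert m.values.min() >= 0 and m.values.max() <= 1

    def test_matches_entrywise_calls(self, blosum_scheme, rng):
        aas = list(ALPHABET[:20])
        panel = [
            ProteinRecord(f"p{i}", "".join(rng.choice(aas, size=20)))
            for i in range(5)
        ]
        m = sw_similarity_matrix(panel, blosum_scheme)
        for i in range(5):
            for j in range(5):
                expected = normalized_sw(panel[i].sequence, panel[j].sequence, blosum_scheme)
                assert m.values[i, j] == expected

    def test_csv_roundtrip_bit_exact(self, simple_scheme, tmp_path, rng):
        aas = list("ACDE")
        panel = [
            ProteinRecord(f"p{i}", "".join(rng.choice(aas, size=12)))
            for i in range(4)
        ]
        m = sw_similarity_matrix(panel, simple_scheme)
        m.to_csv(tmp_path / "m.csv", tmp_path / "m.json")
        back = SimilarityMatrix.from_csv(tmp_path / "m.csv", tmp_path / "m.json")
        assert back.kind == MatrixKind.SW
        assert np.abs(back.values - m.values).max() < 1e-12
        assert back.ids == m.ids


class TestScheme:
    def test_blosum_symmetric_positive_diagonal(self, blosum_scheme):
        assert np.allclose(blosum_scheme.matrix, blosum_scheme.matrix.T)
        assert (np.diag(blosum_scheme.matrix)[:20] > 0).all()

    def test_x_is_neutral(self, blosum_scheme):
        assert blosum_scheme.score("X", "W") == 0.0
        assert blosum_scheme.score("X", "X") == 0.0

    def test_extend_larger_than_open_rejected(self):
        with pytest.raises(ValueError):
            AlignmentScheme.simple(gap_open=1.0, gap_extend=2.0)
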