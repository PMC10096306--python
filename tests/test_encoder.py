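"""Combined-similarity encoding and SMILES label encoding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bicompdta.alignment import MatrixKind, SimilarityMatrix, sw_similarity_matrix
from bicompdta.compression import ncd_similarity_matrix
from bicompdta.encoder import (
    BiCompProteinEncoder,
    EncoderConfig,
    SmilesLabelEncoder,
    SmilesVocab,
    build_vocab,
    combine_matrices,
    encode_ligand,
    encode_protein,
)
from bicompdta.records import ProteinRecord


def _pair(ids, sw_vals, ncd_vals):
    sw = SimilarityMatrix(ids=ids, values=np.array(sw_vals), kind=MatrixKind.SW)
    nc = SimilarityMatrix(ids=ids, values=np.array(ncd_vals), kind=MatrixKind.NCD_SIM)
    return sw, nc


class TestCombineMatrices:
    def test_hadamard_product(self):
        sw, nc = _pair(["a", "b"], [[1.0, 0.8], [0.8, 1.0]], [[0.9, 0.5], [0.5, 0.9]])
        out = combine_matrices(sw, nc, EncoderConfig(combiner="product"))
        assert out.kind == MatrixKind.BICOMP
        assert out.values[0, 1] == pytest.approx(0.4)
        assert out.values[0, 0] == 1.0  # diagonal forced

    def test_product_equals_hadamard_off_diagonal(self, rng):
        n = 6
        a = np.clip(rng.random((n, n)), 0, 1)
        a = (a + a.T) / 2
        b = np.clip(rng.random((n, n)), 0, 1)
        b = (b + b.T) / 2
        ids = [f"p{i}" for i in range(n)]
        sw, nc = _pair(ids, a, b)
        out = combine_matrices(sw, nc)
        off = ~np.eye(n, dtype=bool)
        assert np.array_equal(out.values[off], (a * b)[off])

    def test_product_bounded_by_entrywise_min(self, rng):
        n = 5
        a = (lambda m: (m + m.T) / 2)(rng.random((n, n)))
        b = (lambda m: (m + m.T) / 2)(rng.random((n, n)))
        ids = [f"p{i}" for i in range(n)]
        out = combine_matrices(*_pair(ids, a, b))
        off = ~np.eye(n, dtype=bool)
        assert (out.values[off] <= np.minimum(a, b)[off] + 1e-15).all()

    def test_weighted_sum_limits(self):
        sw, nc = _pair(["a", "b"], [[1.0, 0.8], [0.8, 1.0]], [[0.9, 0.5], [0.5, 0.9]])
        w1 = combine_matrices(sw, nc, EncoderConfig(combiner="weighted_sum", weight_w=1.0))
        assert w1.values[0, 1] == 0.8
        w0 = combine_matrices(sw, nc, EncoderConfig(combiner="weighted_sum", weight_w=0.0))
        assert w0.values[0, 1] == 0.5

    def test_single_channel_passthrough(self):
        sw, nc = _pair(["a", "b"], [[1.0, 0.8], [0.8, 1.0]], [[0.9, 0.5], [0.5, 0.9]])
        assert combine_matrices(sw, nc, EncoderConfig(combiner="sw_only")).values[0, 1] == 0.8
        assert combine_matrices(sw, nc, EncoderConfig(combiner="ncd_only")).values[0, 1] == 0.5

    def test_id_order_mismatch_rejected(self):
        sw, _ = _pair(["a", "b"], np.eye(2), np.eye(2))
        _, nc = _pair(["b", "a"], np.eye(2), np.eye(2))
        with pytest.raises(ValueError):
            combine_matrices(sw, nc)

    def test_weight_only_with_weighted_sum(self):
        with pytest.raises(ValueError):
            EncoderConfig(combiner="product", weight_w=0.5)
        with pytest.raises(ValueError):
            EncoderConfig(combiner="weighted_sum", weight_w=None)


@pytest.fixture(scope="module")
def fitted(family_panel):
    panel = family_panel[:7]
    return panel, BiCompProteinEncoder().fit(panel)


class TestProteinEncoder:
    def test_in_panel_protein_equals_matrix_row(self, fitted):
        panel, enc = fitted
        vec = enc.transform([panel[0]])[0]
        assert np.array_equal(vec, enc.matrix_.values[0])

    def test_vector_length_is_panel_size(self, fitted):
        panel, enc = fitted
        assert enc.transform([panel[3]]).shape == (1, 7)

    def test_unseen_clone_close_to_panel_row(self, fitted):
        panel, enc = fitted
        clone = ProteinRecord(id="clone", sequence=panel[3].sequence)
        vec = enc.transform([clone])[0]
        row = enc.matrix_.values[3]
        off = np.arange(7) != 3
        # off-diagonal entries match exactly; the self-entry differs only by
        # the forced unit diagonal vs the clone's true self-similarity
        assert np.allclose(vec[off], row[off], atol=1e-12)
        assert vec[3] > 0.9

    def test_functional_wrapper_matches(self, family_panel):
        panel = family_panel[:5]
        vec = encode_protein(panel[2], panel)
        enc = BiCompProteinEncoder().fit(panel)
        assert np.array_equal(vec, enc.transform([panel[2]])[0])

    def test_family_margin_for_combined_measure(self, family_panel):
        sw = sw_similarity_matrix(family_panel)
        nc = ncd_similarity_matrix(family_panel)
        combined = combine_matrices(sw, nc)
        fam = np.array([p.family for p in family_panel])
        same = (fam[:, None] == fam[None, :]) & ~np.eye(len(fam), dtype=bool)
        within = combined.values[same].mean()
        between = combined.values[fam[:, None] != fam[None, :]].mean()
        assert within - between > 0.05

    def test_sklearn_params_roundtrip(self):
        enc = BiCompProteinEncoder(combiner="weighted_sum", weight_w=0.7)
        params = enc.get_params()
        assert params["combiner"] == "weighted_sum"
        clone = BiCompProteinEncoder(**{k: params[k] for k in ("combiner", "weight_w")})
        assert clone.get_params()["weight_w"] == 0.7


class TestSmilesVocab:
    def test_first_appearance_order(self):
        assert build_vocab(["CCO"]).char_to_code == {"C": 1, "O": 2}
        assert build_vocab(["CN", "NC"]).char_to_code == {"C": 1, "N": 2}

    def test_deterministic(self):
        smiles = ["CC(=O)N", "c1ccccc1"]
        assert build_vocab(smiles).char_to_code == build_vocab(smiles).char_to_code

    def test_zero_code_reserved(self):
        with pytest.raises(ValueError):
            SmilesVocab(char_to_code={"C": 0})


class TestEncodeLigand:
    def test_padding(self):
        vocab = SmilesVocab(char_to_code={"C": 1, "O": 2})
        assert encode_ligand("CCO", vocab, max_len=5).tolist() == [1, 1, 2, 0, 0]

    def test_truncation(self):
        vocab = SmilesVocab(char_to_code={"C": 1, "O": 2})
        assert encode_ligand("CCO", vocab, max_len=2).tolist() == [1, 1]

    def test_unknown_character_reserved_code(self):
        vocab = SmilesVocab(char_to_code={"C": 1, "O": 2})
        out = encode_ligand("CS", vocab, max_len=3)
        assert out.tolist() == [1, 3, 0]  # 3 = unknown code (K+1)

    def test_empty_smiles_rejected(self):
        with pytest.raises(ValueError):
            encode_ligand("", SmilesVocab(char_to_code={"C": 1}), max_len=3)

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(st.text(alphabet="CNOSP=#()12c", min_size=1, max_size=60))
    def test_output_length_invariant(self, smiles):
        vocab = build_vocab(["CNOSP=#()12c"])
        assert encode_ligand(smiles, vocab, max_len=25).shape == (25,)

    def test_transformer_roundtrip(self):
        enc = SmilesLabelEncoder(max_len=10).fit(["CCO", "CN=O"])
        out = enc.transform(["CCO", "CN=O"])
        assert out.shape == (2, 10)
        assert (out[:, -1] == 0).all()
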