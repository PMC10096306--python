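"""Network construction, parameter counting, training and prediction."""

import numpy as np
import pytest

from bicompdta import nn
from bicompdta.model import (
    BiCompDTARegressor,
    DivergenceError,
    ModelConfig,
    build_model,
    conv1d_param_count,
    count_trainable_parameters,
    separable_conv1d_param_count,
)

SMALL = dict(
    n_filters=8, filter_length=3, embedding_dim=8,
    protein_fc_sizes=(16, 16, 8), predictor_fc_sizes=(16, 8, 4),
    dropout=0.0, learning_rate=1e-3, batch_size=16, epochs=3, seed=0,
)


def make_data(rng, n=64, n_panel=10, max_len=12, n_codes=6):
    P = rng.random((n, n_panel))
    D = rng.integers(1, n_codes, size=(n, max_len))
    y = P.sum(axis=1) + 0.1 * rng.normal(size=n)
    return (P, D), y


class TestBuild:
    def test_seeded_build_is_deterministic(self):
        a = BiCompDTARegressor(**SMALL).build(10, 8, 12)
        b = BiCompDTARegressor(**SMALL).build(10, 8, 12)
        assert a.initial_checksum() == b.initial_checksum()

    def test_drug_branch_output_shape(self, rng):
        est = BiCompDTARegressor(**SMALL).build(10, 8, 12)
        D = rng.integers(0, 8, size=(5, 12))
        h = D
        for layer in est.drug_layers_:
            h = layer.forward(h)
        assert h.shape == (5, SMALL["n_filters"])

    def test_fc_variant_has_no_convolutions(self):
        cfg = dict(SMALL, drug_branch="fc")
        est = BiCompDTARegressor(**cfg).build(10, 8, 12)
        assert not any(isinstance(l, (nn.Conv1D, nn.SeparableConv1D))
                       for l in est.drug_layers_)

    def test_too_short_smiles_for_conv_stack_rejected(self):
        with pytest.raises(ValueError):
            BiCompDTARegressor(**SMALL).build(10, 8, 4)

    def test_config_requires_three_fc_layers(self):
        with pytest.raises(ValueError):
            ModelConfig(protein_fc_sizes=(16, 16))

    def test_build_model_wrapper(self):
        cfg = ModelConfig(n_filters=8, filter_length=3, embedding_dim=8,
                          protein_fc_sizes=(16, 16, 8),
                          predictor_fc_sizes=(16, 8, 4), seed=1)
        est = build_model(cfg, n_panel=7, vocab_size=9, max_len=10)
        assert est.n_panel_ == 7 and est.n_codes_ == 9


class TestParameterCounts:
    def test_separable_closed_form_no_bias(self, rng):
        layer = nn.SeparableConv1D(32, 32, 8, np.random.default_rng(0), bias=False)
        assert layer.param_count() == 8 * 32 + 32 * 32 == 1280
        assert separable_conv1d_param_count(8, 32, 32, bias=False) == 1280

    def test_standard_conv_closed_form(self):
        layer = nn.Conv1D(32, 32, 8, np.random.default_rng(0))
        assert layer.param_count() == conv1d_param_count(8, 32, 32) == 8 * 32 * 32 + 32

    def test_separable_cheaper_than_standard(self):
        assert separable_conv1d_param_count(8, 32, 32, bias=False) == 1280
        assert conv1d_param_count(8, 32, 32, bias=False) == 8192
        for k in (4, 8, 16):
            for c in (16, 32, 128):
                assert separable_conv1d_param_count(k, c, c) < conv1d_param_count(k, c, c)

    def test_all_layer_closed_forms(self):
        rng = np.random.default_rng(0)
        assert nn.Dense(10, 7, rng).param_count() == 10 * 7 + 7
        assert nn.Embedding(9, 4, rng).param_count() == 36
        assert nn.GlobalMaxPool().param_count() == 0

    def test_total_count_monotone_in_filters(self):
        small = BiCompDTARegressor(**SMALL).build(10, 8, 12)
        wide = BiCompDTARegressor(**dict(SMALL, n_filters=16)).build(10, 8, 12)
        assert wide.count_parameters() > small.count_parameters()

    def test_separable_substitution_changes_only_drug_branch(self):
        """Swapping the final separable layer for a standard conv changes the
        total count by exactly the closed-form difference."""
        est = BiCompDTARegressor(**SMALL).build(10, 8, 12)
        k, c = SMALL["filter_length"], SMALL["n_filters"]
        sep = separable_conv1d_param_count(k, c, c)
        std = conv1d_param_count(k, c, c)
        standard_total = (
            est.count_parameters() - sep + std
        )
        # rebuild with a standard conv in the separable slot
        rng = np.random.default_rng(0)
        replacement = nn.Conv1D(c, c, k, rng)
        swapped = est.drug_branch_parameters() - sep + replacement.param_count()
        assert replacement.param_count() == std
        assert standard_total - est.count_parameters() == std - sep
        assert swapped - est.drug_branch_parameters() == std - sep

    def test_count_wrapper(self):
        est = BiCompDTARegressor(**SMALL).build(10, 8, 12)
        assert count_trainable_parameters(est) == est.count_parameters()


class TestGradients:
    def test_numerical_gradient_check(self):
        """Backprop gradients match central finite differences end-to-end."""
        rng = np.random.default_rng(31)
        est = BiCompDTARegressor(**SMALL).build(6, 7, 10)
        P = rng.random((4, 6))
        D = rng.integers(0, 7, size=(4, 10))
        y = rng.normal(size=4)

        def loss():
            pred = est._forward(P, D, train=False)
            return np.mean((pred - y) ** 2)

        pred = est._forward(P, D, train=False)
        est._backward(2 * (pred - y) / len(y))
        eps = 1e-6
        checked = 0
        for layer in est.layers_:
            for key, param in layer.params.items():
                flat = param.ravel()
                idx = rng.integers(0, flat.size, size=min(3, flat.size))
                for i in idx:
                    orig = flat[i]
                    flat[i] = orig + eps
                    up = loss()
                    flat[i] = orig - eps
                    down = loss()
                    flat[i] = orig
                    numeric = (up - down) / (2 * eps)
                    analytic = layer.grads[key].ravel()[i]
                    assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7)
                    checked += 1
        assert checked > 20


class TestTraining:
    def test_loss_decreases_on_learnable_data(self, rng):
        X, y = make_data(rng, n=128)
        est = BiCompDTARegressor(**dict(SMALL, epochs=10, validation_fraction=0.0))
        est.fit(X, y)
        assert est.history_[-1]["train_loss"] < est.history_[0]["train_loss"]

    def test_constant_labels_converge_to_constant(self, rng):
        X, _ = make_data(rng, n=96)
        y = np.full(96, 5.0)
        est = BiCompDTARegressor(**dict(SMALL, epochs=100, learning_rate=1e-2,
                                        patience=50, validation_fraction=0.1))
        est.fit(X, y)
        pred = est.predict(X)
        assert np.mean((pred - 5.0) ** 2) < 0.01

    def test_same_seed_identical_training(self, rng):
        X, y = make_data(rng, n=64)
        a = BiCompDTARegressor(**dict(SMALL, epochs=5, dropout=0.1)).fit(X, y)
        b = BiCompDTARegressor(**dict(SMALL, epochs=5, dropout=0.1)).fit(X, y)
        la = [h["val_loss"] for h in a.history_]
        lb = [h["val_loss"] for h in b.history_]
        assert la == pytest.approx(lb, abs=1e-6)

    def test_divergence_raises(self, rng):
        X, _ = make_data(rng, n=32)
        y = np.full(32, 1e200)  # squared error overflows to inf immediately
        est = BiCompDTARegressor(**dict(SMALL, validation_fraction=0.0))
        with pytest.raises(DivergenceError):
            est.fit(X, y)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(7)
    X, y = make_data(rng, n=64)
    est = BiCompDTARegressor(**SMALL).fit(X, y)
    return est, X


class TestPredict:
    def test_batch_permutation_equivariance(self, fitted, rng):
        est, (P, D) = fitted
        perm = rng.permutation(P.shape[0])
        assert np.allclose(est.predict((P, D))[perm], est.predict((P[perm], D[perm])))

    def test_duplicated_pair_duplicated_prediction(self, fitted):
        est, (P, D) = fitted
        P2 = np.vstack([P[:1], P[:1]])
        D2 = np.vstack([D[:1], D[:1]])
        out = est.predict((P2, D2))
        assert out[0] == out[1]

    def test_dim_mismatch_rejected(self, fitted, rng):
        est, (P, D) = fitted
        with pytest.raises(ValueError):
            est.predict((P[:, :-1], D))

    def test_save_load_roundtrip(self, fitted, tmp_path, rng):
        est, (P, D) = fitted
        est.save(tmp_path / "ckpt")
        back = BiCompDTARegressor.load(tmp_path / "ckpt")
        assert np.allclose(est.predict((P, D)), back.predict((P, D)), atol=1e-6)
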