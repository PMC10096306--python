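"""The two-branch affinity regressor.

Protein branch: the panel-similarity vector passes through a three-layer
fully-connected block (the encoding is already a learned-free global
representation; the FC block recovers task-relevant structure from it).

Drug branch: the label-encoded SMILES passes through an embedding, two
standard 1-D convolutions, one depthwise-separable convolution, and a
global max-pool.  The separable final layer keeps the representation
quality of a third convolution at a fraction of its parameters.

The branch outputs are concatenated and passed through a three-layer
fully-connected predictor with a scalar linear output, trained by Adam on
mean-squared error with early stopping on validation loss.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import nn


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass
class ModelConfig:
    """Hyperparameters of the two-branch network.

    ``protein_fc_sizes`` and ``predictor_fc_sizes`` must each have exactly
    three entries (three-layer fully-connected blocks).  ``drug_branch``
    is ``cnn_sep`` (embedding + 2 conv + separable conv + max-pool) or
    ``fc`` (embedding + flatten + dense; the convolution-free baseline).
    """

    n_filters: int = 32
    filter_length: int = 8
    embedding_dim: int = 128
    protein_fc_sizes: tuple[int, int, int] = (1024, 1024, 512)
    predictor_fc_sizes: tuple[int, int, int] = (1024, 1024, 512)
    dropout: float = 0.1
    learning_rate: float = 1e-3
    batch_size: int = 256
    epochs: int = 100
    seed: int = 0
    drug_branch: str = "cnn_sep"
    patience: int = 15
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if len(self.protein_fc_sizes) != 3 or len(self.predictor_fc_sizes) != 3:
            raise ValueError("fc-size lists must have exactly 3 entries")
        if self.drug_branch not in ("cnn_sep", "fc"):
            raise ValueError(f"unknown drug_branch {self.drug_branch!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def conv1d_param_count(kernel: int, c_in: int, c_out: int, bias: bool = True) -> int:
    """Closed-form parameter count of a standard 1-D convolution."""
    return kernel * c_in * c_out + (c_out if bias else 0)


def separable_conv1d_param_count(kernel: int, c_in: int, c_out: int, bias: bool = True) -> int:
    """Closed form for depthwise (k*Cin) + pointwise (Cin*Cout) filters."""
    return kernel * c_in + c_in * c_out + ((c_in + c_out) if bias else 0)


class BiCompDTARegressor(BaseEstimator, RegressorMixin):
    """Two-branch neural regressor over (protein vector, SMILES codes) pairs.

    ``X`` is a tuple ``(P, D)``: ``P`` an (n, panel_size) float matrix of
    panel similarities, ``D`` an (n, max_len) integer matrix of SMILES
    character codes (0 = padding).  ``y`` is the vector of log-scale
    affinities.

    Deterministic given ``seed`` (single-threaded NumPy): weight
    initialization, minibatch order, dropout masks and the validation
    split all derive from it.

    Attributes
    ----------
    layers_ : list
        All layers in forward order (protein branch, drug branch, head).
    history_ : list of dict
        Per-epoch train/validation loss.
    n_panel_, max_len_, n_codes_ : int
        Input dimensions the network was built for.
    """

    def __init__(self, n_filters=32, filter_length=8, embedding_dim=128,
                 protein_fc_sizes=(1024, 1024, 512),
                 predictor_fc_sizes=(1024, 1024, 512),
                 dropout=0.1, learning_rate=1e-3, batch_size=256, epochs=100,
                 seed=0, drug_branch="cnn_sep", patience=15,
                 validation_fraction=0.1, vocab_size=None, verbose=0):
        self.n_filters = n_filters
        self.filter_length = filter_length
        self.embedding_dim = embedding_dim
        self.protein_fc_sizes = protein_fc_sizes
        self.predictor_fc_sizes = predictor_fc_sizes
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed
        self.drug_branch = drug_branch
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.vocab_size = vocab_size
        self.verbose = verbose

    # ---------------------------------------------------------------- build
    def build(self, n_panel: int, n_codes: int, max_len: int) -> "BiCompDTARegressor":
        """Construct seeded initial weights for the given input dimensions."""
        cfg = ModelConfig(
            n_filters=self.n_filters, filter_length=self.filter_length,
            embedding_dim=self.embedding_dim,
            protein_fc_sizes=tuple(self.protein_fc_sizes),
            predictor_fc_sizes=tuple(self.predictor_fc_sizes),
            dropout=self.dropout, learning_rate=self.learning_rate,
            batch_size=self.batch_size, epochs=self.epochs, seed=self.seed,
            drug_branch=self.drug_branch, patience=self.patience,
            validation_fraction=self.validation_fraction,
        )
        if n_panel < 1 or n_codes < 2 or max_len < 1:
            raise ValueError("inconsistent input dimensions")
        if cfg.drug_branch == "cnn_sep" and max_len < 3 * (cfg.filter_length - 1) + 1:
            raise ValueError(
                f"max_len {max_len} too short for three valid convolutions "
                f"of length {cfg.filter_length}"
            )
        rng = np.random.default_rng(self.seed)
        self._dropout_rng = np.random.default_rng(self.seed + 1)

        f1, f2, f3 = cfg.protein_fc_sizes
        self.protein_layers_ = [
            nn.Dense(n_panel, f1, rng),
            nn.Dropout(cfg.dropout, self._dropout_rng),
            nn.Dense(f1, f2, rng),
            nn.Dropout(cfg.dropout, self._dropout_rng),
            nn.Dense(f2, f3, rng),
        ]
        if cfg.drug_branch == "cnn_sep":
            self.drug_layers_ = [
                nn.Embedding(n_codes, cfg.embedding_dim, rng),
                nn.Conv1D(cfg.embedding_dim, cfg.n_filters, cfg.filter_length, rng),
                nn.Conv1D(cfg.n_filters, cfg.n_filters, cfg.filter_length, rng),
                nn.SeparableConv1D(cfg.n_filters, cfg.n_filters, cfg.filter_length, rng),
                nn.GlobalMaxPool(),
            ]
            drug_out = cfg.n_filters
        else:
            self.drug_layers_ = [
                nn.Embedding(n_codes, cfg.embedding_dim, rng),
                nn.Flatten(),
                nn.Dense(max_len * cfg.embedding_dim, cfg.n_filters, rng),
            ]
            drug_out = cfg.n_filters
        g1, g2, g3 = cfg.predictor_fc_sizes
        self.head_layers_ = [
            nn.Dense(f3 + drug_out, g1, rng),
            nn.Dropout(cfg.dropout, self._dropout_rng),
            nn.Dense(g1, g2, rng),
            nn.Dropout(cfg.dropout, self._dropout_rng),
            nn.Dense(g2, g3, rng),
            nn.Dense(g3, 1, rng, activation="linear"),
        ]
        self.layers_ = self.protein_layers_ + self.drug_layers_ + self.head_layers_
        self.config_ = cfg
        self.n_panel_, self.n_codes_, self.max_len_ = n_panel, n_codes, max_len
        self.history_ = []
        return self

    # -------------------------------------------------------------- forward
    def _forward(self, P, D, train=False):
        hp = P
        for layer in self.protein_layers_:
            hp = layer.forward(hp, train=train)
        hd = D
        for layer in self.drug_layers_:
            hd = layer.forward(hd, train=train)
        h = np.concatenate([hp, hd], axis=1)
        self._split = hp.shape[1]
        for layer in self.head_layers_:
            h = layer.forward(h, train=train)
        return h[:, 0]

    def _backward(self, dpred):
        d = dpred[:, None]
        for layer in reversed(self.head_layers_):
            d = layer.backward(d)
        dp, dd = d[:, : self._split], d[:, self._split:]
        for layer in reversed(self.protein_layers_):
            dp = layer.backward(dp)
        for layer in reversed(self.drug_layers_):
            dd = layer.backward(dd)
            if dd is None:  # reached the embedding
                break

    @staticmethod
    def _as_xy(X):
        P, D = X
        P = np.asarray(P, dtype=float)
        D = np.asarray(D)
        if not np.issubdtype(D.dtype, np.integer):
            raise ValueError("drug codes must be integers")
        if P.ndim != 2 or D.ndim != 2 or P.shape[0] != D.shape[0]:
            raise ValueError("P and D must be 2-D with matching row counts")
        return P, D

    # ------------------------------------------------------------------ fit
    def fit(self, X, y, validation_data=None):
        P, D = self._as_xy(X)
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != P.shape[0]:
            raise ValueError("y length mismatch")
        if P.shape[0] == 0:
            raise ValueError("cannot fit on an empty training set")
        n_codes = self.vocab_size if self.vocab_size is not None else int(D.max()) + 2
        self.build(P.shape[1], n_codes, D.shape[1])

        rng = np.random.default_rng(self.seed + 2)
        if validation_data is not None:
            (Pv, Dv), yv = validation_data
            Pv, Dv = np.asarray(Pv, float), np.asarray(Dv)
            yv = np.asarray(yv, float).ravel()
            Pt, Dt, yt = P, D, y
        elif self.validation_fraction > 0 and P.shape[0] >= 10:
            n_val = max(1, int(round(self.validation_fraction * P.shape[0])))
            order = rng.permutation(P.shape[0])
            val_idx, tr_idx = order[:n_val], order[n_val:]
            Pt, Dt, yt = P[tr_idx], D[tr_idx], y[tr_idx]
            Pv, Dv, yv = P[val_idx], D[val_idx], y[val_idx]
        else:
            Pt, Dt, yt = P, D, y
            Pv = None

        opt = nn.Adam(self.layers_, lr=self.learning_rate)
        n = Pt.shape[0]
        best_val = np.inf
        best_params = None
        stale = 0
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                pred = self._forward(Pt[idx], Dt[idx], train=True)
                err = pred - yt[idx]
                with np.errstate(over="ignore"):  # overflow -> inf -> DivergenceError
                    loss = float(np.mean(err ** 2))
                if not np.isfinite(loss):
                    raise DivergenceError(
                        f"non-finite loss at epoch {epoch}: {loss!r}"
                    )
                losses.append(loss)
                self._backward(2.0 * err / len(idx))
                opt.step()
            train_loss = float(np.mean(losses))
            entry = {"epoch": epoch, "train_loss": train_loss, "val_loss": None}
            if Pv is not None and len(Pv):
                val_pred = self._predict_arrays(Pv, Dv)
                val_loss = float(np.mean((val_pred - yv) ** 2))
                entry["val_loss"] = val_loss
                if val_loss < best_val - 1e-12:
                    best_val = val_loss
                    best_params = [copy.deepcopy(l.params) for l in self.layers_]
                    stale = 0
                else:
                    stale += 1
            self.history_.append(entry)
            if self.verbose:
                print(f"epoch {epoch}: train {train_loss:.4f} val {entry['val_loss']}")
            if Pv is not None and stale > self.patience:
                break
        if best_params is not None:
            for layer, params in zip(self.layers_, best_params):
                layer.params = params
        return self

    # -------------------------------------------------------------- predict
    def _predict_arrays(self, P, D, batch=1024):
        out = np.empty(P.shape[0])
        for start in range(0, P.shape[0], batch):
            sl = slice(start, start + batch)
            out[sl] = self._forward(P[sl], D[sl], train=False)
        return out

    def predict(self, X) -> np.ndarray:
        P, D = self._as_xy(X)
        if P.shape[1] != self.n_panel_ or D.shape[1] != self.max_len_:
            raise ValueError(
                f"input dims ({P.shape[1]}, {D.shape[1]}) do not match the "
                f"fitted model ({self.n_panel_}, {self.max_len_})"
            )
        if D.max(initial=0) >= self.n_codes_:
            raise ValueError("drug code outside the embedding table")
        return self._predict_arrays(P, D)

    # ------------------------------------------------------------ accessors
    def count_parameters(self) -> int:
        return int(sum(l.param_count() for l in self.layers_))

    def drug_branch_parameters(self) -> int:
        return int(sum(l.param_count() for l in self.drug_layers_))

    def initial_checksum(self) -> float:
        return nn.checksum(self.layers_)

    # -------------------------------------------------------------- persist
    def save(self, directory) -> None:
        """Weights (npz) plus a self-describing JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, layer in enumerate(self.layers_):
            for k, v in layer.params.items():
                arrays[f"{i}:{k}"] = v
        np.savez(directory / "weights.npz", **arrays)
        manifest = {
            "config": asdict(self.config_),
            "n_panel": self.n_panel_, "n_codes": self.n_codes_,
            "max_len": self.max_len_,
            "history": self.history_,
        }
        with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "BiCompDTARegressor":
        directory = Path(directory)
        with open(directory / "manifest.json", encoding="utf-8") as fh:
            manifest = json.load(fh)
        cfg = manifest["config"]
        est = cls(
            n_filters=cfg["n_filters"], filter_length=cfg["filter_length"],
            embedding_dim=cfg["embedding_dim"],
            protein_fc_sizes=tuple(cfg["protein_fc_sizes"]),
            predictor_fc_sizes=tuple(cfg["predictor_fc_sizes"]),
            dropout=cfg["dropout"], learning_rate=cfg["learning_rate"],
            batch_size=cfg["batch_size"], epochs=cfg["epochs"],
            seed=cfg["seed"], drug_branch=cfg["drug_branch"],
            patience=cfg["patience"],
            validation_fraction=cfg["validation_fraction"],
        )
        est.build(manifest["n_panel"], manifest["n_codes"], manifest["max_len"])
        with np.load(directory / "weights.npz") as data:
            for key in data.files:
                i, name = key.split(":", 1)
                est.layers_[int(i)].params[name] = data[key]
        est.history_ = manifest["history"]
        return est


# ---------------------------------------------------------------- wrappers

def build_model(cfg: ModelConfig, n_panel: int, vocab_size: int, max_len: int) -> BiCompDTARegressor:
    """Construct an untrained, seeded model from a :class:`ModelConfig`."""
    est = BiCompDTARegressor(**asdict(cfg), vocab_size=vocab_size)
    return est.build(n_panel, vocab_size, max_len)


def count_trainable_parameters(model: BiCompDTARegressor) -> int:
    return model.count_parameters()


def train(model: BiCompDTARegressor, X_train, y_train, validation_data=None) -> BiCompDTARegressor:
    return model.fit(X_train, y_train, validation_data=validation_data)


def predict(model: BiCompDTARegressor, X) -> np.ndarray:
    return model.predict(X)
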