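"""Unified protein encoding (BiComp) and SMILES label encoding.

BiComp combines the alignment and compression similarities entrywise:

    BiComp(p_i, p_j) = S_SW(p_i, p_j) * S_NCD(p_i, p_j)

A protein is represented by its vector of combined similarities to a fixed
reference panel (the training proteins), so the feature dimension equals
the panel size and unseen proteins in cold settings are encoded without
touching test-set identities.

Ligands are character-level label encoded: each SMILES character gets a
positive integer code in first-appearance order over the training set,
sequences are truncated/zero-padded to a fixed maximum length, and unknown
characters at inference map to a reserved code.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .alignment import (
    AlignmentScheme,
    MatrixKind,
    SimilarityMatrix,
    normalized_sw,
    sw_similarity_matrix,
)
from .compression import (
    DEFAULT_CONFIG as DEFAULT_COMPRESSOR,
    CompressorConfig,
    ncd_similarity,
    ncd_similarity_matrix,
)
from .records import LigandRecord, ProteinRecord

logger = logging.getLogger(__name__)

COMBINERS = ("product", "sw_only", "ncd_only", "weighted_sum")

# conventional per-dataset-style SMILES length caps
MAX_LEN_PRESETS = {"davis": 85, "kiba": 100, "default": 200}


@dataclass(frozen=True)
class EncoderConfig:
    combiner: str = "product"
    weight_w: float | None = None

    def __post_init__(self) -> None:
        if self.combiner not in COMBINERS:
            raise ValueError(f"unknown combiner {self.combiner!r}")
        if self.combiner == "weighted_sum":
            if self.weight_w is None or not 0.0 <= self.weight_w <= 1.0:
                raise ValueError("weighted_sum requires weight_w in [0, 1]")
        elif self.weight_w is not None:
            raise ValueError("weight_w only valid for weighted_sum")


def combine_matrices(
    sw: SimilarityMatrix, ncd: SimilarityMatrix, cfg: EncoderConfig = EncoderConfig()
) -> SimilarityMatrix:
    """Merge the two similarity matrices into the combined encoding matrix.

    ``product`` is the Hadamard product (the default unified measure);
    ``weighted_sum`` computes w*SW + (1-w)*NCD; the ``*_only`` modes pass a
    single factor through (feature ablations).  Output is clamped to
    [0, 1] and the diagonal forced to 1 (a protein is maximally similar to
    itself in its own encoding, despite NCD self-overhead).
    """
    if list(sw.ids) != list(ncd.ids):
        raise ValueError("similarity matrices have mismatched id ordering")
    values = _combine_values(sw.values, ncd.values, cfg)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(
        ids=list(sw.ids), values=values, kind=MatrixKind.BICOMP,
        meta={"combiner": cfg.combiner, "weight_w": cfg.weight_w,
              "sw_meta": sw.meta, "ncd_meta": ncd.meta},
    )


def _combine_values(sw: np.ndarray, ncd: np.ndarray, cfg: EncoderConfig) -> np.ndarray:
    if cfg.combiner == "product":
        out = sw * ncd
    elif cfg.combiner == "weighted_sum":
        out = cfg.weight_w * sw + (1.0 - cfg.weight_w) * ncd
    elif cfg.combiner == "sw_only":
        out = sw.copy()
    else:
        out = ncd.copy()
    return np.clip(out, 0.0, 1.0)


class BiCompProteinEncoder(BaseEstimator, TransformerMixin):
    """Encode proteins as combined-similarity vectors against a panel.

    ``fit`` takes the training proteins (list of :class:`ProteinRecord`,
    or an object with a ``proteins`` attribute), computes the alignment
    and compression similarity matrices over that panel and combines them.
    ``transform`` maps proteins -- in-panel or unseen -- to vectors of
    combined similarity to each panel member.

    Parameters
    ----------
    combiner : {'product', 'sw_only', 'ncd_only', 'weighted_sum'}
        How the two similarity channels are merged.
    weight_w : float or None
        Weight on the alignment channel for ``weighted_sum``.
    scheme : AlignmentScheme or None
        Substitution/gap scheme; defaults to BLOSUM62 with open 10,
        extend 0.5.
    compressor : CompressorConfig
        Pinned LZMA settings.

    Attributes
    ----------
    panel_ : list of ProteinRecord
        The reference panel (training proteins).
    sw_matrix_, ncd_matrix_, matrix_ : SimilarityMatrix
        The two channel matrices and their combination over the panel.
    """

    def __init__(self, combiner="product", weight_w=None, scheme=None,
                 compressor=DEFAULT_COMPRESSOR):
        self.combiner = combiner
        self.weight_w = weight_w
        self.scheme = scheme
        self.compressor = compressor

    def _cfg(self) -> EncoderConfig:
        return EncoderConfig(combiner=self.combiner, weight_w=self.weight_w)

    def _scheme(self) -> AlignmentScheme:
        return self.scheme if self.scheme is not None else AlignmentScheme.blosum62()

    def fit(self, X, y=None):
        panel = list(getattr(X, "proteins", X))
        if not panel:
            raise ValueError("cannot fit on an empty protein panel")
        scheme = self._scheme()
        self.panel_ = panel
        self.sw_matrix_ = sw_similarity_matrix(panel, scheme)
        self.ncd_matrix_ = ncd_similarity_matrix(panel, self.compressor)
        self.matrix_ = combine_matrices(self.sw_matrix_, self.ncd_matrix_, self._cfg())
        self._row_of_ = {p.id: k for k, p in enumerate(panel)}
        self._seq_of_ = {p.id: p.sequence for p in panel}
        return self

    def transform(self, X) -> np.ndarray:
        """Vectors of combined similarity to the fitted panel, row per protein."""
        proteins = list(getattr(X, "proteins", X))
        out = np.empty((len(proteins), len(self.panel_)))
        for r, p in enumerate(proteins):
            known = self._row_of_.get(p.id)
            if known is not None and self._seq_of_[p.id] == p.sequence:
                out[r] = self.matrix_.values[known]
            else:
                out[r] = self._encode_unseen(p)
        return out

    def _encode_unseen(self, p: ProteinRecord) -> np.ndarray:
        scheme = self._scheme()
        cfg = self._cfg()
        sw_vec = np.array(
            [normalized_sw(p.sequence, q.sequence, scheme) for q in self.panel_]
        )
        ncd_vec = np.array(
            [ncd_similarity(p.sequence, q.sequence, self.compressor) for q in self.panel_]
        )
        return _combine_values(sw_vec[None, :], ncd_vec[None, :], cfg)[0]

    def get_feature_names_out(self, input_features=None):
        return np.array([f"sim_{p.id}" for p in self.panel_], dtype=object)


def encode_protein(p: ProteinRecord, panel, scheme=None,
                   cfg: EncoderConfig = EncoderConfig(),
                   compressor: CompressorConfig = DEFAULT_COMPRESSOR) -> np.ndarray:
    """One-shot functional form of :class:`BiCompProteinEncoder` for a protein."""
    enc = BiCompProteinEncoder(
        combiner=cfg.combiner, weight_w=cfg.weight_w, scheme=scheme, compressor=compressor
    ).fit(panel)
    return enc.transform([p])[0]


@dataclass(frozen=True)
class SmilesVocab:
    """Character -> positive code map; 0 is padding, max+1 is 'unknown'."""

    char_to_code: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        codes = list(self.char_to_code.values())
        if 0 in codes:
            raise ValueError("code 0 is reserved for padding")
        if len(set(codes)) != len(codes):
            raise ValueError("vocabulary codes must be injective")

    @property
    def unknown_code(self) -> int:
        return len(self.char_to_code) + 1

    def __len__(self) -> int:
        return len(self.char_to_code)

    @property
    def n_codes(self) -> int:
        """Total distinct codes including padding and unknown."""
        return len(self.char_to_code) + 2

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.char_to_code, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SmilesVocab":
        with open(path, encoding="utf-8") as fh:
            return cls(char_to_code=json.load(fh))


def build_vocab(smiles_list) -> SmilesVocab:
    """Assign codes 1..K in first-appearance order over the training SMILES."""
    if not smiles_list:
        raise ValueError("cannot build a vocabulary from an empty list")
    mapping: dict[str, int] = {}
    for s in smiles_list:
        s = s.smiles if isinstance(s, LigandRecord) else s
        for ch in s:
            if ch not in mapping:
                mapping[ch] = len(mapping) + 1
    return SmilesVocab(char_to_code=mapping)


def encode_ligand(l, vocab: SmilesVocab, max_len: int) -> np.ndarray:
    """Fixed-length integer encoding: truncate at ``max_len``, zero-pad."""
    if max_len < 1:
        raise ValueError("max_len must be positive")
    smiles = l.smiles if isinstance(l, LigandRecord) else l
    if not smiles:
        raise ValueError("empty SMILES string")
    codes = np.zeros(max_len, dtype=np.int64)
    unknown = 0
    for k, ch in enumerate(smiles[:max_len]):
        code = vocab.char_to_code.get(ch)
        if code is None:
            code = vocab.unknown_code
            unknown += 1
        codes[k] = code
    if unknown:
        logger.warning("%d unknown SMILES character(s) mapped to reserved code", unknown)
    return codes


class SmilesLabelEncoder(BaseEstimator, TransformerMixin):
    """Character-level label encoder over SMILES strings.

    ``fit`` builds the vocabulary from the training ligands; ``transform``
    emits an (n, max_len) integer matrix.  ``max_len=None`` uses the
    longest training SMILES (capped at the 'default' preset of 200).
    """

    def __init__(self, max_len=None):
        self.max_len = max_len

    def fit(self, X, y=None):
        ligands = list(getattr(X, "ligands", X))
        self.vocab_ = build_vocab(ligands)
        if self.max_len is None:
            longest = max(
                len(l.smiles if isinstance(l, LigandRecord) else l) for l in ligands
            )
            self.max_len_ = min(longest, MAX_LEN_PRESETS["default"])
        else:
            self.max_len_ = int(self.max_len)
        return self

    def transform(self, X) -> np.ndarray:
        ligands = list(getattr(X, "ligands", X))
        return np.stack([encode_ligand(l, self.vocab_, self.max_len_) for l in ligands])
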