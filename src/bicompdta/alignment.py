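"""Smith-Waterman local alignment and the normalized similarity matrix.

The alignment half of the unified protein encoding: raw local-alignment
scores SW(a, b) under an affine-gap scheme, normalized to

    S_SW(a, b) = SW(a, b) / sqrt(SW(a, a) * SW(b, b))

so that self-similarity is exactly 1 and all entries live in [0, 1].

Gap convention: a gap of length L costs ``gap_open + (L - 1) * gap_extend``
(the first gap column pays the opening penalty), matching the open/extend
semantics of common aligners.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_CODE = {aa: i for i, aa in enumerate(ALPHABET)}


class AlphabetError(ValueError):
    """Sequence contains residues outside the supported alphabet."""


class DegenerateSequenceError(ValueError):
    """Sequence whose self-alignment score is zero cannot be normalized."""


class MatrixKind(str, Enum):
    SW = "SW"
    NCD_SIM = "NCD_SIM"
    BICOMP = "BICOMP"


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over an ordered protein panel."""

    ids: list[str]
    values: np.ndarray
    kind: MatrixKind
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} vs {n} ids")
        self.kind = MatrixKind(self.kind)

    def row(self, protein_id: str) -> np.ndarray:
        return self.values[self.ids.index(protein_id)]

    def to_csv(self, csv_path, sidecar_path=None) -> None:
        """CSV with id header row/column; optional JSON sidecar of metadata."""
        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        # repr-precision floats so the round-trip is bit-exact
        df.to_csv(csv_path, float_format="%.17g")
        if sidecar_path is not None:
            with open(sidecar_path, "w", encoding="utf-8") as fh:
                json.dump({"kind": self.kind.value, "meta": self.meta}, fh, indent=1)

    @classmethod
    def from_csv(cls, csv_path, sidecar_path=None, kind=None) -> "SimilarityMatrix":
        df = pd.read_csv(csv_path, index_col=0)
        meta: dict = {}
        if sidecar_path is not None:
            with open(sidecar_path, encoding="utf-8") as fh:
                payload = json.load(fh)
            kind = kind or payload["kind"]
            meta = payload.get("meta", {})
        if kind is None:
            raise ValueError("kind required when no sidecar is given")
        return cls(ids=[str(i) for i in df.index], values=df.to_numpy(), kind=kind, meta=meta)


@dataclass(frozen=True)
class AlignmentScheme:
    """Substitution scores plus affine gap penalties.

    ``matrix`` is indexed by :data:`ALPHABET` codes.  Must be symmetric with
    positive self-scores for the 20 standard residues; 'X' scores 0 against
    everything (neutral wildcard).  ``gap_open`` and ``gap_extend`` are
    nonnegative penalties with ``gap_extend <= gap_open``.
    """

    matrix: np.ndarray
    gap_open: float
    gap_extend: float
    name: str = "custom"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (len(ALPHABET), len(ALPHABET)):
            raise ValueError(f"substitution matrix must be {len(ALPHABET)}x{len(ALPHABET)}")
        if not np.allclose(m, m.T):
            raise ValueError("substitution matrix must be symmetric")
        if np.any(np.diag(m)[:20] <= 0):
            raise ValueError("standard residues need positive self-scores")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be nonnegative")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[_CODE[a], _CODE[b]])

    @classmethod
    def blosum62(cls, gap_open: float = 10.0, gap_extend: float = 0.5) -> "AlignmentScheme":
        """BLOSUM62 with EMBOSS-water-like gap penalties (default scheme)."""
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        m = np.zeros((len(ALPHABET), len(ALPHABET)))
        for i, a in enumerate(ALPHABET[:20]):
            for j, b in enumerate(ALPHABET[:20]):
                m[i, j] = blosum[a][b]
        # 'X' row/column forced to 0: neutral, never blows up on real data
        return cls(matrix=m, gap_open=gap_open, gap_extend=gap_extend, name="BLOSUM62")

    @classmethod
    def simple(
        cls, match: float = 2.0, mismatch: float = -1.0,
        gap_open: float = 1.0, gap_extend: float = 1.0,
    ) -> "AlignmentScheme":
        """Flat match/mismatch scheme, mostly for tests and small examples."""
        m = np.full((len(ALPHABET), len(ALPHABET)), mismatch, dtype=float)
        np.fill_diagonal(m, match)
        m[_CODE["X"], :] = 0.0
        m[:, _CODE["X"]] = 0.0
        return cls(matrix=m, gap_open=gap_open, gap_extend=gap_extend, name="simple")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
            "alphabet": ALPHABET,
        }


def encode_sequence(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise AlphabetError(f"invalid residue {exc.args[0]!r} in sequence") from exc


def _sw_kernel_py(a, b, sub, gap_open, gap_extend):
    n, m = len(a), len(b)
    h_prev = np.zeros(m + 1)
    f_prev = np.full(m + 1, -np.inf)
    best = 0.0
    for i in range(1, n + 1):
        h_cur = np.zeros(m + 1)
        f_cur = np.empty(m + 1)
        f_cur[0] = -np.inf
        e = -np.inf
        for j in range(1, m + 1):
            e = max(h_cur[j - 1] - gap_open, e - gap_extend)
            f_cur[j] = max(h_prev[j] - gap_open, f_prev[j] - gap_extend)
            diag = h_prev[j - 1] + sub[a[i - 1], b[j - 1]]
            h = max(0.0, diag, e, f_cur[j])
            h_cur[j] = h
            if h > best:
                best = h
        h_prev, f_prev = h_cur, f_cur
    return best


try:  # numba gives ~100x on long panels; the pure-Python path is the reference
    from numba import njit

    _sw_kernel_nb = njit(cache=False)(_sw_kernel_py)
except Exception:  # pragma: no cover
    _sw_kernel_nb = None


def sw_score(a: str, b: str, scheme: AlignmentScheme | None = None) -> float:
    """Raw Smith-Waterman local-alignment score (affine gaps, floor 0)."""
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    if scheme is None:
        scheme = AlignmentScheme.blosum62()
    ca, cb = encode_sequence(a), encode_sequence(b)
    kernel = _sw_kernel_nb if _sw_kernel_nb is not None else _sw_kernel_py
    return float(kernel(ca, cb, scheme.matrix, float(scheme.gap_open), float(scheme.gap_extend)))


def normalized_sw(a: str, b: str, scheme: AlignmentScheme | None = None) -> float:
    """Geometric-mean-normalized SW similarity in [0, 1]; 1 for a == b."""
    if scheme is None:
        scheme = AlignmentScheme.blosum62()
    saa = sw_score(a, a, scheme)
    sbb = sw_score(b, b, scheme)
    if saa <= 0 or sbb <= 0:
        raise DegenerateSequenceError("zero self-alignment score")
    value = sw_score(a, b, scheme) / np.sqrt(saa * sbb)
    return float(min(1.0, max(0.0, value)))


def sw_similarity_matrix(panel, scheme: AlignmentScheme | None = None) -> SimilarityMatrix:
    """Normalized-SW similarity matrix over a protein panel.

    Computes self-scores once, then the upper triangle, and mirrors; the
    diagonal is exactly 1 by construction.
    """
    if not panel:
        raise ValueError("panel must be nonempty")
    if scheme is None:
        scheme = AlignmentScheme.blosum62()
    ids = [p.id for p in panel]
    if len(set(ids)) != len(ids):
        raise ValueError("panel ids must be unique")
    seqs = [p.sequence for p in panel]
    n = len(seqs)
    self_scores = np.array([sw_score(s, s, scheme) for s in seqs])
    if np.any(self_scores <= 0):
        raise DegenerateSequenceError("zero self-alignment score in panel")
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            raw = sw_score(seqs[i], seqs[j], scheme)
            v = raw / np.sqrt(self_scores[i] * self_scores[j])
            values[i, j] = values[j, i] = min(1.0, max(0.0, v))
    return SimilarityMatrix(ids=ids, values=values, kind=MatrixKind.SW, meta={"scheme": scheme.to_dict()})
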