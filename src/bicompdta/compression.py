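"""Compression-based protein similarity: LZMA lengths, NCD, S_NCD.

The compression half of the unified encoding uses the normalized
compression distance

    NCD(a, b) = (C(ab) - min{C(a), C(b)}) / max{C(a), C(b)}

with C(.) the LZMA-compressed length in bytes of the raw residue string
(no headers, no newlines), an alignment-free proxy for shared information
content.  The similarity is S_NCD = 1 - NCD, symmetrized over the two
concatenation orders and clamped into [0, 1].

NCD is near 0 for near-identical long strings and near 1 (sometimes
slightly above, due to compressor overhead) for unrelated random strings.
"""

from __future__ import annotations

import logging
import lzma
from dataclasses import dataclass

import numpy as np

from .alignment import MatrixKind, SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompressorConfig:
    """Pinned LZMA settings so compressed lengths are reproducible.

    ``stream_mode='raw'`` (default) strips container/header bytes, which
    matter for short proteins; ``'container'`` uses the .xz framing.
    """

    level: int = 9
    stream_mode: str = "raw"
    algorithm: str = "LZMA"
    #: explicit dictionary size; for inputs below this the compressed output
    #: is identical to the full preset while avoiding the preset's large
    #: per-call dictionary allocation
    dict_size: int = 1 << 20

    def __post_init__(self) -> None:
        if not 0 <= self.level <= 9:
            raise ValueError("LZMA preset level must be in 0..9")
        if self.stream_mode not in ("raw", "container"):
            raise ValueError(f"unknown stream_mode {self.stream_mode!r}")
        if self.algorithm != "LZMA":
            raise ValueError("only LZMA is supported")
        if self.dict_size < 1 << 12:
            raise ValueError("dict_size must be at least 4 KiB")

    def to_dict(self) -> dict:
        return {"algorithm": self.algorithm, "level": self.level,
                "stream_mode": self.stream_mode, "dict_size": self.dict_size}


DEFAULT_CONFIG = CompressorConfig()


def compressed_length(s: str, cfg: CompressorConfig = DEFAULT_CONFIG) -> int:
    """Length in bytes of the LZMA-compressed residue string."""
    if not s:
        raise ValueError("cannot compress an empty sequence")
    data = s.encode("ascii")
    filters = [{"id": lzma.FILTER_LZMA2, "preset": cfg.level, "dict_size": cfg.dict_size}]
    if cfg.stream_mode == "raw":
        out = lzma.compress(data, format=lzma.FORMAT_RAW, filters=filters)
    else:
        out = lzma.compress(data, format=lzma.FORMAT_XZ, filters=filters)
    return len(out)


def ncd(a: str, b: str, cfg: CompressorConfig = DEFAULT_CONFIG) -> float:
    """Normalized compression distance for one concatenation order (a·b)."""
    ca = compressed_length(a, cfg)
    cb = compressed_length(b, cfg)
    cab = compressed_length(a + b, cfg)
    return (cab - min(ca, cb)) / max(ca, cb)


def symmetrized_ncd(a: str, b: str, cfg: CompressorConfig = DEFAULT_CONFIG) -> float:
    """Mean of NCD over both concatenation orders; exactly symmetric."""
    return 0.5 * (ncd(a, b, cfg) + ncd(b, a, cfg))


def ncd_similarity(a: str, b: str, cfg: CompressorConfig = DEFAULT_CONFIG) -> float:
    """S_NCD = 1 - symmetrized NCD, clamped to [0, 1]."""
    value = 1.0 - symmetrized_ncd(a, b, cfg)
    if value < 0.0:
        logger.debug("NCD similarity clamped from %.4f to 0", value)
    return float(min(1.0, max(0.0, value)))


def ncd_similarity_matrix(panel, cfg: CompressorConfig = DEFAULT_CONFIG) -> SimilarityMatrix:
    """S_NCD matrix over a protein panel.

    The diagonal is the actual self-similarity (compressor overhead keeps
    it below 1); it is recorded as-is, clamped like every other entry.
    Caches per-sequence compressed lengths so each pair costs only the two
    concatenation compressions.
    """
    if not panel:
        raise ValueError("panel must be nonempty")
    ids = [p.id for p in panel]
    seqs = [p.sequence for p in panel]
    n = len(seqs)
    lengths = np.array([compressed_length(s, cfg) for s in seqs], dtype=float)
    values = np.zeros((n, n))
    clamped = 0
    for i in range(n):
        for j in range(i, n):
            cij = compressed_length(seqs[i] + seqs[j], cfg)
            cji = cij if i == j else compressed_length(seqs[j] + seqs[i], cfg)
            lo, hi = min(lengths[i], lengths[j]), max(lengths[i], lengths[j])
            d = 0.5 * ((cij - lo) / hi + (cji - lo) / hi)
            v = 1.0 - d
            if v < 0.0 or v > 1.0:
                clamped += 1
            values[i, j] = values[j, i] = min(1.0, max(0.0, v))
    if clamped:
        logger.warning("clamped %d NCD similarity entries into [0, 1]", clamped)
    return SimilarityMatrix(
        ids=ids, values=values, kind=MatrixKind.NCD_SIM,
        meta={"compressor": cfg.to_dict(), "clamped_entries": clamped},
    )
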