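"""Small shared numerics: seeded substreams and cosine geometry."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "cosine_similarity", "pairwise_mean_cosine_distance"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random substream derived from a master seed.

    Each pipeline stage draws from its own stream so stages can be re-run
    independently with identical randomness.
    """
    key = zlib.crc32(name.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), key]))


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors; NaN if either is zero."""
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        return float("nan")
    return float(np.dot(u, v) / (nu * nv))


def pairwise_mean_cosine_distance(vectors: np.ndarray) -> float:
    """Mean of (1 - cosine similarity) over all unordered pairs of rows.

    Rows that are exactly zero carry no direction and are skipped; if fewer
    than two nonzero rows remain the value is NaN.
    """
    vectors = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(vectors, axis=1)
    keep = vectors[norms > 0]
    m = keep.shape[0]
    if m < 2:
        return float("nan")
    unit = keep / np.linalg.norm(keep, axis=1, keepdims=True)
    gram = unit @ unit.T
    iu = np.triu_indices(m, k=1)
    return float(np.mean(1.0 - gram[iu]))
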