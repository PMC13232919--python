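"""Pluggable text-embedding backends and cosine similarity.

The reference backend is a deterministic hashed bag-of-words embedder:
tokens are mapped to coordinates by a 32-bit FNV-1a hash modulo the
dimension, counted, and L2-normalised. It requires no model weights, is
byte-stable across platforms, and supports every similarity operation the
pipeline needs. Transformer sentence encoders (the 384-dimensional class
of models typically used for this kind of semantic matching) can be
plugged in by registering a backend that satisfies :class:`Embedder`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Protocol

import numpy as np

from ._text import word_tokens

REFERENCE_DIMENSION = 256

_FNV_OFFSET = 0x811C9DC5
_FNV_PRIME = 0x01000193
_MASK32 = 0xFFFFFFFF


class BackendUnavailableError(RuntimeError):
    """An external embedding/scoring backend was requested but is not installed."""


def fnv1a_32(data: bytes) -> int:
    """32-bit FNV-1a hash; portable and dependency-free."""
    h = _FNV_OFFSET
    for byte in data:
        h ^= byte
        h = (h * _FNV_PRIME) & _MASK32
    return h


def hash_embed(text: str, dimension: int = REFERENCE_DIMENSION) -> np.ndarray:
    """Embed ``text`` as L2-normalised hashed token counts.

    Empty text (no tokens) maps to the zero vector, which by the cosine
    convention below has similarity 0 to everything — an empty post can
    never cross a labeling threshold.
    """
    if dimension <= 0:
        raise ValueError("dimension must be positive")
    vec = np.zeros(dimension, dtype=np.float64)
    for tok in word_tokens(text):
        vec[fnv1a_32(tok.encode("utf-8")) % dimension] += 1.0
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec /= norm
    return vec


class Embedder(Protocol):
    """Contract every backend satisfies."""

    dimension: int

    def embed(self, text: str) -> np.ndarray: ...

    def embed_texts(self, texts: Iterable[str]) -> np.ndarray: ...


@dataclass(frozen=True)
class EmbedderSpec:
    """Backend selection record (config key ``embedder.backend_id``)."""

    backend_id: str = "hashed_reference"
    dimension: int = REFERENCE_DIMENSION
    normalization: str = "l2"

    def __post_init__(self) -> None:
        if self.dimension <= 0:
            raise ValueError("dimension must be positive")


class HashedEmbedder:
    """Deterministic reference backend (FNV-1a hashed counts, L2-normalised)."""

    def __init__(self, dimension: int = REFERENCE_DIMENSION) -> None:
        if dimension <= 0:
            raise ValueError("dimension must be positive")
        self.dimension = dimension

    def embed(self, text: str) -> np.ndarray:
        return hash_embed(text, self.dimension)

    def embed_texts(self, texts: Iterable[str]) -> np.ndarray:
        texts = list(texts)
        out = np.zeros((len(texts), self.dimension), dtype=np.float64)
        for i, t in enumerate(texts):
            out[i] = self.embed(t)
        return out


_BACKENDS: dict[str, Callable[[EmbedderSpec], Embedder]] = {
    "hashed_reference": lambda spec: HashedEmbedder(spec.dimension),
}


def register_backend(backend_id: str, factory: Callable[[EmbedderSpec], Embedder]) -> None:
    _BACKENDS[backend_id] = factory


def get_embedder(spec: EmbedderSpec | str | None = None) -> Embedder:
    """Resolve a backend. Unknown external backends raise, never fall back silently."""
    if spec is None:
        spec = EmbedderSpec()
    if isinstance(spec, str):
        spec = EmbedderSpec(backend_id=spec)
    try:
        factory = _BACKENDS[spec.backend_id]
    except KeyError:
        raise BackendUnavailableError(
            f"embedding backend {spec.backend_id!r} is not registered; "
            f"available: {sorted(_BACKENDS)}"
        ) from None
    return factory(spec)


def embed_texts(spec: EmbedderSpec | str | None, texts: Iterable[str]) -> np.ndarray:
    """Order-preserving batch embedding; batch equals per-item results."""
    return get_embedder(spec).embed_texts(texts)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of two vectors; 0 if either has zero norm (documented convention)."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))
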