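"""Target word-embedding bank with pluggable backends.

The decoding targets are fixed vectors Y in R^d, one per (non-contextual)
lexicon word.  Backends that split a word into several tokens must average
the token vectors into a single target.  The deterministic fallback backend
maps each word to a seeded, unit-normalized Gaussian vector, so the whole
pipeline runs and is testable with no model download; large-language-model
backends implement the same two-method protocol.
"""

from __future__ import annotations

import base64
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np

__all__ = ["EmbeddingTable", "EmbeddingBackend", "FallbackBackend",
           "embed_words", "fallback_embed"]


def normalize_word(word: str) -> str:
    """Lowercase; keep internal apostrophes and hyphens."""
    return word.strip().lower()


class EmbeddingBackend(Protocol):
    """Anything that can turn a word into one or more token vectors."""

    dim: int
    tag: str

    def token_vectors(self, word: str) -> np.ndarray:
        """Return an array of shape (n_tokens, dim) for one word."""
        ...


def _word_digest(word: str) -> int:
    return int.from_bytes(hashlib.sha1(word.encode("utf-8")).digest()[:8], "big")


def fallback_embed(word: str, dim: int, seed: int = 0) -> np.ndarray:
    """Deterministic unit-norm Gaussian embedding keyed by (word, seed).

    Platform-stable: the word enters through a SHA-1 digest, not Python's
    salted hash.
    """
    if dim < 8:
        raise ValueError("embedding dim must be >= 8")
    rng = np.random.default_rng(
        np.random.SeedSequence([_word_digest(normalize_word(word)), seed & 0x7FFFFFFF]))
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


@dataclass
class FallbackBackend:
    """Seeded random-vector backend (single token per word)."""

    dim: int = 1024
    seed: int = 0
    tag: str = "fallback-gaussian"

    def token_vectors(self, word: str) -> np.ndarray:
        return fallback_embed(word, self.dim, self.seed)[None, :]


@dataclass
class EmbeddingTable:
    """Word -> vector store; the only embedding surface downstream code sees."""

    dim: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)
    backend_tag: str = "unknown"

    def __contains__(self, word: str) -> bool:
        return normalize_word(word) in self.vectors

    def __getitem__(self, word: str) -> np.ndarray:
        return self.vectors[normalize_word(word)]

    def __len__(self) -> int:
        return len(self.vectors)

    @property
    def words(self) -> list[str]:
        return list(self.vectors)

    def matrix(self, words: list[str]) -> np.ndarray:
        """Stack vectors for `words` into an (n, dim) array."""
        return np.stack([self[w] for w in words], axis=0)

    # -- persistence: two-column text store with a JSON header ---------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        header = json.dumps({"dim": self.dim, "backend_tag": self.backend_tag})
        lines = [f"#{header}"]
        for w, v in self.vectors.items():
            b64 = base64.b64encode(v.astype(np.float32).tobytes()).decode("ascii")
            lines.append(f"{w}\t{b64}")
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingTable":
        lines = Path(path).read_text().splitlines()
        header = json.loads(lines[0].lstrip("#"))
        table = cls(dim=header["dim"], backend_tag=header["backend_tag"])
        for line in lines[1:]:
            if not line:
                continue
            w, b64 = line.split("\t")
            v = np.frombuffer(base64.b64decode(b64), dtype=np.float32)
            table.vectors[w] = v.astype(np.float64)
        return table


def embed_words(words: list[str], backend: EmbeddingBackend) -> EmbeddingTable:
    """Embed each unique word; multi-token words average their token vectors."""
    table = EmbeddingTable(dim=backend.dim, backend_tag=backend.tag)
    for word in words:
        key = normalize_word(word)
        if key in table.vectors:
            continue
        try:
            toks = np.asarray(backend.token_vectors(key), dtype=np.float64)
        except Exception as exc:  # surface which word broke the backend
            raise RuntimeError(f"embedding backend failed on word {key!r}") from exc
        if toks.ndim != 2 or toks.shape[1] != backend.dim:
            raise ValueError(f"backend returned bad shape for {key!r}: {toks.shape}")
        vec = toks.mean(axis=0)
        if not np.all(np.isfinite(vec)):
            raise ValueError(f"non-finite embedding for word {key!r}")
        table.vectors[key] = vec
    return table
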