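"""Dense phrase embeddings and exact top-k retrieval.

The retrieval layer embeds every KB phrase into a fixed-dimension vector
and answers cosine top-k queries.  Similarity is cosine on L2-normalized
vectors, realized as an inner product.  The index here is *exact*
(brute-force over the matrix); with a KB of tens of thousands of rows a
full scan is a single matrix-vector product and needs no approximate
structure.  Any embedding backend satisfying :class:`EmbeddingBackend`
can be plugged in; the default :class:`HashingEmbedder` is a seeded
character-n-gram feature-hash projection, fully deterministic and
dependency-free.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from .ontology import KnowledgeBase


class IndexSchemaError(ValueError):
    """Persisted index files disagree with each other or the reader."""


class EmbeddingBackendError(RuntimeError):
    pass


class EmbeddingBackend(Protocol):
    """Contract: map a list of strings to a (n, d) float matrix with fixed d,
    deterministically for fixed input."""

    tag: str

    def embed(self, texts: Sequence[str]) -> np.ndarray: ...


class HashingEmbedder:
    """Seeded feature-hash projection of character n-grams and word tokens.

    Each n-gram of the padded phrase is hashed (keyed BLAKE2b, so the seed
    changes the projection) to a bucket and a sign; the phrase vector is
    the signed bucket histogram, L2-normalized.  Phrases sharing surface
    n-grams land near each other, which is the property the retrieval
    layer needs from an embedding.
    """

    def __init__(self, dim: int = 256, seed: int = 0, ngram_range: tuple[int, int] = (3, 5)):
        if dim < 2:
            raise ValueError("dim must be >= 2")
        self.dim = dim
        self.seed = seed
        self.ngram_range = ngram_range
        self._key = seed.to_bytes(8, "little", signed=False)
        self.tag = f"hashing-ngram/d={dim}/seed={seed}"

    def _features(self, text: str) -> list[str]:
        padded = f"\x02{text}\x03"
        lo, hi = self.ngram_range
        feats = [
            padded[i : i + n]
            for n in range(lo, hi + 1)
            for i in range(len(padded) - n + 1)
        ]
        feats.extend(f"w:{w}" for w in text.split())
        return feats

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.dim), dtype=np.float64)
        for row, text in enumerate(texts):
            for feat in self._features(text):
                digest = hashlib.blake2b(
                    feat.encode("utf-8"), digest_size=8, key=self._key
                ).digest()
                value = int.from_bytes(digest, "little")
                bucket = value % self.dim
                sign = 1.0 if (value >> 63) & 1 else -1.0
                out[row, bucket] += sign
            norm = np.linalg.norm(out[row])
            if norm == 0.0:
                out[row, 0] = 1.0
            else:
                out[row] /= norm
        return out


@dataclass
class EmbeddingMatrix:
    """One L2-normalized row per KB entry, parallel to ``row_meta``."""

    vectors: np.ndarray
    row_meta: list[tuple[str, str]]  # (phrase, hpo_id)
    backend_tag: str
    normalized: bool = True


@dataclass
class CandidateMatch:
    """A retrieval hit handed to the assignment step."""

    phrase: str
    hpo_id: str
    label: str
    lineage: str
    organ_system: str
    similarity: float
    rank: int


def embed_phrases(kb: KnowledgeBase, backend: EmbeddingBackend) -> EmbeddingMatrix:
    """Embed every KB phrase; rows are L2-normalized."""
    if not kb.entries:
        raise ValueError("knowledge base has no entries to embed")
    phrases = [e.phrase for e in kb.entries]
    try:
        vectors = np.asarray(backend.embed(phrases), dtype=np.float64)
    except Exception as exc:  # propagate with the failing batch identified
        raise EmbeddingBackendError(
            f"embedding backend failed on batch of {len(phrases)} phrases "
            f"({phrases[0]!r}..{phrases[-1]!r})"
        ) from exc
    if vectors.ndim != 2 or vectors.shape[0] != len(phrases):
        raise EmbeddingBackendError(
            f"backend returned shape {vectors.shape}, expected ({len(phrases)}, d)"
        )
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    vectors = vectors / norms
    return EmbeddingMatrix(
        vectors=vectors,
        row_meta=[(e.phrase, e.hpo_id) for e in kb.entries],
        backend_tag=backend.tag,
        normalized=True,
    )


class ExactVectorIndex:
    """Exact cosine top-k over an embedding matrix with KB metadata payload.

    Ties in similarity break by ascending HPO id, then ascending phrase,
    so results are reproducible across platforms.
    """

    def __init__(self, matrix: EmbeddingMatrix, kb: KnowledgeBase):
        if matrix.vectors.shape[0] == 0:
            raise ValueError("cannot build an index over an empty matrix")
        if matrix.vectors.shape[0] != len(matrix.row_meta):
            raise IndexSchemaError("matrix rows and row_meta length disagree")
        self.vectors = np.ascontiguousarray(matrix.vectors, dtype=np.float64)
        self.row_meta = list(matrix.row_meta)
        self.backend_tag = matrix.backend_tag
        self.dim = self.vectors.shape[1]
        by_key = {(e.phrase, e.hpo_id): e for e in kb.entries}
        self._payload = []
        for key in self.row_meta:
            entry = by_key.get(key)
            if entry is None:
                raise IndexSchemaError(f"row {key} has no matching KB entry")
            self._payload.append(
                {
                    "phrase": entry.phrase,
                    "hpo_id": entry.hpo_id,
                    "label": kb.term_index[entry.hpo_id].label,
                    "lineage": entry.lineage_str(),
                    "organ_system": entry.organ_system,
                }
            )

    def __len__(self) -> int:
        return self.vectors.shape[0]

    def query_top_k(self, query_vector: np.ndarray, k: int) -> list[CandidateMatch]:
        """Top-``min(k, n)`` rows by cosine similarity, descending."""
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        q = np.asarray(query_vector, dtype=np.float64).ravel()
        if q.shape[0] != self.dim:
            raise ValueError(f"query has dimension {q.shape[0]}, index has {self.dim}")
        norm = np.linalg.norm(q)
        if norm > 0:
            q = q / norm
        sims = self.vectors @ q
        order = sorted(
            range(len(self)),
            key=lambda i: (-sims[i], self.row_meta[i][1], self.row_meta[i][0]),
        )[: min(k, len(self))]
        return [
            CandidateMatch(similarity=float(sims[i]), rank=rank, **self._payload[i])
            for rank, i in enumerate(order, start=1)
        ]

    # -- persistence --------------------------------------------------------

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.npy`` (vectors) and ``<prefix>.meta.json``."""
        prefix = Path(prefix)
        np.save(str(prefix) + ".npy", self.vectors)
        meta = {
            "dim": self.dim,
            "rows": len(self),
            "backend_tag": self.backend_tag,
            "row_meta": [list(m) for m in self.row_meta],
        }
        Path(str(prefix) + ".meta.json").write_text(
            json.dumps(meta, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def load(cls, prefix: str | Path, kb: KnowledgeBase) -> "ExactVectorIndex":
        prefix = Path(prefix)
        try:
            vectors = np.load(str(prefix) + ".npy")
            meta = json.loads(Path(str(prefix) + ".meta.json").read_text(encoding="utf-8"))
        except (OSError, ValueError, json.JSONDecodeError) as exc:
            raise IndexSchemaError(f"cannot read index files at {prefix}: {exc}") from exc
        if vectors.ndim != 2 or vectors.shape != (meta["rows"], meta["dim"]):
            raise IndexSchemaError(
                f"vector file shape {vectors.shape} disagrees with metadata "
                f"({meta['rows']}, {meta['dim']})"
            )
        matrix = EmbeddingMatrix(
            vectors=vectors,
            row_meta=[tuple(m) for m in meta["row_meta"]],
            backend_tag=meta["backend_tag"],
        )
        return cls(matrix, kb)


def build_index(matrix: EmbeddingMatrix, kb: KnowledgeBase) -> ExactVectorIndex:
    """Build the searchable index over an embedding matrix."""
    return ExactVectorIndex(matrix, kb)
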