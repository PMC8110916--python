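"""Word-embedding providers for coherence and content-distance features.

Two implementations of the same contract (word -> fixed-dimension vector,
deterministic, out-of-vocabulary -> fallback):

* :class:`HashEmbedding` — deterministic pseudo-random unit vectors keyed by
  a hash of the word and a fixed seed.  No external data; identical words map
  to identical vectors across processes and platforms.  This is the default
  for tests and the synthetic pipeline.
* :class:`TextEmbedding` — loads word2vec/GloVe-style text files
  (``word v1 v2 ...`` per line) for production use on real transcripts.

Coherence features use *two* inventories (mirroring word2vec- and
GloVe-based variants); by default these are two hash providers with
different seeds.
"""

from __future__ import annotations

import hashlib

import numpy as np


class HashEmbedding:
    """Deterministic per-word pseudo-random unit vectors.

    Every word is embedded by seeding a PCG64 generator with
    ``md5(word || seed)`` and drawing a standard-normal vector, normalized
    to unit length.  Vectors for distinct words are near-orthogonal in
    high dimension, so utterance similarity is driven by lexical overlap.
    """

    def __init__(self, dim: int = 50, seed: int = 0):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.dim = dim
        self.seed = seed
        self._cache: dict[str, np.ndarray] = {}

    def __call__(self, word: str) -> np.ndarray:
        w = word.lower()
        vec = self._cache.get(w)
        if vec is None:
            digest = hashlib.md5(f"{w}|{self.seed}".encode()).digest()
            rng = np.random.Generator(
                np.random.PCG64(int.from_bytes(digest[:8], "little")))
            v = rng.standard_normal(self.dim)
            vec = v / np.linalg.norm(v)
            self._cache[w] = vec
        return vec

    def embed_tokens(self, tokens: list[str]) -> np.ndarray | None:
        """Mean of token vectors; None if no token is embeddable."""
        if not tokens:
            return None
        return np.mean([self(t) for t in tokens], axis=0)


class TextEmbedding:
    """Embeddings from a word2vec-text-format file; OOV -> zero fallback."""

    def __init__(self, path: str):
        self.vectors: dict[str, np.ndarray] = {}
        with open(path) as fh:
            first = fh.readline().split()
            if len(first) == 2 and all(p.isdigit() for p in first):
                pass  # header line "n dim"
            elif first:
                self.vectors[first[0]] = np.array(first[1:], dtype=float)
            for line in fh:
                parts = line.split()
                if len(parts) > 2:
                    self.vectors[parts[0]] = np.array(parts[1:], dtype=float)
        if not self.vectors:
            raise ValueError(f"no vectors found in {path}")
        self.dim = len(next(iter(self.vectors.values())))
        self._fallback = np.zeros(self.dim)

    def __call__(self, word: str) -> np.ndarray:
        return self.vectors.get(word.lower(), self._fallback)

    def embed_tokens(self, tokens: list[str]) -> np.ndarray | None:
        vecs = [self(t) for t in tokens if t.lower() in self.vectors]
        if not vecs:
            return None
        return np.mean(vecs, axis=0)


#: closed-class words excluded from utterance embeddings, so that
#: utterance-level similarity reflects content overlap rather than shared
#: function words
STOPWORDS = frozenset("""
the a an this that these those and but or so in on at from with of to by
for about into over under near behind beside through outside inside while
because if as he she it they i you we him her them me us his their my your
its our is are was were be been being am has have had having does do did
done doing will can could would should may might must there not very just
here now then also too again away down up out almost really quite maybe
perhaps soon still always never often oh well yeah yes no one some any
every each much many more most all
""".split())


def embed_utterance(tokens: list[str], emb) -> np.ndarray | None:
    """Utterance vector: mean of content-token vectors (stopwords
    excluded); falls back to all tokens when none remain."""
    content = [t for t in tokens if t.lower() not in STOPWORDS]
    return emb.embed_tokens(content if content else list(tokens))


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    return 1.0 - cosine_similarity(a, b)
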