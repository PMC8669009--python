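"""Word vectors and smooth-inverse-frequency (SIF) sentence embeddings.

A sentence vector is the frequency-down-weighted mean of its in-vocabulary
content-word vectors,

    v(S) = (1/|S_iv|) * sum_{w in S_iv} a / (a + p(w)) * vec(w),

where p(w) is the corpus unigram probability of w and a is the SIF smoothing
parameter (default 1e-3, the method's recommended value). A second, batch-wise
step removes the leading right-singular direction of the stacked sentence
vectors (the common discourse component); see :func:`remove_first_component`.

Out-of-vocabulary tokens are skipped. A sentence with no in-vocabulary token
yields a *degenerate* vector (flagged, all-zero); degeneracy is propagated,
never silently treated as zero similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

DEFAULT_SIF_A = 1e-3


@dataclass
class EmbeddingLexicon:
    """word -> d-dimensional vector map with unigram probabilities."""

    vectors: dict[str, np.ndarray] = field(repr=False)
    frequencies: dict[str, float] = field(repr=False)
    a: float = DEFAULT_SIF_A
    floor_frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.vectors:
            raise ValueError("empty vocabulary")
        if self.a <= 0:
            raise ValueError(f"SIF parameter a must be > 0, got {self.a}")
        dims = {v.shape for v in self.vectors.values()}
        if len(dims) != 1 or len(next(iter(dims))) != 1:
            raise ValueError(f"inconsistent vector dimensions: {dims}")
        total = sum(self.frequencies.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"frequencies sum to {total} > 1")
        if self.floor_frequency is None:
            # unseen words are treated as at least as rare as the rarest
            # observed word (maximal SIF weight among observed words)
            self.floor_frequency = (
                min(self.frequencies.values()) if self.frequencies else 1e-6
            )

    @property
    def dim(self) -> int:
        return next(iter(self.vectors.values())).shape[0]

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def p(self, word: str) -> float:
        return self.frequencies.get(word, self.floor_frequency)

    def sif_weight(self, word: str) -> float:
        return self.a / (self.a + self.p(word))


@dataclass(frozen=True)
class SentenceVector:
    vector: np.ndarray
    n_content_tokens: int
    degenerate: bool

    @property
    def dim(self) -> int:
        return self.vector.shape[0]


def load_lexicon(
    path: str | Path,
    frequency_path: str | Path,
    a: float = DEFAULT_SIF_A,
) -> EmbeddingLexicon:
    """Load word vectors (word2vec text format) and a word-frequency table.

    The vector file starts with a header line ``V d`` followed by lines
    ``word v1 ... vd``. The frequency file has lines ``word count``; counts
    are normalised to probabilities over the listed words. Vocabulary words
    absent from the frequency file receive the floor frequency (the smallest
    observed probability).
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: expected header 'V d', got {header}")
        n_words, dim = int(header[0]), int(header[1])
        vectors: dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                continue
            word, vals = parts[0], parts[1:]
            if len(vals) != dim:
                raise ValueError(
                    f"{path}:{lineno}: expected {dim} floats for {word!r}, "
                    f"got {len(vals)}"
                )
            vectors[word] = np.asarray(vals, dtype=np.float64)
    if not vectors:
        raise ValueError(f"{path}: empty vocabulary")
    if len(vectors) != n_words:
        raise ValueError(
            f"{path}: header declares {n_words} words, parsed {len(vectors)}"
        )

    counts: dict[str, float] = {}
    with Path(frequency_path).open(encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 2:
                continue
            counts[parts[0]] = float(parts[1])
    total = sum(counts.values())
    freqs = {w: c / total for w, c in counts.items() if w in vectors}
    return EmbeddingLexicon(vectors=vectors, frequencies=freqs, a=a)


def save_lexicon(
    lexicon: EmbeddingLexicon, path: str | Path, frequency_path: str | Path
) -> None:
    """Write a lexicon back to word2vec text + frequency-table files."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{len(lexicon)} {lexicon.dim}\n")
        for w, v in lexicon.vectors.items():
            fh.write(w + " " + " ".join(f"{x:.8g}" for x in v) + "\n")
    with Path(frequency_path).open("w", encoding="utf-8") as fh:
        for w, p in lexicon.frequencies.items():
            fh.write(f"{w} {p:.10g}\n")


def sif_embed(tokens: Sequence[str], lexicon: EmbeddingLexicon) -> SentenceVector:
    """SIF-weighted mean of in-vocabulary token vectors (one per occurrence)."""
    in_vocab = [t for t in tokens if t in lexicon]
    if not in_vocab:
        return SentenceVector(
            vector=np.zeros(lexicon.dim), n_content_tokens=0, degenerate=True
        )
    acc = np.zeros(lexicon.dim)
    for t in in_vocab:
        acc += lexicon.sif_weight(t) * lexicon.vectors[t]
    return SentenceVector(
        vector=acc / len(in_vocab),
        n_content_tokens=len(in_vocab),
        degenerate=False,
    )


def remove_first_component(
    vectors: Sequence[SentenceVector],
) -> list[SentenceVector]:
    """Project out the leading right-singular direction of the batch.

    The direction u is estimated from all non-degenerate vectors stacked as
    rows; each non-degenerate v is replaced by v - (u.v)u. Degenerate vectors
    pass through unchanged, as does the whole batch when fewer than two
    non-degenerate vectors are available (too little signal to estimate u).
    """
    usable = [sv for sv in vectors if not sv.degenerate]
    if len(usable) < 2:
        return list(vectors)
    X = np.vstack([sv.vector for sv in usable])
    # first right-singular vector of X
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    u = vt[0]
    out = []
    for sv in vectors:
        if sv.degenerate:
            out.append(sv)
        else:
            v = sv.vector - np.dot(u, sv.vector) * u
            out.append(
                SentenceVector(
                    vector=v,
                    n_content_tokens=sv.n_content_tokens,
                    degenerate=False,
                )
            )
    return out


def cosine(u: np.ndarray | SentenceVector, v: np.ndarray | SentenceVector) -> float:
    """Cosine similarity in [-1, 1]; NaN if either vector is zero/degenerate."""
    if isinstance(u, SentenceVector):
        if u.degenerate:
            return float("nan")
        u = u.vector
    if isinstance(v, SentenceVector):
        if v.degenerate:
            return float("nan")
        v = v.vector
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return float("nan")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def embed_sentences(
    content_sentences: Iterable[Sequence[str]], lexicon: EmbeddingLexicon
) -> list[SentenceVector]:
    """SIF-embed every sentence of a content-token view (empties degenerate)."""
    return [sif_embed(s, lexicon) for s in content_sentences]
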