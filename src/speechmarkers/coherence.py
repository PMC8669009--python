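"""Embedding-based discourse measures for one excerpt.

Four measures, all on SIF sentence vectors:

- **semantic coherence** — mean cosine similarity between adjacent sentences;
- **tangentiality** — slope of the OLS regression of sentence-to-stimulus
  cosine similarity on sentence index (more negative = drifting off-topic
  over time);
- **on-topic score** — mean sentence-to-stimulus cosine similarity;
- **maximum similarity** — maximum cosine similarity over all unordered
  sentence pairs (a repetition marker; 1.0 means at least two sentences have
  identical vectors).

Degenerate sentence vectors (no in-vocabulary content token) are dropped
before pairing, and sentence indices are renumbered over the survivors.
When a measure's precondition is unmet the result is NaN (missing), never a
silent zero.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .lexicon import EmbeddingLexicon, SentenceVector, cosine, sif_embed
from .transcripts import preprocess_tokens, tokenize


@dataclass(frozen=True)
class StimulusDescription:
    """A-priori one-sentence description of a speech-eliciting stimulus."""

    stimulus_id: str
    tokens: tuple[str, ...]
    vector: SentenceVector

    def __post_init__(self) -> None:
        if self.vector.degenerate:
            raise ValueError(
                f"stimulus {self.stimulus_id!r} has a degenerate vector; "
                "tangentiality/on-topic require an embeddable description"
            )


@dataclass(frozen=True)
class CoherenceScores:
    coherence: float
    tangentiality: float
    on_topic: float
    max_similarity: float


def _usable(vectors: Sequence[SentenceVector]) -> list[SentenceVector]:
    return [v for v in vectors if not v.degenerate]


def semantic_coherence(sentence_vectors: Sequence[SentenceVector]) -> float:
    """Mean cosine similarity between adjacent (usable) sentence vectors."""
    vs = _usable(sentence_vectors)
    if len(vs) < 2:
        return float("nan")
    sims = [cosine(vs[i], vs[i + 1]) for i in range(len(vs) - 1)]
    return float(np.mean(sims))


def tangentiality(
    sentence_vectors: Sequence[SentenceVector],
    stimulus: StimulusDescription | SentenceVector,
) -> float:
    """OLS slope of sentence-to-stimulus similarity over sentence index."""
    stim = stimulus.vector if isinstance(stimulus, StimulusDescription) else stimulus
    if stim.degenerate:
        return float("nan")
    vs = _usable(sentence_vectors)
    if len(vs) < 2:
        return float("nan")
    sims = np.array([cosine(v, stim) for v in vs])
    x = np.arange(len(vs), dtype=np.float64)
    slope = np.polyfit(x, sims, 1)[0]
    return float(slope)


def on_topic(
    sentence_vectors: Sequence[SentenceVector],
    stimulus: StimulusDescription | SentenceVector,
) -> float:
    """Mean sentence-to-stimulus cosine similarity across the response."""
    stim = stimulus.vector if isinstance(stimulus, StimulusDescription) else stimulus
    if stim.degenerate:
        return float("nan")
    vs = _usable(sentence_vectors)
    if not vs:
        return float("nan")
    return float(np.mean([cosine(v, stim) for v in vs]))


def max_similarity(sentence_vectors: Sequence[SentenceVector]) -> float:
    """Maximum cosine similarity over unordered sentence pairs (i < j)."""
    vs = _usable(sentence_vectors)
    if len(vs) < 2:
        return float("nan")
    best = -np.inf
    for i in range(len(vs)):
        for j in range(i + 1, len(vs)):
            best = max(best, cosine(vs[i], vs[j]))
    return float(best)


def coherence_scores(
    sentence_vectors: Sequence[SentenceVector],
    stimulus: Optional[StimulusDescription | SentenceVector] = None,
) -> CoherenceScores:
    """All four measures; stimulus-dependent ones are NaN without a stimulus
    (free speech has no a-priori description, so no tangentiality/on-topic).
    """
    return CoherenceScores(
        coherence=semantic_coherence(sentence_vectors),
        tangentiality=(
            tangentiality(sentence_vectors, stimulus)
            if stimulus is not None
            else float("nan")
        ),
        on_topic=(
            on_topic(sentence_vectors, stimulus)
            if stimulus is not None
            else float("nan")
        ),
        max_similarity=max_similarity(sentence_vectors),
    )


def read_stimuli(
    path: str | Path,
    lexicon: EmbeddingLexicon,
    stopwords=None,
    fillers=None,
) -> dict[str, StimulusDescription]:
    """Read a stimulus-description CSV (stimulus_id, description).

    Descriptions are tokenized and preprocessed like transcripts, then
    SIF-embedded with the same lexicon so stimulus and sentence vectors live
    in the same space.
    """
    kwargs = {}
    if stopwords is not None:
        kwargs["stopwords"] = stopwords
    if fillers is not None:
        kwargs["fillers"] = fillers
    out: dict[str, StimulusDescription] = {}
    with Path(path).open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {
            "stimulus_id",
            "description",
        } <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: expected columns stimulus_id, description"
            )
        for row in reader:
            sid = row["stimulus_id"]
            toks = tokenize(row["description"])
            content = preprocess_tokens([toks], **kwargs)[0]
            out[sid] = StimulusDescription(
                stimulus_id=sid,
                tokens=tuple(toks),
                vector=sif_embed(content, lexicon),
            )
    return out
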