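"""Transcript parsing and preprocessing.

Transcripts are plain UTF-8 text in which inaudible spans are marked ``[?]``
and (optionally) interviewer prompts appear on their own lines marked
``[PROMPT]``. Parsing produces an :class:`Excerpt`: ordered sentences of
lowercase tokens plus bookkeeping counts. Surface measures (word count,
sentence count, words per sentence) are computed on the raw token stream;
embedding-based measures operate on a content-token view produced by
:func:`preprocess_tokens` (stopword and filler removal).
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .wordlists import FILLERS, STOPWORDS

TASKS = ("TAT", "DCT", "FREE")
GROUPS = ("CON", "CHR-P", "FEP")

COVARIATE_COLUMNS = ("IQ", "years_education", "digit_span", "medication")

_INAUDIBLE = "[?]"
_PROMPT = "[PROMPT]"
_SENT_SPLIT = re.compile(r"[.!?]+")
_STRIP_CHARS = string.punctuation + "‘’“”…"


@dataclass(frozen=True)
class Excerpt:
    """One transcribed response, tokenized and sentence-segmented."""

    subject_id: str
    task: str
    stimulus_id: Optional[str]
    sentences: tuple[tuple[str, ...], ...]
    n_inaudible: int
    n_prompts: int = 0

    @property
    def n_words_raw(self) -> int:
        return sum(len(s) for s in self.sentences)

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)

    @property
    def mean_sentence_length(self) -> float:
        return self.n_words_raw / self.n_sentences

    def word_sequence(self) -> list[str]:
        """All tokens in spoken order, across sentence boundaries."""
        return [w for s in self.sentences for w in s]

    def to_text(self) -> str:
        """Canonical text form: one sentence per line, terminated by '.'"""
        return "\n".join(" ".join(s) + "." for s in self.sentences)


def _clean_token(tok: str) -> str:
    return tok.strip(_STRIP_CHARS).lower()


def tokenize(text: str) -> list[str]:
    """Whitespace split, strip surrounding punctuation, lowercase.

    Hyphens and internal apostrophes are kept, so "self-made" and "didn't"
    survive as single tokens (matching bag-of-words embedding lookup).
    """
    return [t for t in (_clean_token(t) for t in text.split()) if t]


def parse_excerpt(
    raw_text: str,
    subject_id: str,
    task: str,
    stimulus_id: Optional[str] = None,
    *,
    sentence_mode: str = "punct",
    source: Optional[str] = None,
) -> Excerpt:
    """Parse raw transcript text into an :class:`Excerpt`.

    Parameters
    ----------
    sentence_mode:
        ``"punct"`` (default) splits sentences on terminal punctuation
        ``. ! ?``; a transcript with no terminal punctuation becomes a single
        sentence. ``"line"`` treats every non-empty line as one sentence
        (for transcripts that delimit utterances by line).
    source:
        Optional provenance string (e.g. a file path) used in error messages.

    Raises
    ------
    ValueError
        If the text is empty/whitespace-only or the task label is unknown.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    where = f" ({source})" if source else ""
    if not raw_text or not raw_text.strip():
        raise ValueError(f"empty transcript for subject {subject_id!r}{where}")

    n_prompts = 0
    kept_lines = []
    for line in raw_text.splitlines():
        if line.strip().startswith(_PROMPT):
            n_prompts += 1
        else:
            kept_lines.append(line)

    n_inaudible = sum(line.count(_INAUDIBLE) for line in kept_lines)
    kept_lines = [line.replace(_INAUDIBLE, " ") for line in kept_lines]

    if sentence_mode == "line":
        raw_sentences = [ln for ln in kept_lines if ln.strip()]
    elif sentence_mode == "punct":
        raw_sentences = _SENT_SPLIT.split(" ".join(kept_lines))
    else:
        raise ValueError(f"unknown sentence_mode {sentence_mode!r}")

    sentences = tuple(
        tuple(toks) for toks in (tokenize(s) for s in raw_sentences) if toks
    )
    if not sentences:
        raise ValueError(
            f"transcript for subject {subject_id!r}{where} contains no words"
        )
    return Excerpt(
        subject_id=subject_id,
        task=task,
        stimulus_id=stimulus_id,
        sentences=sentences,
        n_inaudible=n_inaudible,
        n_prompts=n_prompts,
    )


def read_excerpt_file(
    path: str | Path,
    subject_id: str,
    task: str,
    stimulus_id: Optional[str] = None,
    **kwargs,
) -> Excerpt:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    return parse_excerpt(
        text, subject_id, task, stimulus_id, source=str(path), **kwargs
    )


def preprocess_tokens(
    sentences: Sequence[Sequence[str]] | Excerpt,
    stopwords: Iterable[str] = STOPWORDS,
    fillers: Iterable[str] = FILLERS,
) -> list[list[str]]:
    """Content-token view: remove stopwords and fillers, keep structure.

    Multi-word fillers (e.g. "you know") are removed as exact token bigrams
    first. Sentences emptied by filtering are retained as empty lists so the
    parallel structure (and hence sentence indices) is preserved; callers
    that embed sentences decide how to treat empties.
    """
    if isinstance(sentences, Excerpt):
        sentences = sentences.sentences
    stopset = set(stopwords)
    fillset = set(fillers)
    bigrams = {tuple(f.split()) for f in fillset if " " in f}
    unigrams = {f for f in fillset if " " not in f}

    out: list[list[str]] = []
    for sent in sentences:
        toks = list(sent)
        if bigrams:
            kept: list[str] = []
            i = 0
            while i < len(toks):
                if i + 1 < len(toks) and (toks[i], toks[i + 1]) in bigrams:
                    i += 2
                else:
                    kept.append(toks[i])
                    i += 1
            toks = kept
        out.append([t for t in toks if t not in stopset and t not in unigrams])
    return out


def inaudible_rate(excerpt: Excerpt) -> float:
    """Inaudible markers per raw word (the paper-style normalisation)."""
    if excerpt.n_words_raw <= 0:
        raise ValueError(
            f"excerpt {excerpt.subject_id!r} has no words; cannot normalise"
        )
    return excerpt.n_inaudible / excerpt.n_words_raw


# --- cohort manifest --------------------------------------------------------

REQUIRED_MANIFEST_COLUMNS = ("subject_id", "group", "task", "excerpt_path")


@dataclass
class CohortManifest:
    """Validated cohort manifest: one row per excerpt file."""

    rows: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.rows
        missing = [c for c in REQUIRED_MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing required column(s): {missing}")
        bad_groups = set(df["group"].unique()) - set(GROUPS)
        if bad_groups:
            raise ValueError(
                f"unknown group label(s) {sorted(bad_groups)}; "
                f"expected one of {GROUPS}"
            )
        bad_tasks = set(df["task"].unique()) - set(TASKS)
        if bad_tasks:
            raise ValueError(f"unknown task label(s) {sorted(bad_tasks)}")
        key_cols = ["subject_id", "task"]
        if "stimulus_id" in df.columns:
            key_cols.append("stimulus_id")
        dupes = df.duplicated(subset=key_cols)
        if dupes.any():
            first = df.loc[dupes.idxmax(), key_cols].tolist()
            raise ValueError(f"duplicate manifest row for {first}")
        self.rows = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def subjects(self) -> pd.DataFrame:
        """One row per subject with group label and covariates."""
        cols = ["subject_id", "group"] + [
            c for c in COVARIATE_COLUMNS if c in self.rows.columns
        ]
        return self.rows[cols].drop_duplicates("subject_id").reset_index(drop=True)


def read_manifest(path: str | Path) -> CohortManifest:
    """Read and validate a cohort manifest CSV.

    Required columns: subject_id, group, task, excerpt_path. Optional:
    stimulus_id plus covariates (IQ, years_education, digit_span,
    medication). Blank covariate cells become NaN (explicit missing),
    never zero.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "stimulus_id": str})
    return CohortManifest(df)
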