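"""Synthetic embedding lexicons and 3-group speech cohorts.

Real clinical speech recordings cannot be redistributed, so every pipeline
stage is exercised against generated data with known ground truth. The
generator emulates the structure the markers are sensitive to, not natural
language itself:

- a **topic lexicon**: near-orthogonal topic centroids on the unit sphere,
  word vectors scattered around them, Zipfian word frequencies;
- **excerpts**: sentences realised as bag-of-topic-words on a small
  function-word scaffold ("the X Y the Z ..."), with per-group dynamics —
  off-topic jumps (i.i.d. draws from a non-stimulus topic), gradual topic
  drift (a random walk on a topic ring), verbatim sentence repetition,
  restricted vocabulary breadth (lowers speech-graph connectivity),
  ambiguous-pronoun insertions (pronoun-first entity mentions) and
  inaudible ``[?]`` markers;
- **cohorts**: three groups (control-like, clinical-high-risk-like,
  first-episode-psychosis-like) with group-graded parameters, default
  sample sizes 13/25/16 subjects and 8 excerpts each, plus per-subject
  covariates (IQ, years of education, digit span) drawn around the
  group-level means of the study population the cohort emulates.

Every latent choice (sentence topic, repetition flag, inserted pronouns,
inaudible markers) is recorded in a ground-truth table, and everything is
a pure function of the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lexicon import EmbeddingLexicon
from .transcripts import CohortManifest, Excerpt

AMBIGUOUS_PRONOUN = "they"  # plural: never matches the singular scaffold nouns
NAMED_PRONOUN_RATE = 0.04  # resolvable name+pronoun sentences, all groups


@dataclass(frozen=True)
class TopicLexiconSpec:
    n_topics: int = 12
    words_per_topic: int = 40
    dim: int = 50
    sigma_topic: float = 0.35
    zipf_exponent: float = 1.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_topics, self.words_per_topic, self.dim) <= 0:
            raise ValueError("lexicon spec fields must be positive")
        if self.sigma_topic < 0 or self.zipf_exponent <= 0:
            raise ValueError("sigma_topic must be >= 0 and zipf_exponent > 0")


@dataclass(frozen=True)
class GroupGeneratorSpec:
    """Disorganisation parameters for one group."""

    label: str
    n_subjects: int
    excerpts_per_subject: int = 8
    off_topic_rate: float = 0.05  # P(sentence drawn from a random other topic)
    drift_rate: float = 0.02  # P(per sentence) of a topic-ring random-walk step
    repetition_rate: float = 0.03  # P(sentence verbatim-repeats an earlier one)
    vocab_breadth: float = 1.0  # fraction of topic vocabulary accessible
    mean_sentences: float = 9.0
    mean_content_words: float = 7.0  # content words per sentence (Poisson mean)
    pronoun_ambiguity_rate: float = 0.02  # P(per sentence) of an ambiguous pronoun
    inaudible_rate: float = 0.01  # per-word [?] probability
    covariate_means: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "off_topic_rate",
            "repetition_rate",
            "pronoun_ambiguity_rate",
            "inaudible_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.vocab_breadth <= 1.0:
            raise ValueError(f"vocab_breadth={self.vocab_breadth} outside (0, 1]")
        if self.drift_rate < 0:
            raise ValueError("drift_rate must be >= 0")
        if self.mean_sentences <= 0 or self.mean_content_words <= 0:
            raise ValueError("sentence distributions need positive means")
        if self.n_subjects < 1 or self.excerpts_per_subject < 1:
            raise ValueError("need at least one subject and one excerpt")


def topic_word(topic: int, idx: int) -> str:
    return f"t{topic}w{idx}"


def make_topic_lexicon(spec: TopicLexiconSpec) -> EmbeddingLexicon:
    """Generate a topical embedding lexicon, fully determined by the seed.

    Topic centroids are orthonormal when n_topics <= dim (QR of a Gaussian
    matrix), otherwise random unit vectors (with a warning if any two are
    closer than cosine 0.3). Word vectors are unit-normalised centroid +
    Gaussian(sigma_topic) perturbations; frequencies follow a Zipf law over
    a topic-interleaved global ranking and sum to 1.
    """
    rng = np.random.default_rng(spec.seed)
    d, k = spec.dim, spec.n_topics
    if k <= d:
        q, _ = np.linalg.qr(rng.normal(size=(d, k)))
        centroids = q.T
    else:
        centroids = rng.normal(size=(k, d))
        centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
        cos = np.abs(centroids @ centroids.T - np.eye(k)).max()
        if cos > 0.3:
            warnings.warn(
                f"{k} topics in {d} dimensions: centroid cosines up to "
                f"{cos:.2f}; topics will overlap"
            )
    vectors: dict[str, np.ndarray] = {}
    for ti in range(k):
        noise = rng.normal(scale=spec.sigma_topic, size=(spec.words_per_topic, d))
        vecs = centroids[ti] + noise if spec.sigma_topic > 0 else np.tile(
            centroids[ti], (spec.words_per_topic, 1)
        )
        vecs = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
        for wi in range(spec.words_per_topic):
            vectors[topic_word(ti, wi)] = vecs[wi]
    # global Zipf ranking, interleaved across topics so every topic has
    # both common and rare words
    ranked = [
        topic_word(ti, wi)
        for wi in range(spec.words_per_topic)
        for ti in range(k)
    ]
    weights = 1.0 / np.arange(1, len(ranked) + 1) ** spec.zipf_exponent
    probs = weights / weights.sum()
    freqs = dict(zip(ranked, probs))
    return EmbeddingLexicon(vectors=vectors, frequencies=freqs)


def stimulus_description_tokens(
    topic: int, lexicon: EmbeddingLexicon, n_words: int = 6
) -> list[str]:
    """A-priori description: the topic's highest-frequency words."""
    words = [w for w in lexicon.frequencies if w.startswith(f"t{topic}w")]
    words.sort(key=lambda w: -lexicon.frequencies[w])
    return words[:n_words]


@dataclass
class ExcerptTruth:
    """Latent generator state for one excerpt, for audit and recovery tests."""

    subject_id: str
    group: str
    stimulus_id: str
    stimulus_topic: int
    sentence_topics: list[int]
    repetition_flags: list[bool]
    n_ambiguous_pronouns: int
    n_named_pronouns: int
    n_inaudible: int
    n_words: int


def _scaffold_sentence(content: Sequence[str]) -> list[str]:
    toks: list[str] = []
    for i, c in enumerate(content):
        if i % 2 == 0:
            toks.append("the")
        toks.append(c)
    return toks


def generate_excerpt(
    spec: GroupGeneratorSpec,
    stimulus_topic: int,
    lexicon_spec: TopicLexiconSpec,
    rng: np.random.Generator,
    subject_id: str = "S00",
    stimulus_id: Optional[str] = None,
    task: str = "TAT",
) -> tuple[Excerpt, str, ExcerptTruth]:
    """Generate one excerpt: (parsed Excerpt, raw transcript text, truth).

    Sentence topics follow the drift/off-topic dynamics; words are drawn
    from the active topic restricted to ``vocab_breadth``; repetition
    verbatim-copies an earlier sentence. The returned text re-parses to an
    Excerpt with identical sentences (round-trip invariant).
    """
    k = lexicon_spec.n_topics
    wpt = lexicon_spec.words_per_topic
    n_accessible = max(2, int(round(spec.vocab_breadth * wpt)))
    n_sent = max(2, int(rng.poisson(spec.mean_sentences)))
    stim = stimulus_id if stimulus_id is not None else f"stim{stimulus_topic}"

    offset = 0  # drift random-walk position on the topic ring
    sentences: list[list[str]] = []
    topics: list[int] = []
    rep_flags: list[bool] = []
    n_amb = 0
    n_named = 0
    names = ("john", "mary", "peter", "anna")
    for _ in range(n_sent):
        if sentences and rng.random() < spec.repetition_rate:
            j = int(rng.integers(len(sentences)))
            sentences.append(list(sentences[j]))
            topics.append(topics[j])
            rep_flags.append(True)
            continue
        if rng.random() < spec.drift_rate:
            offset += int(rng.choice((-1, 1)))
        if rng.random() < spec.off_topic_rate:
            topic = int((stimulus_topic + 1 + rng.integers(k - 1)) % k)
        else:
            topic = int((stimulus_topic + offset) % k)
        n_content = max(2, int(rng.poisson(spec.mean_content_words)))
        word_ids = rng.integers(n_accessible, size=n_content)
        content = [topic_word(topic, int(w)) for w in word_ids]
        toks = _scaffold_sentence(content)
        r = rng.random()
        if r < spec.pronoun_ambiguity_rate:
            # pronoun-first mention of an entity that is never named
            toks = [AMBIGUOUS_PRONOUN, "saw"] + toks
            n_amb += 1
        elif r < spec.pronoun_ambiguity_rate + NAMED_PRONOUN_RATE:
            # name-first mention followed by a resolvable pronoun
            name = names[int(rng.integers(len(names)))]
            pron = "he" if name in ("john", "peter") else "she"
            toks = [name, "saw"] + toks + ["and", pron, "stopped"]
            n_named += 1
        sentences.append(toks)
        topics.append(topic)
        rep_flags.append(False)

    n_words = sum(len(s) for s in sentences)
    n_inaudible = int(rng.binomial(n_words, spec.inaudible_rate))
    marker_slots = (
        sorted(rng.choice(n_words, size=n_inaudible, replace=False).tolist())
        if n_inaudible
        else []
    )

    # render transcript text, inserting [?] before the chosen word slots
    lines = []
    flat_idx = 0
    slot_set = set(marker_slots)
    for sent in sentences:
        parts = []
        for tok in sent:
            if flat_idx in slot_set:
                parts.append("[?]")
            parts.append(tok)
            flat_idx += 1
        lines.append(" ".join(parts) + ".")
    text = "\n".join(lines)

    excerpt = Excerpt(
        subject_id=subject_id,
        task=task,
        stimulus_id=stim,
        sentences=tuple(tuple(s) for s in sentences),
        n_inaudible=n_inaudible,
    )
    truth = ExcerptTruth(
        subject_id=subject_id,
        group=spec.label,
        stimulus_id=stim,
        stimulus_topic=stimulus_topic,
        sentence_topics=topics,
        repetition_flags=rep_flags,
        n_ambiguous_pronouns=n_amb,
        n_named_pronouns=n_named,
        n_inaudible=n_inaudible,
        n_words=n_words,
    )
    return excerpt, text, truth


# --- cohort-level generation ------------------------------------------------

# Group-level covariate distributions of the emulated study population
# (means and standard deviations: IQ, years of education, digit span).
_COVARIATE_PARAMS = {
    "CON": {"IQ": (115.6, 5.2), "years_education": (18.4, 4.2), "digit_span": (20.7, 4.1)},
    "CHR-P": {"IQ": (103.3, 11.8), "years_education": (13.0, 2.8), "digit_span": (17.0, 3.6)},
    "FEP": {"IQ": (99.8, 15.0), "years_education": (13.3, 1.9), "digit_span": (13.3, 4.5)},
}


def default_group_specs() -> dict[str, GroupGeneratorSpec]:
    """Default graded 3-group cohort: disorganisation increases CON -> FEP.

    Sample sizes (13/25/16, 8 excerpts each) and the direction of every
    gradient (fewer words and shorter sentences but more sentences, lower
    coherence/on-topic, lower graph connectivity, slightly more inaudible
    and ambiguous-pronoun events in the patient-like groups) mirror the
    cohort structure the package is designed to analyse.
    """
    return {
        "CON": GroupGeneratorSpec(
            label="CON",
            n_subjects=13,
            off_topic_rate=0.05,
            drift_rate=0.02,
            repetition_rate=0.03,
            vocab_breadth=1.0,
            mean_sentences=9.0,
            mean_content_words=7.0,
            pronoun_ambiguity_rate=0.02,
            inaudible_rate=0.010,
        ),
        "CHR-P": GroupGeneratorSpec(
            label="CHR-P",
            n_subjects=25,
            off_topic_rate=0.15,
            drift_rate=0.06,
            repetition_rate=0.06,
            vocab_breadth=0.50,
            mean_sentences=9.0,
            mean_content_words=6.5,
            pronoun_ambiguity_rate=0.04,
            inaudible_rate=0.020,
        ),
        "FEP": GroupGeneratorSpec(
            label="FEP",
            n_subjects=16,
            off_topic_rate=0.30,
            drift_rate=0.12,
            repetition_rate=0.10,
            vocab_breadth=0.25,
            mean_sentences=11.0,
            mean_content_words=5.0,
            pronoun_ambiguity_rate=0.06,
            inaudible_rate=0.018,
        ),
    }


@dataclass
class CohortData:
    """An in-memory synthetic cohort (optionally mirrored to disk)."""

    manifest: CohortManifest
    excerpts: list[Excerpt]
    texts: list[str]
    stimuli: dict[str, list[str]]  # stimulus_id -> description tokens
    ground_truth: pd.DataFrame
    lexicon_spec: TopicLexiconSpec
    seed: int


def generate_cohort(
    specs: dict[str, GroupGeneratorSpec] | None = None,
    lexicon_spec: TopicLexiconSpec | None = None,
    seed: int = 0,
    n_stimuli: int = 8,
    task: str = "TAT",
    out_dir: Optional[str | Path] = None,
    lexicon: Optional[EmbeddingLexicon] = None,
) -> CohortData:
    """Generate a full cohort: manifest + transcripts + ground truth.

    Stimuli are the first ``n_stimuli`` lexicon topics, cycled over each
    subject's excerpts. Per-subject RNG streams are spawned from the seed,
    so the cohort is reproducible byte-for-byte. If ``out_dir`` is given,
    transcripts, ``manifest.csv``, ``stimuli.csv`` and ``ground_truth.csv``
    are written in exactly the formats the parsing layer consumes.
    """
    specs = specs if specs is not None else default_group_specs()
    lexicon_spec = lexicon_spec if lexicon_spec is not None else TopicLexiconSpec(seed=seed)
    if n_stimuli > lexicon_spec.n_topics:
        raise ValueError(
            f"n_stimuli={n_stimuli} exceeds n_topics={lexicon_spec.n_topics}"
        )
    worst = max(s.excerpts_per_subject for s in specs.values())
    if worst > n_stimuli:
        raise ValueError(
            f"excerpts_per_subject={worst} exceeds n_stimuli={n_stimuli}: "
            "each subject answers each stimulus at most once"
        )
    if lexicon is None:
        lexicon = make_topic_lexicon(lexicon_spec)

    ss = np.random.SeedSequence(seed)
    subject_keys: list[tuple[str, GroupGeneratorSpec, int]] = []
    for label in specs:
        spec = specs[label]
        for i in range(spec.n_subjects):
            subject_keys.append((f"{label.replace('-', '')}{i:02d}", spec, i))
    children = ss.spawn(len(subject_keys))

    stimuli = {
        f"stim{t}": stimulus_description_tokens(t, lexicon)
        for t in range(n_stimuli)
    }

    rows = []
    excerpts: list[Excerpt] = []
    texts: list[str] = []
    truth_rows = []
    for (sid, spec, _), child in zip(subject_keys, children):
        rng = np.random.default_rng(child)
        cov = {
            name: float(np.round(rng.normal(mu, sd), 1))
            for name, (mu, sd) in _COVARIATE_PARAMS[spec.label].items()
        }
        for e in range(spec.excerpts_per_subject):
            topic = e % n_stimuli
            stim = f"stim{topic}"
            excerpt, text, truth = generate_excerpt(
                spec,
                topic,
                lexicon_spec,
                rng,
                subject_id=sid,
                stimulus_id=stim,
                task=task,
            )
            excerpts.append(excerpt)
            texts.append(text)
            rows.append(
                {
                    "subject_id": sid,
                    "group": spec.label,
                    "task": task,
                    "stimulus_id": stim,
                    "excerpt_path": f"transcripts/{sid}_{stim}.txt",
                    **cov,
                }
            )
            truth_rows.append(
                {
                    "subject_id": sid,
                    "group": spec.label,
                    "stimulus_id": stim,
                    "stimulus_topic": truth.stimulus_topic,
                    "n_sentences": len(truth.sentence_topics),
                    "n_words": truth.n_words,
                    "n_off_stimulus_sentences": sum(
                        t != truth.stimulus_topic for t in truth.sentence_topics
                    ),
                    "n_repetitions": sum(truth.repetition_flags),
                    "n_ambiguous_pronouns": truth.n_ambiguous_pronouns,
                    "n_named_pronouns": truth.n_named_pronouns,
                    "n_inaudible": truth.n_inaudible,
                    "sentence_topics": " ".join(map(str, truth.sentence_topics)),
                }
            )

    manifest = CohortManifest(pd.DataFrame(rows))
    truth_df = pd.DataFrame(truth_rows)
    cohort = CohortData(
        manifest=manifest,
        excerpts=excerpts,
        texts=texts,
        stimuli=stimuli,
        ground_truth=truth_df,
        lexicon_spec=lexicon_spec,
        seed=seed,
    )
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: CohortData, out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "transcripts").mkdir(parents=True, exist_ok=True)
    for row, text in zip(cohort.manifest.rows.itertuples(), cohort.texts):
        (out / row.excerpt_path).write_text(text + "\n", encoding="utf-8")
    cohort.manifest.rows.to_csv(out / "manifest.csv", index=False)
    stim_df = pd.DataFrame(
        {
            "stimulus_id": list(cohort.stimuli),
            "description": [" ".join(toks) for toks in cohort.stimuli.values()],
        }
    )
    stim_df.to_csv(out / "stimuli.csv", index=False)
    cohort.ground_truth.to_csv(out / "ground_truth.csv", index=False)
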