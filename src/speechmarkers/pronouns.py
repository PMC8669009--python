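"""Ambiguous-pronoun counting from coreference structure.

A third-person pronoun is *ambiguous* when its referent is never named
(the pronoun's chain contains no noun at all) or is named only after the
pronoun's first use. Both cases reduce to a single rule on coreference
chains: count the chains whose **first** mention is a third-person pronoun.

The resolver backend is pluggable. The bundled backend is a deterministic
rule-based resolver intended for testing and synthetic data: it links each
third-person pronoun to the nearest preceding gender/number-compatible
name or nominal within a two-sentence window, falls back to the nearest
*following* compatible mention (modelling late naming), and otherwise
leaves the pronoun as a singleton chain. Mismatches yield singletons — a
conservative policy that can only inflate the count. Pleonastic "it"
("it rains") is not detected and leaks into the count; real analyses
should plug in a neural resolver via the JSON interchange adapter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

from .transcripts import Excerpt
from .wordlists import (
    DETERMINERS,
    FEMININE_PRONOUNS,
    MASCULINE_PRONOUNS,
    NEUTER_PRONOUNS,
    PERSON_NAMES,
    PERSON_NOMINALS_PLURAL,
    PERSON_NOMINALS_SINGULAR,
    PLURAL_PRONOUNS,
    STOPWORDS,
    THIRD_PERSON_PRONOUNS,
)

KIND_PRONOUN = "third_person_pronoun"
KIND_OTHER_PRONOUN = "other_pronoun"
KIND_PROPER = "proper_noun"
KIND_NOMINAL = "nominal"

BACKWARD_WINDOW = 2  # sentences before the pronoun's sentence
FORWARD_WINDOW = 1  # sentences after, for late-naming attachment


@dataclass(frozen=True)
class Mention:
    sentence: int
    start: int
    end: int
    surface: str
    kind: str

    @property
    def position(self) -> tuple[int, int]:
        return (self.sentence, self.start)


@dataclass
class CorefChain:
    entity_id: int
    mentions: list[Mention]

    def __post_init__(self) -> None:
        if not self.mentions:
            raise ValueError("empty coreference chain")
        self.mentions = sorted(self.mentions, key=lambda m: m.position)

    @property
    def first(self) -> Mention:
        return self.mentions[0]


@dataclass(frozen=True)
class _Candidate:
    mention: Mention
    gender: str  # m / f / a(ny) / n(euter)
    number: str  # sg / pl
    person: bool


def _pronoun_features(word: str) -> tuple[str, str]:
    if word in MASCULINE_PRONOUNS:
        return "m", "sg"
    if word in FEMININE_PRONOUNS:
        return "f", "sg"
    if word in PLURAL_PRONOUNS:
        return "a", "pl"
    if word in NEUTER_PRONOUNS:
        return "n", "sg"
    raise ValueError(f"not a third-person pronoun: {word!r}")


def _compatible(pron_gender: str, pron_number: str, cand: _Candidate) -> bool:
    if pron_number != cand.number:
        return False
    if pron_gender == "n":
        return not cand.person
    if pron_gender == "a":  # they/them: person groups or plural nouns
        return True
    # gendered singular pronoun: needs a person of matching (or any) gender
    return cand.person and cand.gender in (pron_gender, "a")


def _collect_candidates(excerpt: Excerpt) -> list[_Candidate]:
    cands: list[_Candidate] = []
    for si, sent in enumerate(excerpt.sentences):
        for ti, tok in enumerate(sent):
            if tok in THIRD_PERSON_PRONOUNS:
                continue
            if tok in PERSON_NAMES:
                m = Mention(si, ti, ti + 1, tok, KIND_PROPER)
                cands.append(_Candidate(m, PERSON_NAMES[tok], "sg", True))
            elif tok in PERSON_NOMINALS_SINGULAR:
                m = Mention(si, ti, ti + 1, tok, KIND_NOMINAL)
                cands.append(
                    _Candidate(m, PERSON_NOMINALS_SINGULAR[tok], "sg", True)
                )
            elif tok in PERSON_NOMINALS_PLURAL:
                m = Mention(si, ti, ti + 1, tok, KIND_NOMINAL)
                cands.append(_Candidate(m, "a", "pl", True))
            elif ti > 0 and sent[ti - 1] in DETERMINERS and tok not in STOPWORDS:
                number = "pl" if sent[ti - 1] in ("these", "those") else "sg"
                if tok.endswith("s") and number == "sg" and len(tok) > 3:
                    number = "pl"
                m = Mention(si, ti, ti + 1, tok, KIND_NOMINAL)
                cands.append(_Candidate(m, "n", number, False))
    return cands


def rule_based_backend(excerpt: Excerpt) -> list[CorefChain]:
    """Deterministic rule-based resolver (the bundled test backend)."""
    candidates = _collect_candidates(excerpt)
    # one entity per distinct candidate surface form
    entity_of_surface: dict[str, int] = {}
    next_entity = 0
    entity_mentions: dict[int, list[Mention]] = {}
    cand_entity: list[int] = []
    for c in candidates:
        if c.mention.surface not in entity_of_surface:
            entity_of_surface[c.mention.surface] = next_entity
            entity_mentions[next_entity] = []
            next_entity += 1
        eid = entity_of_surface[c.mention.surface]
        cand_entity.append(eid)
        entity_mentions[eid].append(c.mention)

    pronouns: list[Mention] = []
    for si, sent in enumerate(excerpt.sentences):
        for ti, tok in enumerate(sent):
            if tok in THIRD_PERSON_PRONOUNS:
                pronouns.append(Mention(si, ti, ti + 1, tok, KIND_PRONOUN))

    deferred: list[Mention] = []
    for pm in pronouns:
        g, n = _pronoun_features(pm.surface)
        best = None
        for c, eid in zip(candidates, cand_entity):
            cm = c.mention
            if cm.position >= pm.position:
                continue
            if cm.sentence < pm.sentence - BACKWARD_WINDOW:
                continue
            if not _compatible(g, n, c):
                continue
            if best is None or cm.position > best[0].position:
                best = (cm, eid)
        if best is not None:
            entity_mentions[best[1]].append(pm)
        else:
            deferred.append(pm)

    for pm in deferred:
        g, n = _pronoun_features(pm.surface)
        best = None
        for c, eid in zip(candidates, cand_entity):
            cm = c.mention
            if cm.position <= pm.position:
                continue
            if cm.sentence > pm.sentence + FORWARD_WINDOW:
                continue
            if not _compatible(g, n, c):
                continue
            if best is None or cm.position < best[0].position:
                best = (cm, eid)
        if best is not None:
            entity_mentions[best[1]].append(pm)
        else:
            entity_mentions[next_entity] = [pm]
            next_entity += 1

    return [
        CorefChain(entity_id=eid, mentions=ms)
        for eid, ms in sorted(entity_mentions.items())
        if ms
    ]


def chains_from_json(data: str | Path | dict) -> list[CorefChain]:
    """Load externally computed chains from the JSON interchange schema.

    Schema: ``{"chains": [{"entity_id": int, "mentions": [{"sentence": int,
    "start": int, "end": int, "surface": str, "kind": str}, ...]}, ...]}``.
    """
    if isinstance(data, (str, Path)):
        data = json.loads(Path(data).read_text(encoding="utf-8"))
    chains = []
    for ch in data["chains"]:
        mentions = [Mention(**m) for m in ch["mentions"]]
        chains.append(CorefChain(entity_id=ch["entity_id"], mentions=mentions))
    return chains


Backend = Callable[[Excerpt], list[CorefChain]]


def resolve_coreference(
    excerpt: Excerpt, backend: str | Backend = "rule"
) -> list[CorefChain]:
    """Resolve coreference with the chosen backend.

    ``backend`` is ``"rule"`` (bundled fallback) or any callable mapping an
    :class:`Excerpt` to chains (the adapter contract). Every third-person
    pronoun token is guaranteed to appear in some chain (unresolved pronouns
    become singletons).
    """
    if backend == "rule":
        fn: Backend = rule_based_backend
        name = "rule"
    elif callable(backend):
        fn = backend
        name = getattr(backend, "__name__", repr(backend))
    else:
        raise ValueError(f"unknown coreference backend {backend!r}")
    try:
        return fn(excerpt)
    except Exception as exc:  # surface backend identity per contract
        raise RuntimeError(f"coreference backend {name!r} failed: {exc}") from exc


def count_ambiguous_pronouns(chains: Sequence[CorefChain]) -> int:
    """Number of chains whose first mention is a third-person pronoun."""
    return sum(1 for ch in chains if ch.first.kind == KIND_PRONOUN)


def ambiguous_pronoun_count(
    excerpt: Excerpt, backend: str | Backend = "rule"
) -> int:
    return count_ambiguous_pronouns(resolve_coreference(excerpt, backend))
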