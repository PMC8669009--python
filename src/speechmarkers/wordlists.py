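"""Bundled word lists: stopwords, fillers, and the small person/name lexicon
used by the rule-based coreference fallback.

The stopword list is a static snapshot of the standard English stopword corpus
(179 entries) so that preprocessing is reproducible without any download. Both
lists are plain Python sets and are passed explicitly into the preprocessing
functions, so callers can substitute their own.
"""

from __future__ import annotations

# fmt: off
STOPWORDS: frozenset[str] = frozenset({
    "i", "me", "my", "myself", "we", "our", "ours", "ourselves", "you",
    "you're", "you've", "you'll", "you'd", "your", "yours", "yourself",
    "yourselves", "he", "him", "his", "himself", "she", "she's", "her",
    "hers", "herself", "it", "it's", "its", "itself", "they", "them",
    "their", "theirs", "themselves", "what", "which", "who", "whom",
    "this", "that", "that'll", "these", "those", "am", "is", "are", "was",
    "were", "be", "been", "being", "have", "has", "had", "having", "do",
    "does", "did", "doing", "a", "an", "the", "and", "but", "if", "or",
    "because", "as", "until", "while", "of", "at", "by", "for", "with",
    "about", "against", "between", "into", "through", "during", "before",
    "after", "above", "below", "to", "from", "up", "down", "in", "out",
    "on", "off", "over", "under", "again", "further", "then", "once",
    "here", "there", "when", "where", "why", "how", "all", "any", "both",
    "each", "few", "more", "most", "other", "some", "such", "no", "nor",
    "not", "only", "own", "same", "so", "than", "too", "very", "s", "t",
    "can", "will", "just", "don", "don't", "should", "should've", "now",
    "d", "ll", "m", "o", "re", "ve", "y", "ain", "aren", "aren't",
    "couldn", "couldn't", "didn", "didn't", "doesn", "doesn't", "hadn",
    "hadn't", "hasn", "hasn't", "haven", "haven't", "isn", "isn't", "ma",
    "mightn", "mightn't", "mustn", "mustn't", "needn", "needn't", "shan",
    "shan't", "shouldn", "shouldn't", "wasn", "wasn't", "weren",
    "weren't", "won", "won't", "wouldn", "wouldn't",
})
# fmt: on

# Versioned filler list (v1). Multi-word fillers are removed as token bigrams
# before single-token filtering. "like" is included deliberately: transcribed
# spontaneous speech uses it overwhelmingly as a discourse filler.
FILLERS: frozenset[str] = frozenset({
    "um", "uh", "er", "erm", "ah", "eh", "hm", "hmm", "mm", "mhm", "huh",
    "yeah", "yep", "okay", "ok", "like", "you know", "i mean",
})

# --- coreference fallback lexicon ------------------------------------------

THIRD_PERSON_PRONOUNS: frozenset[str] = frozenset({
    "he", "him", "his", "she", "her", "hers",
    "they", "them", "their", "theirs", "it", "its",
})

MASCULINE_PRONOUNS = frozenset({"he", "him", "his"})
FEMININE_PRONOUNS = frozenset({"she", "her", "hers"})
PLURAL_PRONOUNS = frozenset({"they", "them", "their", "theirs"})
NEUTER_PRONOUNS = frozenset({"it", "its"})

# Given names with grammatical gender, for antecedent matching. Deliberately
# small: the fallback is a deterministic test backend, not a real resolver.
PERSON_NAMES: dict[str, str] = {
    "john": "m", "james": "m", "peter": "m", "david": "m", "tom": "m",
    "michael": "m", "paul": "m", "george": "m", "harry": "m", "jack": "m",
    "mary": "f", "sarah": "f", "anna": "f", "emma": "f", "lucy": "f",
    "jane": "f", "alice": "f", "susan": "f", "laura": "f", "kate": "f",
}

# Person-denoting common nouns: gender in {m, f, a(ny)}.
PERSON_NOMINALS_SINGULAR: dict[str, str] = {
    "man": "m", "boy": "m", "father": "m", "brother": "m", "son": "m",
    "guy": "m", "husband": "m", "uncle": "m",
    "woman": "f", "girl": "f", "mother": "f", "sister": "f",
    "daughter": "f", "lady": "f", "wife": "f", "aunt": "f",
    "friend": "a", "person": "a", "child": "a", "doctor": "a",
    "teacher": "a", "neighbour": "a", "neighbor": "a", "stranger": "a",
    "farmer": "a", "worker": "a", "student": "a",
}

PERSON_NOMINALS_PLURAL: frozenset[str] = frozenset({
    "men", "women", "boys", "girls", "people", "friends", "children",
    "parents", "brothers", "sisters", "neighbours", "neighbors",
    "students", "workers", "family", "couple",
})

DETERMINERS: frozenset[str] = frozenset({
    "the", "a", "an", "this", "that", "these", "those",
})
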