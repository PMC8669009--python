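"""Profile one transcribed response with a toy embedding lexicon.

Builds a tiny 2-topic lexicon, parses a short transcript with an inaudible
marker, and prints the embedding-based markers plus surface counts.
"""

import numpy as np

from speechmarkers import (
    TopicLexiconSpec,
    embed_sentences,
    inaudible_rate,
    make_topic_lexicon,
    max_similarity,
    on_topic,
    parse_excerpt,
    preprocess_tokens,
    semantic_coherence,
    sif_embed,
    tangentiality,
)
from speechmarkers.synthetic import stimulus_description_tokens

lexicon = make_topic_lexicon(
    TopicLexiconSpec(n_topics=2, words_per_topic=10, dim=16, seed=0)
)

# a transcript that starts on the stimulus topic (topic 0) and drifts to
# topic 1; [?] marks an inaudible span
text = (
    "The t0w0 sat near the t0w1 and the t0w2. "
    "The t0w3 was [?] with the t0w4. "
    "Then the t1w0 came with the t1w1. "
    "The t1w2 took the t1w3 away."
)
excerpt = parse_excerpt(text, subject_id="demo", task="TAT")
vectors = embed_sentences(preprocess_tokens(excerpt), lexicon)
stimulus = sif_embed(stimulus_description_tokens(0, lexicon), lexicon)

print(f"sentences:          {excerpt.n_sentences}")
print(f"words:              {excerpt.n_words_raw}")
print(f"words/sentence:     {excerpt.mean_sentence_length:.2f}")
print(f"inaudible per word: {inaudible_rate(excerpt):.3f}")
print(f"semantic coherence: {semantic_coherence(vectors):.3f}")
print(f"on-topic score:     {on_topic(vectors, stimulus):.3f}")
print(f"tangentiality:      {tangentiality(vectors, stimulus):.3f}")
print(f"max similarity:     {max_similarity(vectors):.3f}")
print()
print("The response drifts from the stimulus topic to another topic, so the")
print("on-topic score is moderate and the tangentiality slope is negative")
print("(similarity to the stimulus declines over sentence index).")
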