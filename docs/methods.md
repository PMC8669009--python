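# Methods

This note documents the models and procedures implemented in
`speechmarkers`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions that a
user reproducing or extending an analysis needs to know.

## Transcript model and preprocessing

A transcript is UTF-8 text; `[?]` marks an inaudible span and optional
`[PROMPT]` lines mark interviewer prompts (both are counted, then removed).
Sentences are segmented on terminal punctuation `. ! ?` by default; a
per-line mode treats each line as one utterance, for transcribers who
delimit by line. A transcript with no terminal punctuation is one sentence.
Tokens are whitespace-split, lowercased, and stripped of surrounding
punctuation; hyphens and internal apostrophes are kept so tokens match
bag-of-words embedding vocabularies.

Surface measures (N_word, N_sent, words/sentence) are computed on the raw
token stream *before* content filtering. Embedding measures use a content
view with stopwords (a bundled 179-entry snapshot of the standard English
stopword list) and fillers (a versioned list: um, uh, er, erm, ah, eh, hm,
hmm, mm, mhm, huh, yeah, yep, okay, ok, like, "you know", "i mean")
removed; both lists are explicit inputs and can be replaced. Sentences
emptied by filtering stay in place as empties — they still count in N_sent
but are excluded from embedding-based measures, and sentence indices for
the tangentiality regression are renumbered over the surviving sentences.

## Sentence embeddings

Words map to d-dimensional vectors (word2vec text format). A sentence
vector is the smooth-inverse-frequency weighted mean over in-vocabulary
content tokens, weight a/(a+p(w)) with a = 1e-3 (the SIF method's
recommended default; config-exposed) and p(w) the corpus unigram
probability from a supplied frequency table — deliberately *not*
re-estimated from the analysed cohort, which is far too small for stable
unigram estimates. Words missing from the frequency table get the smallest
observed probability (treated as maximally rare, hence maximally
weighted). Out-of-vocabulary tokens are skipped; a sentence with no
in-vocabulary token is flagged *degenerate* and propagates as missing,
never as a zero similarity.

The SIF correction removes the leading right-singular direction of the
stacked sentence vectors. The batch is **all sentence vectors of one
cohort × task run, stimulus-description vectors included**, so stimulus
and response vectors live in the same corrected space. Per-excerpt removal
was rejected: 2–3 sentence responses make the singular direction estimate
unstable. With fewer than two non-degenerate vectors the batch is returned
unchanged.

## The four coherence-family measures

- **Semantic coherence**: mean cosine between adjacent sentence vectors
  (degenerate sentences dropped before adjacency pairing).
- **Tangentiality**: OLS slope of sentence-to-stimulus cosine on sentence
  index 0,1,2,…. Sentence index, not word position, is the time axis. Note
  the slope is not confined to [−1, 1]: a two-sentence response whose
  similarity flips sign can reach ±2; the property tests assert the true
  bound |slope| ≤ 2 and the statistic is not clipped.
- **On-topic score**: mean sentence-to-stimulus cosine.
- **Maximum similarity**: maximum cosine over unordered sentence pairs;
  1.0 means two sentences embed identically (verbatim or near-verbatim
  repetition). Known saturation: for long excerpts the maximum over many
  pairs approaches 1 even without pathological repetition.

Stimulus-dependent measures are missing (NaN) when no a-priori stimulus
description is available — free speech by design, or an absent description
file. Missingness is explicit end to end: a measure is missing at subject
level only if missing in all of the subject's excerpts.

## Ambiguous pronouns

A third-person pronoun (he, him, his, she, her, hers, they, them, their,
theirs, it, its) is *ambiguous* if the first mention in its coreference
chain is a pronoun — covering both "never named" (singleton chain) and
"named only after first use" (pronoun-first chain). The excerpt score is
the raw count; a per-word rate is emitted as a secondary column.

The resolver backend is pluggable (adapter contract: excerpt in, chains
out; a JSON interchange schema accepts externally computed chains). The
bundled backend is a deterministic rule-based fallback: nearest preceding
gender/number-compatible name or person nominal within a two-sentence
window; failing that, the nearest *following* compatible mention within
one sentence (modelling late naming); otherwise a singleton chain. Its
name/nominal lexicon is small and its mismatches yield singletons — a
conservative bias that can only inflate the count, and pleonastic "it"
("it rains") leaks in. It exists so the pipeline is fully testable offline;
substantive analyses should plug in a neural resolver.

## Speech graphs

One graph per response over the whole excerpt's word sequence (sentence
boundaries ignored, stopwords retained — graphing all spoken words; a
config flag restricts to content words). Nodes are unique words, directed
edges link consecutively spoken word pairs; self-loops are retained but
cannot affect component sizes. LCC and LSC are node counts of the largest
weakly and strongly connected components (computed with compiled
connected-components routines; exactness is verified against union-find
and pairwise-reachability oracles).

LCCr/LSCr divide LCC/LSC by their means over uniform permutations of the
word multiset, graphed by the same rule — a *ratio* normalisation (values
near 1 mean connectivity is what the word multiset alone produces),
chosen over a z-score; n_shuffles defaults to 1000, which stabilises the
ratios to about two decimals for typical 150-word excerpts. The shuffle
stream is seeded per excerpt from the run seed. Excerpts are never
concatenated; subject values are means over per-excerpt metrics.

## Statistical harness

- **Aggregation**: unweighted mean per measure over a subject's excerpts,
  skipping missing excerpt values (subjects with partial data are included
  with what they have).
- **Normality**: Shapiro–Wilk (n ≥ 3, non-constant input required).
- **Group contrasts**: two-sided Mann–Whitney U via midranks, reported as
  the tie-corrected normal-approximation Z without continuity correction;
  sign fixed so Z > 0 when the first-listed group stochastically exceeds
  the second. Fully tied data give Z = 0, p = 1. The uncorrected normal
  approximation estimates the exact two-sided *mid-p* (half weight on
  equally extreme assignments); the exact enumeration oracle therefore
  defaults to the mid-p convention, under which the off-centre
  disagreement is at most 0.0194 for 5–8 subjects per group (verified over
  every achievable U). Groups with fewer than 2 subjects are marked not
  computable rather than dropped.
- **Inter-measure associations**: OLS of marker j on marker i plus group
  indicator columns; the reported statistic is the T of the marker-i
  coefficient; an edge list thresholds the pair matrix at p < 0.01.
- **Covariate sensitivity**: gamma GLM with log link on the mean and
  constant dispersion — a deliberate reduction of a full
  location-scale-shape model, which these cohort sizes cannot support; the
  reported effect is λ = exp(group coefficient), the multiplicative effect
  on the mean. Markers with non-positive values (tangentiality, coherence
  can be ≤ 0) are shifted by a recorded affine constant to reach positive
  support; contrasts that cannot be fit are reported "model not
  applicable", never silently dropped.
- **FDR**: Benjamini–Hochberg step-up; the family size m is an explicit
  argument and may exceed the number of supplied p-values (e.g. 96 for a
  12-marker × 8-covariate association family). Primary contrast tables
  report raw p.
- **Speech-profile (spider) display**: per-marker min–max scaling over the
  cohort to [0,1] (config-overridable; constant markers map to 0.5).

## Synthetic data: what it emulates, what it does not

The generator produces the 3-group study conditions: 13/25/16 subjects
(CON/CHR-P/FEP) with 8 excerpts each by default, per-subject covariates
(IQ, years of education, digit span) drawn around the group-level means of
the emulated population, and group-graded disorganisation:

| parameter | CON | CHR-P | FEP | targeted marker |
|---|---|---|---|---|
| off_topic_rate | 0.05 | 0.15 | 0.30 | on-topic ↓ |
| drift_rate | 0.02 | 0.06 | 0.12 | tangentiality ↓ |
| repetition_rate | 0.03 | 0.06 | 0.10 | max similarity ↑ |
| vocab_breadth | 1.0 | 0.50 | 0.25 | LCC ↓ |
| mean sentences | 9 | 9 | 11 | N_sent ↑ |
| mean content words/sentence | 7 | 6.5 | 5 | sentence length ↓ |
| pronoun_ambiguity_rate | 0.02 | 0.04 | 0.06 | ambiguous pronouns ↑ |
| inaudible_rate | 0.010 | 0.020 | 0.018 | inaudible/word |

Mechanics: topic centroids are near-orthogonal unit vectors (orthonormal
when n_topics ≤ d); word vectors are unit-normalised centroid + Gaussian
(σ = 0.35) perturbations; frequencies are Zipfian over a topic-interleaved
global ranking. Sentences are bags of topic words on a function-word
scaffold ("the X Y the Z …"), so graphs, embeddings and the pronoun
counter are all exercised by one generator. Topic dynamics separate two
failure modes: *off-topic* is an i.i.d. jump to a random other topic
(on-topic-sensitive), *drift* is a ±1 random walk on a topic ring
(tangentiality-sensitive). Repetition verbatim-copies an earlier sentence.
`vocab_breadth` restricts each topic to its first fraction of words — the
gradient is steep (1.0/0.50/0.25) because it must dominate the vocabulary
*inflation* that off-topic jumps cause, or connectivity would rise, not
fall, with disorganisation. Ambiguous-pronoun insertions are
pronoun-first mentions ("they saw …") that never get named; a fixed
low rate of resolvable name+pronoun sentences is added in all groups.
Every latent choice (sentence topics, repetition flags, insertions,
inaudible markers) is recorded in a ground-truth table, and all artifacts
are pure functions of the seed.

What it does **not** emulate — and hence what passing tests do not show
about real data: syntax and discourse structure (sentences are bags of
words), lexical semantics beyond topic geometry, realistic coreference
(only the inserted patterns), speaker disfluency structure, transcription
error beyond uniform `[?]` insertion. Two known artefacts: the
function-word scaffold makes connectivity largely order-insensitive, so
LCCr/LSCr hover near 1 in all groups and carry little group signal here
(unlike LCC/LSC); and with near-orthogonal topics a single drift step
fully decorrelates a sentence from the stimulus, so the tangentiality
response saturates once about one step is expected per response — the
recovery experiments therefore probe drift in its responsive regime,
0–0.1 per sentence.

## Validation experiments and problem sizes

All sizes below are the package's own choices, fixed in code:

- **Measure oracles**: 200 generated excerpts; the four coherence-family
  measures match explicit-loop/hand-OLS oracles to 1e-10.
- **Graph oracles**: 500 random sequences (≤ 50 tokens, ≤ 20-word
  vocabulary); LCC/LSC match union-find and Floyd–Warshall reachability
  exactly; LCCr = 1 exactly for all-distinct-word sequences.
- **Null calibration**: 2000 synthetic cohorts, identical generator
  parameters in all three groups, 15 subjects/group × 2 excerpts
  (6 sentences, d = 8 lexicon, uncorrected SIF vectors — the correction is
  immaterial to test calibration and skipping it keeps the grid cheap);
  rejection rate of the 6 contrasts per cohort is checked against the
  nominal 5%.
- **Exact-enumeration agreement**: 50 random continuous samples at 6–8
  subjects per group; max |asymptotic p − mid-p| < 0.02.
- **Monotone recovery**: 6-point grid per parameter × 50 subjects × 8
  excerpts (12 sentences, ~8 content words), Spearman |ρ| > 0.9 between
  each parameter and its targeted marker.
- **Gamma recovery**: true multiplicative effect 0.8, gamma shape 5,
  25 subjects/group, 200 replicates; the mean λ̂ lands in [0.72, 0.88].
- **Determinism**: the full simulate → profile → compare chain run twice
  with one config yields byte-identical CSVs.

`scripts/acceptance.py` re-runs all of these from scratch (calibration at
500 cohorts there, to keep the script short) plus the default graded
cohort (n_shuffles = 300 for the graph normalisation in that run) and
writes the resulting numbers as JSON.

## Limitations

The generator validates the *machinery* — estimator correctness,
calibration, recovery, determinism — not clinical validity; effect sizes
on synthetic cohorts say nothing about effect sizes in patients. The
rule-based coreference fallback is a test scaffold with documented biases.
The SIF first-component batch (cohort × task) is one defensible choice
among several (per task vs per cohort); results can shift slightly with
the batch definition, so it is recorded in every run summary. Sentence
segmentation of unpunctuated transcripts collapses to one sentence, which
zeroes adjacency-based measures' information; use per-line mode for such
transcripts.
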