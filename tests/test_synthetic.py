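"""The synthetic lexicon and cohort generator: geometry, dynamics, determinism."""

import numpy as np
import pytest

from speechmarkers.lexicon import cosine
from speechmarkers.coherence import max_similarity, on_topic
from speechmarkers.lexicon import embed_sentences, sif_embed
from speechmarkers.pronouns import ambiguous_pronoun_count
from speechmarkers.synthetic import (
    GroupGeneratorSpec,
    TopicLexiconSpec,
    default_group_specs,
    generate_cohort,
    generate_excerpt,
    make_topic_lexicon,
    stimulus_description_tokens,
)
from speechmarkers.transcripts import parse_excerpt, preprocess_tokens, read_manifest


def _spec(**over):
    base = dict(label="CON", n_subjects=2, excerpts_per_subject=2)
    base.update(over)
    return GroupGeneratorSpec(**base)


class TestTopicLexicon:
    def test_within_topic_tighter_than_between(self):
        lex = make_topic_lexicon(
            TopicLexiconSpec(n_topics=2, words_per_topic=5, dim=8, seed=0)
        )
        within, between = [], []
        words = list(lex.vectors)
        for i, wi in enumerate(words):
            for wj in words[i + 1:]:
                c = cosine(lex.vectors[wi], lex.vectors[wj])
                (within if wi[:2] == wj[:2] else between).append(c)
        assert np.mean(within) > np.mean(between)

    def test_zero_noise_collapses_to_centroid(self):
        lex = make_topic_lexicon(
            TopicLexiconSpec(n_topics=2, words_per_topic=4, dim=6,
                             sigma_topic=0.0, seed=0)
        )
        assert cosine(lex.vectors["t0w0"], lex.vectors["t0w3"]) == pytest.approx(1.0)

    def test_same_seed_bit_identical(self):
        spec = TopicLexiconSpec(n_topics=3, words_per_topic=6, dim=8, seed=4)
        l1, l2 = make_topic_lexicon(spec), make_topic_lexicon(spec)
        for w in l1.vectors:
            np.testing.assert_array_equal(l1.vectors[w], l2.vectors[w])
        assert l1.frequencies == l2.frequencies

    def test_frequencies_are_zipfian_and_normalised(self):
        lex = make_topic_lexicon(
            TopicLexiconSpec(n_topics=2, words_per_topic=10, dim=6, seed=1)
        )
        ps = sorted(lex.frequencies.values(), reverse=True)
        assert sum(ps) == pytest.approx(1.0)
        assert ps[0] > ps[-1]

    def test_overcrowded_topics_warn(self):
        with pytest.warns(UserWarning, match="overlap"):
            make_topic_lexicon(
                TopicLexiconSpec(n_topics=40, words_per_topic=2, dim=4, seed=0)
            )

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            TopicLexiconSpec(n_topics=0)


class TestGenerateExcerpt:
    LEX_SPEC = TopicLexiconSpec(n_topics=4, words_per_topic=12, dim=10, seed=11)

    def test_degenerate_dynamics_stay_on_stimulus_topic(self, topic_lexicon):
        spec = _spec(off_topic_rate=0.0, drift_rate=0.0, repetition_rate=0.0,
                     pronoun_ambiguity_rate=0.0)
        rng = np.random.default_rng(0)
        _, _, truth = generate_excerpt(spec, 1, self.LEX_SPEC, rng)
        assert all(t == 1 for t in truth.sentence_topics)

    def test_on_topic_maximal_without_disorganisation(self, topic_lexicon):
        stim = sif_embed(stimulus_description_tokens(0, topic_lexicon), topic_lexicon)

        def mean_on_topic(off_rate, seed):
            rng = np.random.default_rng(seed)
            vals = []
            for _ in range(30):
                exc, _, _ = generate_excerpt(
                    _spec(off_topic_rate=off_rate, drift_rate=0.0), 0,
                    self.LEX_SPEC, rng,
                )
                vs = embed_sentences(preprocess_tokens(exc), topic_lexicon)
                vals.append(on_topic(vs, stim))
            return np.nanmean(vals)

        assert mean_on_topic(0.0, 1) > mean_on_topic(0.6, 1)

    def test_forced_repetition_gives_max_similarity_one(self, topic_lexicon):
        spec = _spec(repetition_rate=1.0, pronoun_ambiguity_rate=0.0)
        rng = np.random.default_rng(2)
        exc, _, truth = generate_excerpt(spec, 0, self.LEX_SPEC, rng)
        assert any(truth.repetition_flags)
        vs = embed_sentences(preprocess_tokens(exc), topic_lexicon)
        assert max_similarity(vs) == pytest.approx(1.0)

    def test_inaudible_rate_binomial(self):
        spec = _spec(inaudible_rate=0.1, mean_sentences=10, mean_content_words=8)
        rng = np.random.default_rng(3)
        rates = []
        for _ in range(500):
            exc, _, _ = generate_excerpt(spec, 0, self.LEX_SPEC, rng)
            rates.append(exc.n_inaudible / exc.n_words_raw)
        assert 0.08 <= np.mean(rates) <= 0.12

    def test_transcript_text_reparses_identically(self):
        spec = _spec(inaudible_rate=0.05, pronoun_ambiguity_rate=0.2)
        rng = np.random.default_rng(4)
        exc, text, _ = generate_excerpt(spec, 0, self.LEX_SPEC, rng)
        again = parse_excerpt(text, exc.subject_id, exc.task, exc.stimulus_id)
        assert again.sentences == exc.sentences
        assert again.n_inaudible == exc.n_inaudible

    def test_inserted_pronouns_detected_by_fallback(self):
        spec = _spec(pronoun_ambiguity_rate=0.5, repetition_rate=0.0,
                     mean_sentences=10)
        rng = np.random.default_rng(5)
        for _ in range(10):
            exc, _, truth = generate_excerpt(spec, 0, self.LEX_SPEC, rng)
            assert ambiguous_pronoun_count(exc) == truth.n_ambiguous_pronouns

    def test_rate_validation(self):
        with pytest.raises(ValueError, match="off_topic_rate"):
            _spec(off_topic_rate=1.5)
        with pytest.raises(ValueError, match="vocab_breadth"):
            _spec(vocab_breadth=0.0)


class TestGenerateCohort:
    def test_bookkeeping_sizes(self):
        specs = default_group_specs()
        cohort = generate_cohort(specs, seed=1, n_stimuli=8)
        assert len(cohort.manifest) == (13 + 25 + 16) * 8
        assert cohort.manifest.subjects.shape[0] == 54
        assert len(cohort.ground_truth) == len(cohort.manifest)

    def test_deterministic_artifacts(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(seed=9, out_dir=d1)
        generate_cohort(seed=9, out_dir=d2)
        for name in ("manifest.csv", "stimuli.csv", "ground_truth.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
        t1 = sorted(p.name for p in (d1 / "transcripts").iterdir())
        for name in t1[:5]:
            assert (d1 / "transcripts" / name).read_bytes() == (
                d2 / "transcripts" / name
            ).read_bytes()

    def test_written_cohort_reads_back(self, tmp_path):
        generate_cohort(seed=2, out_dir=tmp_path)
        m = read_manifest(tmp_path / "manifest.csv")
        assert len(m) == 54 * 8
        first = m.rows.iloc[0]
        exc = parse_excerpt(
            (tmp_path / first.excerpt_path).read_text(),
            first.subject_id,
            first.task,
        )
        assert exc.n_sentences >= 2

    def test_graded_ordering_recovered_in_medians(self):
        """Group-graded off-topic rates surface as ordered on-topic scores."""
        from speechmarkers.pipeline import RunConfig, profile_cohort

        specs = {
            k: GroupGeneratorSpec(
                label=k, n_subjects=6, excerpts_per_subject=3,
                off_topic_rate=r, mean_sentences=7, mean_content_words=6,
            )
            for k, r in (("CON", 0.02), ("CHR-P", 0.25), ("FEP", 0.55))
        }
        cohort = generate_cohort(
            specs,
            lexicon_spec=TopicLexiconSpec(n_topics=6, words_per_topic=15,
                                          dim=12, seed=3),
            seed=3,
            n_stimuli=3,
        )
        _, sdf = profile_cohort(cohort, config=RunConfig(n_shuffles=25, seed=3))
        med = sdf.groupby("group")["on_topic"].median()
        assert med["CON"] > med["CHR-P"] > med["FEP"]

    def test_ground_truth_audit_columns_complete(self):
        cohort = generate_cohort(seed=5)
        gt = cohort.ground_truth
        assert (gt["n_sentences"] > 0).all()
        assert (
            gt["sentence_topics"].str.split().str.len() == gt["n_sentences"]
        ).all()
        assert (gt["n_repetitions"] >= 0).all()

    def test_too_many_stimuli_rejected(self):
        with pytest.raises(ValueError, match="n_stimuli"):
            generate_cohort(
                lexicon_spec=TopicLexiconSpec(n_topics=4, seed=0),
                seed=0,
                n_stimuli=8,
            )
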