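"""End-to-end orchestration: cohort -> per-excerpt markers -> per-subject
profiles -> group statistics.

The twelve markers per excerpt: word count, sentence count, mean sentence
length, semantic coherence, tangentiality, on-topic score, maximum
similarity, ambiguous-pronoun count, and the four speech-graph measures
(LCC, LSC, LCCr, LSCr); plus the inaudible-markers-per-word rate.

SIF first-component removal is a batch operation: the leading singular
direction is estimated over all sentence vectors of one cohort x task batch
(stimulus-description vectors included) and removed from every vector in
that batch. Per-excerpt removal would be unstable for 2-3 sentence
responses.

Every run is a pure function of the configuration (paths, SIF parameter,
shuffle count, seeds, backend choices); reruns produce byte-identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .coherence import (
    StimulusDescription,
    max_similarity,
    on_topic,
    read_stimuli,
    semantic_coherence,
    tangentiality,
)
from .lexicon import (
    DEFAULT_SIF_A,
    EmbeddingLexicon,
    embed_sentences,
    load_lexicon,
    remove_first_component,
    sif_embed,
)
from .pronouns import ambiguous_pronoun_count
from .graphs import DEFAULT_N_SHUFFLES, normalized_connectivity
from .stats import (
    GROUP_PAIRS,
    MEASURES,
    aggregate_subject,
    association_matrix,
    compare_groups,
    gamma_adjusted_model,
    normalize_profiles,
)
from .synthetic import CohortData, make_topic_lexicon
from .transcripts import (
    CohortManifest,
    Excerpt,
    inaudible_rate,
    preprocess_tokens,
    read_excerpt_file,
    read_manifest,
)

DEFAULT_COVARIATES = ("inaudible_per_word", "IQ", "years_education", "digit_span")


@dataclass
class RunConfig:
    """Single source of truth for a pipeline run."""

    manifest: Optional[str] = None
    lexicon: Optional[str] = None
    frequencies: Optional[str] = None
    stimuli: Optional[str] = None
    output_dir: str = "speechmarkers_out"
    sif_a: float = DEFAULT_SIF_A
    n_shuffles: int = DEFAULT_N_SHUFFLES
    seed: int = 0
    sentence_mode: str = "punct"
    coref_backend: str = "rule"
    spider_normalization: str = "minmax"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    strict: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load config from YAML or JSON (both accepted)."""
        text = Path(path).read_text(encoding="utf-8")
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            data = yaml.safe_load(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "covariates" in data:
            data["covariates"] = tuple(data["covariates"])
        return cls(**data)


def _corrected_vectors(
    excerpts: Sequence[Excerpt],
    lexicon: EmbeddingLexicon,
    stimuli: dict[str, StimulusDescription] | dict[str, Sequence[str]] | None,
):
    """SIF-embed all sentences, remove the batch first component per task.

    Returns (per-excerpt corrected vector lists, per-task corrected stimulus
    vectors keyed (task, stimulus_id)).
    """
    stim_vectors: dict[str, object] = {}
    if stimuli:
        for sid, desc in stimuli.items():
            if isinstance(desc, StimulusDescription):
                stim_vectors[sid] = desc.vector
            else:  # raw token sequence
                content = preprocess_tokens([list(desc)])[0]
                stim_vectors[sid] = sif_embed(content, lexicon)

    tasks = sorted({e.task for e in excerpts})
    exc_vectors: list[list] = [None] * len(excerpts)  # type: ignore[list-item]
    stim_corrected: dict[tuple[str, str], object] = {}
    for task in tasks:
        idxs = [i for i, e in enumerate(excerpts) if e.task == task]
        batch = []
        spans = []
        for i in idxs:
            content = preprocess_tokens(excerpts[i])
            vs = embed_sentences(content, lexicon)
            spans.append((i, len(batch), len(batch) + len(vs)))
            batch.extend(vs)
        stim_ids = sorted(
            {e.stimulus_id for e in (excerpts[i] for i in idxs) if e.stimulus_id}
            & set(stim_vectors)
        ) if task != "FREE" else []
        stim_start = len(batch)
        batch.extend(stim_vectors[s] for s in stim_ids)
        corrected = remove_first_component(batch)
        for i, lo, hi in spans:
            exc_vectors[i] = corrected[lo:hi]
        for off, s in enumerate(stim_ids):
            stim_corrected[(task, s)] = corrected[stim_start + off]
    return exc_vectors, stim_corrected


def profile_excerpts(
    excerpts: Sequence[Excerpt],
    lexicon: EmbeddingLexicon,
    stimuli: dict | None = None,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
    coref_backend: str = "rule",
    compute_graphs: bool = True,
    compute_pronouns: bool = True,
) -> pd.DataFrame:
    """All markers for each excerpt; one row per excerpt.

    Stimulus-dependent measures (tangentiality, on-topic) are NaN for
    excerpts without a usable stimulus description (e.g. free speech).
    Graph randomisation streams are spawned per excerpt from ``seed``.
    """
    exc_vectors, stim_corrected = _corrected_vectors(excerpts, lexicon, stimuli)
    children = np.random.SeedSequence(seed).spawn(len(excerpts))
    rows = []
    for i, exc in enumerate(excerpts):
        vs = exc_vectors[i]
        stim_vec = stim_corrected.get((exc.task, exc.stimulus_id))
        row = {
            "subject_id": exc.subject_id,
            "task": exc.task,
            "stimulus_id": exc.stimulus_id,
            "n_word": exc.n_words_raw,
            "n_sentence": exc.n_sentences,
            "sentence_length": exc.mean_sentence_length,
            "coherence": semantic_coherence(vs),
            "tangentiality": (
                tangentiality(vs, stim_vec) if stim_vec is not None else float("nan")
            ),
            "on_topic": (
                on_topic(vs, stim_vec) if stim_vec is not None else float("nan")
            ),
            "max_similarity": max_similarity(vs),
            "inaudible_per_word": inaudible_rate(exc),
            "n_degenerate_sentences": sum(v.degenerate for v in vs),
        }
        if compute_pronouns:
            row["ambiguous_pronouns"] = ambiguous_pronoun_count(exc, coref_backend)
            row["ambiguous_pronouns_per_word"] = (
                row["ambiguous_pronouns"] / exc.n_words_raw
            )
        if compute_graphs:
            rng = np.random.default_rng(children[i])
            m = normalized_connectivity(
                exc.word_sequence(), n_shuffles=n_shuffles, seed=rng
            )
            row.update(lcc=m.lcc, lsc=m.lsc, lccr=m.lccr, lscr=m.lscr)
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_profiles(
    excerpt_df: pd.DataFrame,
    subjects: pd.DataFrame,
    measures: Sequence[str] = MEASURES,
) -> pd.DataFrame:
    """Per-subject speech profiles: mean over available excerpt values."""
    extra = [
        c
        for c in ("inaudible_per_word", "ambiguous_pronouns_per_word")
        if c in excerpt_df.columns
    ]
    cols = [m for m in measures if m in excerpt_df.columns] + extra
    rows = []
    for sid, grp in excerpt_df.groupby("subject_id", sort=True):
        agg = aggregate_subject(grp[cols].to_dict("records"), measures=cols)
        agg["subject_id"] = sid
        agg["n_excerpts"] = len(grp)
        rows.append(agg)
    prof = pd.DataFrame(rows)
    return prof.merge(subjects, on="subject_id", how="left")


def profile_cohort(
    cohort: CohortData | CohortManifest | str | Path,
    lexicon: Optional[EmbeddingLexicon] = None,
    stimuli: dict | None = None,
    base_dir: Optional[str | Path] = None,
    config: Optional[RunConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Profile a cohort given in memory, as a manifest object, or as a path.

    Returns (per-excerpt table, per-subject table).
    """
    cfg = config or RunConfig()
    if isinstance(cohort, (str, Path)):
        cohort = read_manifest(cohort)
        base_dir = base_dir or Path(cfg.manifest or ".").parent
    if isinstance(cohort, CohortData):
        excerpts = cohort.excerpts
        manifest = cohort.manifest
        if lexicon is None:
            lexicon = make_topic_lexicon(cohort.lexicon_spec)
        if stimuli is None:
            stimuli = cohort.stimuli
    else:
        manifest = cohort
        if lexicon is None:
            if not (cfg.lexicon and cfg.frequencies):
                raise ValueError("a lexicon is required to profile a manifest")
            lexicon = load_lexicon(cfg.lexicon, cfg.frequencies, a=cfg.sif_a)
        if stimuli is None and cfg.stimuli:
            stimuli = read_stimuli(cfg.stimuli, lexicon)
        base = Path(base_dir) if base_dir is not None else Path(".")
        excerpts = [
            read_excerpt_file(
                base / r.excerpt_path,
                r.subject_id,
                r.task,
                getattr(r, "stimulus_id", None),
                sentence_mode=cfg.sentence_mode,
            )
            for r in manifest.rows.itertuples()
        ]
    excerpt_df = profile_excerpts(
        excerpts,
        lexicon,
        stimuli=stimuli,
        n_shuffles=cfg.n_shuffles,
        seed=cfg.seed,
        coref_backend=cfg.coref_backend,
    )
    subject_df = aggregate_profiles(excerpt_df, manifest.subjects)
    return excerpt_df, subject_df


def adjusted_models_table(
    subject_df: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    measures: Sequence[str] = MEASURES,
    pairs: Sequence[tuple[str, str]] = GROUP_PAIRS,
) -> pd.DataFrame:
    """Gamma-GLM sensitivity table: every measure x pair x covariate.

    Contrasts that cannot be fit (missing covariate, degenerate data) are
    recorded with NaN statistics rather than dropped.
    """
    rows = []
    for cov in covariates:
        if cov not in subject_df.columns:
            continue
        for measure in measures:
            for ga, gb in pairs:
                sub = subject_df[subject_df["group"].isin([ga, gb])]
                sub = sub.dropna(subset=[measure, cov])
                ok = (
                    (sub["group"] == ga).sum() >= 3
                    and (sub["group"] == gb).sum() >= 3
                    and sub[measure].nunique() > 2
                )
                if not ok:
                    rows.append(
                        {
                            "measure": measure,
                            "group_a": ga,
                            "group_b": gb,
                            "covariate": cov,
                            "t": float("nan"),
                            "p": float("nan"),
                            "lambda": float("nan"),
                            "n": len(sub),
                            "shift": float("nan"),
                            "note": "not_computable",
                        }
                    )
                    continue
                try:
                    res = gamma_adjusted_model(
                        sub[measure],
                        sub["group"],
                        sub[cov],
                        measure=measure,
                        group_a=ga,
                        group_b=gb,
                        covariate_name=cov,
                    )
                    rows.append(
                        {
                            "measure": measure,
                            "group_a": ga,
                            "group_b": gb,
                            "covariate": cov,
                            "t": res.t,
                            "p": res.p,
                            "lambda": res.lam,
                            "n": res.n,
                            "shift": res.shift,
                            "note": "" if res.converged else "not_converged",
                        }
                    )
                except RuntimeError:
                    rows.append(
                        {
                            "measure": measure,
                            "group_a": ga,
                            "group_b": gb,
                            "covariate": cov,
                            "t": float("nan"),
                            "p": float("nan"),
                            "lambda": float("nan"),
                            "n": len(sub),
                            "shift": float("nan"),
                            "note": "model_not_applicable",
                        }
                    )
    return pd.DataFrame(rows)


def compare_cohort(
    subject_df: pd.DataFrame,
    config: Optional[RunConfig] = None,
) -> dict[str, pd.DataFrame]:
    """Group contrasts, association matrix/edges, adjusted models, spider table."""
    cfg = config or RunConfig()
    present = [m for m in MEASURES if m in subject_df.columns]
    contrasts = compare_groups(subject_df, measures=present)
    t_mat, p_mat, edges = association_matrix(subject_df, measures=present)
    adjusted = adjusted_models_table(subject_df, covariates=cfg.covariates, measures=present)
    spider = normalize_profiles(subject_df, measures=present)
    spider = (
        spider.groupby("group", sort=True)[present].mean().reset_index()
    )
    return {
        "contrasts": contrasts,
        "association_t": t_mat,
        "association_p": p_mat,
        "association_edges": edges,
        "adjusted_models": adjusted,
        "spider_profiles": spider,
    }


def write_outputs(
    out_dir: str | Path,
    config: RunConfig,
    tables: dict[str, pd.DataFrame],
) -> None:
    """Write CSV tables plus a JSON run summary (config, seed, version)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        keep_index = name in ("association_t", "association_p")
        df.to_csv(out / f"{name}.csv", index=keep_index)
    summary = {
        "tool": "speechmarkers",
        "version": __version__,
        "config": asdict(config),
    }
    (out / "run_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
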