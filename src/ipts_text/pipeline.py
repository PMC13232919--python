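"""End-to-end orchestration: configuration, seeded runs, artifacts, manifest.

Stages run in a fixed order (simulate -> clean -> classify/codebook/label ->
topics -> lexicon comparison -> sage -> response metrics); each writes its
artifact into the output directory and registers it, with a checksum, in a
manifest that also records the configuration hash and seeds, so a run can
be reproduced byte-for-byte. All randomness flows from one root seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from sklearn.metrics import f1_score

from .codebook import (Codebook, NearestPhraseVetting, iterate_to_fixed_point,
                       load_seed_codebooks, save_codebooks)
from .corpus import Corpus, clean_corpus, corpus_summary, load_corpus, save_corpus_jsonl
from .distant import ClassifierConfig, select_candidates, train_dimension_classifier
from .embed import EmbedderSpec, get_embedder
from .labeling import DIMENSIONS, distribution_table, label_table, scores_frame
from .lexicon import compare_groups, load_fixture_lexicon
from .metrics import ResponseRecord, compare_modalities, profile_records
from .sage import fit_sage_corpora, rank_discriminative
from .synth import SynthConfig, gen_distant_dataset, gen_ipts_posts, gen_threads_with_responses
from .topics import select_k, topic_ipts_prevalence

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "clean", "label", "topics", "lexicon", "sage", "metrics")


def _log(stage: str, level: str, message: str, **extra) -> None:
    payload = {"stage": stage, "level": level, "message": message,
               "time": round(time.time(), 3), **extra}
    print(json.dumps(payload), file=sys.stderr)


@dataclass
class PipelineConfig:
    seed: int = 0
    n_posts: int = 2000
    similarity_threshold: float = 0.60
    candidate_threshold: float = 0.5
    vetting_threshold: float = 0.5
    k_min: int = 5
    k_max: int = 14
    outlier_min_similarity: float = 0.1
    stages: tuple[str, ...] = ALL_STAGES
    corpus_path: str | None = None
    codebook_path: str | None = None
    lexicon_path: str | None = None
    embedder: EmbedderSpec = field(
        default_factory=lambda: EmbedderSpec(dimension=4096))
    synth: SynthConfig | None = None
    use_classifier: bool = True
    topic_sample: int = 600

    def __post_init__(self) -> None:
        for name in ("similarity_threshold", "candidate_threshold", "vetting_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.k_min > self.k_max:
            raise ValueError("k_min must not exceed k_max")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "embedder" in raw:
            raw["embedder"] = EmbedderSpec(**raw["embedder"])
        if "synth" in raw:
            raw["synth"] = SynthConfig(**raw["synth"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class Manifest:
    def __init__(self, out_dir: Path, config: PipelineConfig) -> None:
        self.out_dir = out_dir
        self.data = {"config_hash": config.config_hash(), "seed": config.seed,
                     "files": {}}

    def register(self, path: Path) -> None:
        self.data["files"][path.name] = _sha256(path)

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True), "utf-8")
        return path


def label_corpus(texts: dict[str, str], config: PipelineConfig,
                 codebooks: dict[str, Codebook] | None = None,
                 ) -> tuple[pd.DataFrame, dict[str, Codebook]]:
    """Classify -> codebook-expand -> score every dimension; return the
    flag/score table and the final codebooks."""
    embedder = get_embedder(config.embedder)
    codebooks = codebooks or load_seed_codebooks(config.codebook_path)
    vetting = NearestPhraseVetting(config.vetting_threshold)
    score_maps: dict[str, dict[str, float]] = {}
    final: dict[str, Codebook] = {}
    for i, dim in enumerate(DIMENSIONS):
        if config.use_classifier:
            train = gen_distant_dataset(dim, 200, 200, seed=config.seed + 101 + i)
            clf = train_dimension_classifier(
                ClassifierConfig(seed=config.seed + i), train)
            cand_ids = select_candidates(clf, texts, config.candidate_threshold)
            candidates = {pid: texts[pid] for pid in sorted(cand_ids)}
        else:
            candidates = texts
        result = iterate_to_fixed_point(
            candidates, codebooks[dim], embedder,
            threshold=config.similarity_threshold, vetting=vetting)
        score_maps[dim] = result.scores
        final[dim] = result.codebook
        _log("label", "info", f"dimension {dim}: {len(result.labeled)} labeled, "
             f"codebook {len(result.codebook)} phrases, "
             f"{result.iterations} iteration(s)")
    scores = scores_frame(score_maps, texts.keys())
    return label_table(scores, config.similarity_threshold), final


def run_labeling_experiment(n_posts: int = 2000, seed: int = 0,
                            config: PipelineConfig | None = None) -> dict:
    """Parameter-recovery experiment: synthetic corpus in, per-dimension F1
    against ground truth out."""
    config = config or PipelineConfig(seed=seed, n_posts=n_posts)
    synth = config.synth or SynthConfig(seed=config.seed, n_posts=config.n_posts)
    corpus, truth = gen_ipts_posts(synth)
    labels, codebooks = label_corpus(corpus.post_texts(), config)
    labels = labels.reindex(truth.index)
    f1 = {dim: float(f1_score(truth[dim], labels[dim])) for dim in DIMENSIONS}
    return {"corpus": corpus, "truth": truth, "labels": labels,
            "codebooks": codebooks, "f1": f1}


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the enabled stages in order; returns the manifest path.

    A stage failure aborts with the stage name and cause; artifacts written
    so far are retained.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(out_dir, config)
    synth = config.synth or SynthConfig(seed=config.seed, n_posts=config.n_posts)
    lexicon = load_fixture_lexicon() if config.lexicon_path is None else None
    if lexicon is None:
        from .lexicon import load_liwc_dic
        lexicon = load_liwc_dic(config.lexicon_path)

    corpus: Corpus | None = None
    truth: pd.DataFrame | None = None
    labels: pd.DataFrame | None = None

    def _write_frame(df: pd.DataFrame, name: str, **kwargs) -> None:
        path = out_dir / name
        df.to_csv(path, **kwargs)
        manifest.register(path)

    try:
        if "simulate" in config.stages and config.corpus_path is None:
            _log("simulate", "info", f"generating {synth.n_posts} posts (seed={synth.seed})")
            corpus, truth = gen_ipts_posts(synth)
            save_corpus_jsonl(corpus, out_dir / "corpus.jsonl")
            manifest.register(out_dir / "corpus.jsonl")
            _write_frame(truth, "ground_truth.csv")
        elif config.corpus_path is not None:
            corpus = load_corpus(config.corpus_path)

        if "clean" in config.stages and corpus is not None:
            corpus, report = clean_corpus(corpus)
            (out_dir / "cleaning_report.json").write_text(report.to_json(), "utf-8")
            manifest.register(out_dir / "cleaning_report.json")
            _write_frame(corpus_summary(corpus).to_frame(), "corpus_summary.csv",
                         index=False)

        if "label" in config.stages and corpus is not None:
            labels, codebooks = label_corpus(corpus.post_texts(), config)
            _write_frame(labels, "ipts_labels.csv")
            _write_frame(distribution_table(labels), "distribution.csv", index=False)
            save_codebooks(codebooks, out_dir / "codebooks.yaml")
            manifest.register(out_dir / "codebooks.yaml")

        if "topics" in config.stages and corpus is not None:
            texts = corpus.post_texts()
            ids = sorted(texts)[: config.topic_sample]
            docs = [texts[i] for i in ids]
            vectors = get_embedder(config.embedder).embed_texts(docs)
            result = select_k(vectors, docs,
                              range(config.k_min, config.k_max + 1), config.seed)
            _log("topics", "info", f"selected k={result.k}",
                 coherence=result.coherence)
            keywords = pd.DataFrame({"topic": range(result.k),
                                     "keywords": [" ".join(k) for k in result.topic_keywords]})
            _write_frame(keywords, "topic_keywords.csv", index=False)
            if labels is not None:
                assignments = dict(zip(ids, (int(t) for t in result.assignments)))
                _write_frame(topic_ipts_prevalence(assignments, labels),
                             "topic_prevalence.csv")

        responses = None
        if {"lexicon", "sage", "metrics"} & set(config.stages):
            fixture_words = {"sad": sorted(lexicon.words.get("sad", []))}
            responses = gen_threads_with_responses(synth, lexicon_words=fixture_words)

        if "lexicon" in config.stages and responses is not None:
            oc = responses[responses["modality"] == "OC"]
            by_group = {g: sub["response_text"].tolist()
                        for g, sub in oc.groupby("group") if g != "none"}
            if len(by_group) >= 2:
                _write_frame(compare_groups(by_group, lexicon),
                             "lexicon_comparison.csv", index=False)

        if "sage" in config.stages and responses is not None:
            oc = responses[responses["modality"] == "OC"]
            target = oc.loc[oc["group"] == "lethal", "response_text"].tolist()
            background = oc.loc[oc["group"] != "lethal", "response_text"].tolist()
            if target and background:
                model = fit_sage_corpora(target, background, min_count=2)
                pos, neg = rank_discriminative(model, top_k=15)
                _write_frame(pd.DataFrame(pos + neg, columns=["term", "eta"]),
                             "sage_terms.csv", index=False)

        if "metrics" in config.stages and responses is not None:
            records = [ResponseRecord(r.post_text, r.response_text, r.modality, r.post_id)
                       for r in responses.itertuples()]
            profiles = profile_records(records, lexicon)
            _write_frame(profiles, "metric_profiles.csv", index=False)
            _write_frame(compare_modalities(profiles), "modality_comparison.csv")
    except Exception as exc:
        _log("pipeline", "error", f"stage failed: {exc}")
        raise

    path = manifest.write()
    _log("pipeline", "info", "run complete", manifest=str(path))
    return path
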