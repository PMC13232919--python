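"""Distantly supervised per-dimension binary classifiers.

Each construct gets a binary text classifier trained on an external
stand-in dataset (distant supervision), whose positive predictions form
the candidate pool for codebook-similarity labeling. Two architectures
satisfy the same contract:

* ``linear_reference`` — weighted logistic regression over hashed
  bag-of-words features; deterministic, dependency-light, the backend used
  by tests and unattended pipelines.
* ``recurrent_lstm`` — a recurrent architecture with fixed reference
  hyperparameters (64-dim embedding, 128-unit LSTM with dropout, global
  max pooling, 64-unit ReLU dense, sigmoid output, cross-entropy loss,
  Adam, class weights in the loss); an optional adapter that requires a
  keras runtime.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .corpus import Corpus
from .embed import BackendUnavailableError, HashedEmbedder


@dataclass(frozen=True)
class LabeledExample:
    text: str
    label: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class ClassifierConfig:
    architecture: str = "linear_reference"
    embed_dim: int = 64
    recurrent_units: int = 128
    dense_units: int = 64
    dropout: float = 0.2
    split_ratio: float = 0.55
    seed: int = 0
    decision_threshold: float = 0.5
    hash_dimension: int = 1024
    l2_c: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must lie strictly between 0 and 1")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must lie strictly between 0 and 1")


def load_labeled_csv(path: str | Path, source: str = "") -> list[LabeledExample]:
    """Generic (text,label) CSV loader so real distant-supervision sets drop in."""
    out = []
    with Path(path).open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"text", "label"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns 'text' and 'label'")
        for row in reader:
            out.append(LabeledExample(row["text"], int(row["label"]), source or str(path)))
    return out


def split_train_test(examples: Sequence[LabeledExample],
                     config: ClassifierConfig | None = None,
                     ) -> tuple[list[LabeledExample], list[LabeledExample]]:
    """Stratified 55:45 split (train share = ``config.split_ratio``), seeded."""
    if config is None:
        config = ClassifierConfig()
    labels = [ex.label for ex in examples]
    if len(set(labels)) < 2:
        raise ValueError("stratified split requires both classes to be present")
    train, test = train_test_split(
        list(examples), train_size=config.split_ratio, stratify=labels,
        random_state=config.seed, shuffle=True)
    return list(train), list(test)


def compute_class_weights(labels: Iterable[int]) -> dict[int, float]:
    """weight_c = n_total / (2 * n_c): the minority class gets the larger weight."""
    labels = list(labels)
    n = len(labels)
    n1 = sum(labels)
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to compute class weights")
    return {0: n / (2.0 * n0), 1: n / (2.0 * n1)}


class LinearReferenceClassifier:
    """Hashed-feature weighted logistic classifier (deterministic given seed)."""

    def __init__(self, config: ClassifierConfig, model: LogisticRegression,
                 embedder: HashedEmbedder) -> None:
        self.config = config
        self._model = model
        self._embedder = embedder

    @classmethod
    def train(cls, config: ClassifierConfig,
              train: Sequence[LabeledExample]) -> "LinearReferenceClassifier":
        if not train:
            raise ValueError("empty training set")
        weights = compute_class_weights([ex.label for ex in train])
        embedder = HashedEmbedder(config.hash_dimension)
        X = embedder.embed_texts([ex.text for ex in train])
        y = np.array([ex.label for ex in train])
        model = LogisticRegression(
            C=config.l2_c, class_weight=weights, max_iter=2000,
            random_state=config.seed)
        model.fit(X, y)
        return cls(config, model, embedder)

    def predict_proba(self, texts: str | Sequence[str]) -> np.ndarray:
        single = isinstance(texts, str)
        batch = [texts] if single else list(texts)
        X = self._embedder.embed_texts(batch)
        p = self._model.predict_proba(X)[:, 1]
        return p[0] if single else p

    def to_json(self) -> str:
        payload = {
            "architecture": "linear_reference",
            "hash_dimension": self.config.hash_dimension,
            "coef": self._model.coef_.ravel().tolist(),
            "intercept": float(self._model.intercept_[0]),
            "classes": self._model.classes_.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str, config: ClassifierConfig | None = None
                  ) -> "LinearReferenceClassifier":
        payload = json.loads(text)
        if payload.get("architecture") != "linear_reference":
            raise ValueError("not a linear_reference model file")
        config = config or ClassifierConfig(hash_dimension=payload["hash_dimension"])
        model = LogisticRegression()
        model.coef_ = np.array([payload["coef"]])
        model.intercept_ = np.array([payload["intercept"]])
        model.classes_ = np.array(payload["classes"])
        return cls(config, model, HashedEmbedder(payload["hash_dimension"]))


def _train_recurrent(config: ClassifierConfig, train: Sequence[LabeledExample]):
    try:
        import keras  # noqa: F401
    except ImportError as exc:  # pragma: no cover - optional adapter
        raise BackendUnavailableError(
            "the recurrent_lstm architecture needs a keras runtime; "
            "install tensorflow/keras or use architecture='linear_reference'"
        ) from exc
    raise NotImplementedError  # pragma: no cover - adapter body ships separately


def train_dimension_classifier(config: ClassifierConfig,
                               train: Sequence[LabeledExample]):
    """Fit a classifier exposing ``predict_proba(text) -> [0, 1]``."""
    if not train:
        raise ValueError("empty training set")
    if config.architecture == "linear_reference":
        return LinearReferenceClassifier.train(config, train)
    if config.architecture == "recurrent_lstm":
        return _train_recurrent(config, train)
    raise ValueError(f"unknown architecture {config.architecture!r}")


def select_candidates(model, corpus: Corpus | Mapping[str, str],
                      threshold: float = 0.5) -> set[str]:
    """Ids of posts whose predicted probability strictly exceeds ``threshold``.

    Monotone in the threshold: raising it never enlarges the candidate set.
    """
    texts = corpus.post_texts() if isinstance(corpus, Corpus) else dict(corpus)
    if not texts:
        return set()
    ids = list(texts)
    probs = model.predict_proba([texts[i] for i in ids])
    return {pid for pid, p in zip(ids, np.atleast_1d(probs)) if p > threshold}
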