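"""Shared fixtures: tiny corpora on disk, stub embedders, fixture lexicon."""

from __future__ import annotations

import json

import numpy as np
import pytest

from ipts_text.embed import HashedEmbedder
from ipts_text.lexicon import CategoryLexicon, load_fixture_lexicon


class VectorStubEmbedder:
    """Maps known texts to fixed vectors — lets tests pin exact cosines."""

    def __init__(self, mapping: dict[str, np.ndarray]):
        self.mapping = {k: np.asarray(v, dtype=float) for k, v in mapping.items()}
        self.dimension = len(next(iter(self.mapping.values())))

    def embed(self, text: str) -> np.ndarray:
        return self.mapping[text]

    def embed_texts(self, texts):
        return np.vstack([self.embed(t) for t in texts])


@pytest.fixture
def stub_embedder_factory():
    return VectorStubEmbedder


@pytest.fixture
def hashed_embedder() -> HashedEmbedder:
    return HashedEmbedder()


@pytest.fixture
def fixture_lexicon() -> CategoryLexicon:
    return load_fixture_lexicon()


@pytest.fixture
def jsonl_corpus(tmp_path):
    """2 posts, 3 comments."""
    records = [
        {"id": "p1", "post_id": None, "author": "alice", "created_at": "2023-05-01T10:00:00Z",
         "title": "t", "body": "first post body"},
        {"id": "p2", "post_id": None, "author": "bob", "created_at": "2023-05-01T11:00:00Z",
         "title": None, "body": "second post body"},
        {"id": "c1", "post_id": "p1", "author": "carol", "created_at": "2023-05-01T12:00:00Z",
         "body": "a comment"},
        {"id": "c2", "post_id": "p1", "author": "bob", "created_at": "2023-05-01T13:00:00Z",
         "body": "another comment"},
        {"id": "c3", "post_id": "p2", "author": "alice", "created_at": "2023-05-01T14:00:00Z",
         "body": "third comment"},
    ]
    path = tmp_path / "corpus.jsonl"
    path.write_text("\n".join(json.dumps(r) for r in records) + "\n", "utf-8")
    return path


@pytest.fixture
def csv_corpus_bad_timestamp(tmp_path):
    path = tmp_path / "corpus.csv"
    path.write_text(
        "id,post_id,author,created_at,title,body\n"
        "p1,,alice,2023-05-01T10:00:00Z,t,first body\n"
        "p2,,bob,not-a-timestamp,,second body\n"
        "c1,p1,carol,2023-05-01T12:00:00Z,,a comment\n",
        "utf-8")
    return path
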