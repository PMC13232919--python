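"""Threaded post/comment corpus: data model, readers, cleaning, summaries.

The corpus substrate is deliberately plain: posts and comments are frozen
records keyed by opaque string ids, comments referencing their parent post.
Readers accept JSONL (one record per line) or CSV with the same columns
(id, post_id, author, created_at, title, body); a record is a comment iff
it carries a non-empty ``post_id``.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from ._text import whitespace_count

logger = logging.getLogger(__name__)

DEFAULT_DELETION_SENTINELS = ("[deleted]", "[removed]")


class CorpusFormatError(ValueError):
    """Input file cannot be interpreted as a corpus (bad format / missing fields)."""


@dataclass(frozen=True)
class Post:
    id: str
    author: str = ""
    created_at: datetime | None = None
    title: str | None = None
    body: str = ""


@dataclass(frozen=True)
class Comment:
    id: str
    post_id: str
    author: str = ""
    created_at: datetime | None = None
    body: str = ""


@dataclass
class LoadReport:
    n_rows: int = 0
    n_malformed: int = 0
    errors: list[str] = field(default_factory=list)


class Corpus:
    """Container of posts and comments with id-based lookup."""

    def __init__(self, posts: list[Post] | None = None,
                 comments: list[Comment] | None = None,
                 load_report: LoadReport | None = None) -> None:
        self.posts: list[Post] = list(posts or [])
        self.comments: list[Comment] = list(comments or [])
        self.load_report = load_report or LoadReport()

    @property
    def n_posts(self) -> int:
        return len(self.posts)

    @property
    def n_comments(self) -> int:
        return len(self.comments)

    def post_ids(self) -> set[str]:
        return {p.id for p in self.posts}

    def post_texts(self) -> dict[str, str]:
        """Map post id -> title + body text used by every downstream stage."""
        out = {}
        for p in self.posts:
            out[p.id] = f"{p.title} {p.body}".strip() if p.title else p.body
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"Corpus(n_posts={self.n_posts}, n_comments={self.n_comments})"


def _parse_timestamp(value) -> datetime | None:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    ts = pd.to_datetime(value, utc=True, errors="raise")
    if pd.isna(ts):
        raise ValueError(f"unparseable timestamp {value!r}")
    return ts.to_pydatetime()


def _record_to_item(rec: dict) -> Post | Comment:
    rid = str(rec.get("id", "") or "")
    if not rid:
        raise ValueError("empty id")
    created = _parse_timestamp(rec.get("created_at"))
    post_id = rec.get("post_id")
    if post_id is None or (isinstance(post_id, float) and pd.isna(post_id)) or str(post_id) == "":
        title = rec.get("title")
        if title is not None and not isinstance(title, str):
            title = None if pd.isna(title) else str(title)
        return Post(id=rid, author=str(rec.get("author", "") or ""),
                    created_at=created, title=title,
                    body=str(rec.get("body", "") or ""))
    return Comment(id=rid, post_id=str(post_id), author=str(rec.get("author", "") or ""),
                   created_at=created, body=str(rec.get("body", "") or ""))


REQUIRED_FIELDS = ("id", "body")


def load_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Read a corpus from JSONL or CSV.

    Rows whose values cannot be parsed (e.g. a bad timestamp) are rejected
    and counted in ``corpus.load_report``; a missing required column is a
    :class:`CorpusFormatError` naming the field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise CorpusFormatError(f"unknown corpus format {format!r} (expected jsonl or csv)")

    records: list[tuple[int, dict]] = []
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"line {lineno}: invalid JSON ({exc})") from exc
                records.append((lineno, rec))
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is not None:
                missing = [f for f in REQUIRED_FIELDS if f not in reader.fieldnames]
                if missing:
                    raise CorpusFormatError(f"CSV header missing required field(s): {missing}")
            for lineno, rec in enumerate(reader, 2):
                records.append((lineno, rec))

    report = LoadReport(n_rows=len(records))
    posts: list[Post] = []
    comments: list[Comment] = []
    for lineno, rec in records:
        for f in REQUIRED_FIELDS:
            if f not in rec:
                raise CorpusFormatError(f"row {lineno}: missing required field {f!r}")
        try:
            item = _record_to_item(rec)
        except (ValueError, TypeError) as exc:
            report.n_malformed += 1
            report.errors.append(f"row {lineno}: {exc}")
            continue
        if isinstance(item, Post):
            posts.append(item)
        else:
            comments.append(item)
    if not records:
        warnings.warn(f"{path} contained no records", stacklevel=2)
    if report.n_malformed:
        logger.warning("load_corpus: rejected %d malformed row(s)", report.n_malformed)
    return Corpus(posts, comments, load_report=report)


@dataclass
class CleaningReport:
    duplicates: int = 0
    removed: int = 0
    orphans: int = 0
    retained_posts: int = 0
    retained_comments: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def clean_corpus(corpus: Corpus,
                 deletion_sentinels: tuple[str, ...] = DEFAULT_DELETION_SENTINELS,
                 ) -> tuple[Corpus, CleaningReport]:
    """Drop duplicates (keep first), deletion sentinels, and orphan comments.

    Cleaning is total (never raises) and idempotent.
    """
    report = CleaningReport()
    sentinels = set(deletion_sentinels)

    posts: list[Post] = []
    seen: set[str] = set()
    for p in corpus.posts:
        if p.id in seen:
            report.duplicates += 1
            continue
        if p.body.strip() in sentinels:
            report.removed += 1
            continue
        seen.add(p.id)
        posts.append(p)

    post_ids = {p.id for p in posts}
    comments: list[Comment] = []
    seen_c: set[str] = set()
    for c in corpus.comments:
        if c.id in seen_c:
            report.duplicates += 1
            continue
        if c.body.strip() in sentinels:
            report.removed += 1
            continue
        if c.post_id not in post_ids:
            report.orphans += 1
            continue
        seen_c.add(c.id)
        comments.append(c)

    report.retained_posts = len(posts)
    report.retained_comments = len(comments)
    return Corpus(posts, comments), report


@dataclass
class CorpusSummary:
    n_posts: int
    n_comments: int
    n_posting_users: int
    n_commenting_users: int
    mean_post_length: float
    median_post_length: float
    mean_comment_length: float
    median_comment_length: float
    comments_per_post: float
    pct_zero_comment_posts: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def corpus_summary(corpus: Corpus) -> CorpusSummary:
    """Descriptive statistics of a (cleaned) corpus.

    Word counts are whitespace tokens; ratios are exact, rounding is left
    to presentation.
    """
    n_posts = corpus.n_posts
    n_comments = corpus.n_comments
    if n_posts == 0:
        warnings.warn("corpus_summary on empty corpus", stacklevel=2)
        return CorpusSummary(0, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    post_lengths = pd.Series(
        [whitespace_count(f"{p.title or ''} {p.body}") for p in corpus.posts], dtype=float)
    comment_lengths = pd.Series(
        [whitespace_count(c.body) for c in corpus.comments], dtype=float)
    commented = {c.post_id for c in corpus.comments}
    n_zero = sum(1 for p in corpus.posts if p.id not in commented)
    return CorpusSummary(
        n_posts=n_posts,
        n_comments=n_comments,
        n_posting_users=len({p.author for p in corpus.posts if p.author}),
        n_commenting_users=len({c.author for c in corpus.comments if c.author}),
        mean_post_length=float(post_lengths.mean()),
        median_post_length=float(post_lengths.median()),
        mean_comment_length=float(comment_lengths.mean()) if n_comments else 0.0,
        median_comment_length=float(comment_lengths.median()) if n_comments else 0.0,
        comments_per_post=n_comments / n_posts,
        pct_zero_comment_posts=100.0 * n_zero / n_posts,
    )


def save_corpus_jsonl(corpus: Corpus, path: str | Path) -> None:
    """Write the corpus back out in the canonical JSONL layout."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for p in corpus.posts:
            rec = {"id": p.id, "post_id": None, "author": p.author,
                   "created_at": p.created_at.isoformat() if p.created_at else None,
                   "title": p.title, "body": p.body}
            fh.write(json.dumps(rec) + "\n")
        for c in corpus.comments:
            rec = {"id": c.id, "post_id": c.post_id, "author": c.author,
                   "created_at": c.created_at.isoformat() if c.created_at else None,
                   "title": None, "body": c.body}
            fh.write(json.dumps(rec) + "\n")


def utc_now() -> datetime:  # pragma: no cover - convenience for callers
    return datetime.now(timezone.utc)
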