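"""Seeded synthetic corpora with the statistical structure each stage assumes.

Nothing here is real crisis text: background tokens come from a shipped
neutral word list, and construct language is injected as seed phrases from
the shipped codebooks (plus controlled near-paraphrases that are absent
from the seeds, so codebook expansion has something genuine to discover).

Generation is geometry-aware: under the hashed bag-of-words reference
embedder, a post's cosine to a phrase is determined by the share of the
post's token mass the phrase occupies. Positive posts are therefore built
so injected phrases carry enough mass to clear the labeling threshold,
while background posts stay far below it. Posts expressing three or more
constructs at once (the lethal profile) cannot clear the threshold for all
of them simultaneously under a count-based embedder — the sum of squared
cosines onto orthogonal phrase directions is at most 1 — so the lethal
profile exists for ground-truth composition, not for similarity recovery.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._text import STOPWORDS, word_tokens
from .corpus import Corpus, Post
from .distant import LabeledExample
from .labeling import DIMENSIONS

# Injection pools: a subset of each dimension's seed phrases plus
# near-paraphrase variants (content words only, so RAKE can extract them
# whole) that do NOT appear in the shipped seed codebook.
PHRASE_POOLS: dict[str, dict] = {
    "loneliness": {
        "seeds": ["disconnected", "loneliness", "living alone", "no social supports"],
        "paraphrases": {
            "painful loneliness": "loneliness",
            "socially disconnected": "disconnected",
            "zero social supports": "no social supports",
        },
    },
    "lack_love": {
        "seeds": ["lack love", "no love", "social withdrawal", "familial discord"],
        "paraphrases": {
            "lacking real love": "lack love",
            "total social withdrawal": "social withdrawal",
            "constant familial discord": "familial discord",
        },
    },
    "self_hate": {
        "seeds": ["i hate myself", "i am useless", "self-blame", "low self-esteem"],
        "paraphrases": {
            "worthless self hatred": "i hate myself",
            "deep self blame": "self-blame",
            "crushed self esteem": "low self-esteem",
        },
    },
    "liability": {
        "seeds": ["unwanted", "expendability", "distress from unemployment",
                  "belief of burden on family"],
        "paraphrases": {
            "totally unwanted": "unwanted",
            "unemployment distress": "distress from unemployment",
            "heavy family burden": "belief of burden on family",
        },
    },
    "capability": {
        "seeds": ["physical pain", "reduced fear of death", "habituation", "overdose"],
        "paraphrases": {
            "intense physical pain": "physical pain",
            "reduced death fear": "reduced fear of death",
        },
    },
}

# Punctuation-only separators: RAKE splits candidate runs at punctuation,
# and (unlike filler conjunctions) these add no tokens of their own, so the
# injected-phrase mass budget below stays exact.
_SEPARATORS = (", ", ". ")

DEFAULT_DIMENSION_MIX = {
    "loneliness": 0.08, "lack_love": 0.07, "self_hate": 0.07,
    "liability": 0.07, "capability": 0.06,
}
DEFAULT_COMBO_MIX = {
    "thwarted_belongingness": 0.05, "perceived_burdensomeness": 0.05, "lethal": 0.02,
}
_COMBO_DIMS = {
    "thwarted_belongingness": ("loneliness", "lack_love"),
    "perceived_burdensomeness": ("self_hate", "liability"),
    "lethal": DIMENSIONS,
}

DEFAULT_AI_TEMPLATES = [
    ("I hear you about {topic}, and I want you to know your feelings are valid. "
     "It sounds like {topic} has been weighing on you heavily for some time. "
     "Please consider reaching out to someone you trust, a counselor, or a crisis "
     "line, because you deserve support and you do not have to face this alone. "
     "Small steps matter, and talking about {topic} openly is already one of them. "
     "You matter, and there are people who want to help you through this moment."),
    ("Thank you for sharing something so difficult about {topic}. I can imagine how "
     "hard it must be to carry {topic} day after day. You are not a burden for "
     "feeling this way, and support is available. Please reach out to a mental "
     "health professional or a trusted person in your life, and be gentle with "
     "yourself today. Your life has value, and this pain about {topic} can change "
     "with time and help."),
    ("I am truly sorry you are going through {topic}. What you describe about "
     "{topic} sounds exhausting, and it makes sense that you feel overwhelmed. "
     "Please consider talking with a counselor or calling a support line, because "
     "you deserve care and understanding. Many people have found that sharing "
     "{topic} with someone safe brings a little relief, and small moments of "
     "connection can slowly rebuild hope. You are not alone in this."),
]

# bigram components deliberately avoid stopwords: stop-word filtering runs
# before n-gram formation, so a planted bigram with a stopword half could
# never appear in the SAGE vocabulary
DEFAULT_PLANTED_TERMS = {
    "lethal": ["life problems", "strange place", "grow apart", "endless problems",
               "dark tunnel"],
    "nonlethal": ["intrusive thoughts", "bad thing", "small moments", "coworker",
                  "caffeine"],
}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic corpora.

    ``dimension_mix`` gives the share of posts expressing exactly one
    construct; ``combo_mix`` the shares expressing risk-factor pairs or the
    full lethal profile; the remainder is neutral background. Same seed,
    same config => byte-identical output.
    """

    seed: int = 0
    n_posts: int = 2000
    dimension_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DIMENSION_MIX))
    combo_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COMBO_MIX))
    phrase_injection_rate: float = 2.0
    paraphrase_frac: float = 0.3
    background_vocab_size: int = 120
    response_templates: list[str] = field(default_factory=lambda: list(DEFAULT_AI_TEMPLATES))
    planted_terms: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_PLANTED_TERMS.items()})
    planted_enrichment: float = 10.0
    category_rates: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, p in {**self.dimension_mix, **self.combo_mix}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"proportion for {name!r} outside [0, 1]")
        total = sum(self.dimension_mix.values()) + sum(self.combo_mix.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"dimension/combo proportions sum to {total:.3f} > 1")
        if self.planted_enrichment <= 1.0:
            raise ValueError("planted_enrichment must exceed 1")
        unknown = set(self.dimension_mix) - set(DIMENSIONS)
        if unknown:
            raise ValueError(f"unknown dimension id(s) {sorted(unknown)}")


def load_background_vocab(size: int | None = None) -> list[str]:
    text = resources.files("ipts_text.data").joinpath("background_words.txt").read_text("utf-8")
    words = [w.strip() for w in text.splitlines() if w.strip() and not w.startswith("#")]
    return words[:size] if size else words


def _background_chunks(rng: np.random.Generator, vocab: Sequence[str],
                       n_tokens: int) -> list[str]:
    # distinct words within a post: repeated background tokens would add
    # squared mass the injection budget does not account for
    n_tokens = min(n_tokens, len(vocab))
    words = list(rng.choice(vocab, size=n_tokens, replace=False))
    chunks = []
    while words:
        take = int(rng.integers(1, min(3, len(words)) + 1))
        chunks.append(" ".join(words[:take]))
        words = words[take:]
    return chunks


def _assemble(rng: np.random.Generator, chunks: list[str]) -> str:
    order = rng.permutation(len(chunks))
    parts = [chunks[i] for i in order]
    text = parts[0]
    for part in parts[1:]:
        text += str(rng.choice(_SEPARATORS)) + part
    return text + "."


@dataclass
class _Injection:
    """One construct's injected phrases within a post."""

    dim: str
    primary: str          # the phrase that should eventually label the post
    chunks: list[str]     # primary copies (+ optionally the parent seed)

    def add_copy(self) -> None:
        self.chunks.append(self.primary)


def _sample_injections_for_dim(rng: np.random.Generator, dim: str, rate: float,
                               paraphrase_frac: float, min_copies: int,
                               allow_mixed: bool) -> list[_Injection]:
    """Pick the phrase identities for (post, dim) and their copy counts.

    With probability ``paraphrase_frac`` the phrase is a near-paraphrase
    absent from the seed codebook; for single-construct posts, half of
    those also restate the parent seed with its own full copy count (a
    second budgeted primary), which is what lets the seed codebook label
    the post at iteration 1 so RAKE can surface the paraphrase — paraphrase
    and parent need not share any token.
    """
    pool = PHRASE_POOLS[dim]
    copies = max(min_copies, int(rng.poisson(rate)))
    paraphrases = sorted(pool["paraphrases"])
    if paraphrases and rng.random() < paraphrase_frac:
        phrase = str(rng.choice(paraphrases))
        out = [_Injection(dim, phrase, [phrase] * copies)]
        if allow_mixed and rng.random() < 0.5:
            parent = pool["paraphrases"][phrase]
            out.append(_Injection(dim, parent, [parent] * copies))
        return out
    phrase = str(rng.choice(pool["seeds"]))
    return [_Injection(dim, phrase, [phrase] * copies)]


# Target per-construct cosine floor for detectable (one- or two-construct)
# positives; 0.66 leaves slack over the 0.60 labeling threshold for hash
# collisions in the reference embedder.
_COS_FLOOR = 0.66


def _norm_budget(injections: Sequence[_Injection]) -> tuple[float, float]:
    """(squared norm of injected tokens, admissible squared-norm cap).

    Exact bag-of-words accounting: the squared norm is the sum of squared
    token counts over every injected chunk; the cap is the largest total
    squared norm under which every primary phrase's cosine still reaches
    the floor (dot_d / (sqrt(m_d) * sqrt(S)) >= floor for all d).
    """
    counts = Counter()
    for inj in injections:
        for chunk in inj.chunks:
            counts.update(word_tokens(chunk))
    sq_norm = float(sum(c * c for c in counts.values()))
    cap = np.inf
    for inj in injections:
        toks = word_tokens(inj.primary)
        dot = float(sum(counts[t] for t in toks))
        cap = min(cap, dot * dot / (_COS_FLOOR ** 2 * len(toks)))
    return sq_norm, cap


def _positive_text(rng: np.random.Generator, dims: Sequence[str], config: SynthConfig,
                   vocab: Sequence[str]) -> str:
    min_copies = 2 if len(dims) >= 2 else 1
    injections = [
        inj for dim in dims
        for inj in _sample_injections_for_dim(
            rng, dim, config.phrase_injection_rate, config.paraphrase_frac,
            min_copies, allow_mixed=len(dims) == 1)
    ]
    if len(dims) <= 2:
        # escalate copies of the limiting construct until every primary
        # phrase can clear the cosine floor (always feasible for <= 2
        # orthogonal constructs); impossible for >= 3, see module docstring
        for _ in range(8):
            sq_norm, cap = _norm_budget(injections)
            if sq_norm <= cap:
                break
            # escalate the phrase whose admissible-norm cap binds: its cap
            # grows quadratically in its copy count, so this converges,
            # whereas escalating by raw phrase mass can oscillate
            weakest = min(injections, key=lambda inj: _norm_budget([inj])[1])
            weakest.add_copy()
        sq_norm, cap = _norm_budget(injections)
        b_max = int(np.floor(cap - sq_norm))
        if b_max >= 2:
            n_background = int(rng.integers(2, min(b_max, 12) + 1))
        else:
            n_background = max(b_max, 0)
    else:
        # Lethal-profile posts foreground capability language — method and
        # attempt phrasing is what operationally distinguishes them — so the
        # directly-scored construct stays recoverable even though the paired
        # constructs cannot all clear the threshold simultaneously.
        cap_inj = next((inj for inj in injections if inj.dim == "capability"), None)
        if cap_inj is not None:
            for _ in range(8):
                sq_norm, cap = _norm_budget([cap_inj])
                total_sq, _ = _norm_budget(injections)
                if total_sq + 2 <= cap:
                    break
                cap_inj.add_copy()
        n_background = 2
    chunks = [c for inj in injections for c in inj.chunks]
    chunks.extend(_background_chunks(rng, vocab, n_background))
    return _assemble(rng, chunks)


def _profiles(config: SynthConfig) -> tuple[list[tuple[str, ...]], list[float]]:
    profiles: list[tuple[str, ...]] = []
    probs: list[float] = []
    for dim in DIMENSIONS:
        p = config.dimension_mix.get(dim, 0.0)
        if p > 0:
            profiles.append((dim,))
            probs.append(p)
    for combo, p in config.combo_mix.items():
        if p > 0:
            profiles.append(tuple(_COMBO_DIMS[combo]))
            probs.append(p)
    background_p = 1.0 - sum(probs)
    profiles.append(())
    probs.append(max(background_p, 0.0))
    return profiles, probs


def gen_ipts_posts(config: SynthConfig) -> tuple[Corpus, pd.DataFrame]:
    """Seeded corpus of construct-bearing and background posts + ground truth.

    Ground-truth risk-factor flags are always the composition of the
    ground-truth dimension flags (TB = loneliness & lack_love, PB =
    self_hate & liability, AC = capability, lethal = all three).
    """
    rng = np.random.default_rng(config.seed)
    vocab = load_background_vocab(config.background_vocab_size)
    profiles, probs = _profiles(config)
    base_time = datetime(2023, 5, 1, tzinfo=timezone.utc)

    posts: list[Post] = []
    truth_rows: list[dict] = []
    profile_idx = rng.choice(len(profiles), size=config.n_posts, p=probs)
    for i in range(config.n_posts):
        dims = profiles[profile_idx[i]]
        if dims:
            body = _positive_text(rng, dims, config, vocab)
        else:
            body = _assemble(rng, _background_chunks(rng, vocab, int(rng.integers(8, 18))))
        posts.append(Post(
            id=f"p{i:05d}", author=f"user{int(rng.integers(0, config.n_posts)):05d}",
            created_at=base_time + timedelta(minutes=i), body=body))
        flags = {d: d in dims for d in DIMENSIONS}
        tb = flags["loneliness"] and flags["lack_love"]
        pb = flags["self_hate"] and flags["liability"]
        ac = flags["capability"]
        truth_rows.append({
            "post_id": posts[-1].id, **flags,
            "thwarted_belongingness": tb, "perceived_burdensomeness": pb,
            "acquired_capability": ac, "lethal": tb and pb and ac,
        })
    truth = pd.DataFrame(truth_rows).set_index("post_id")
    return Corpus(posts), truth


def gen_distant_dataset(dimension: str, n_pos: int, n_neg: int,
                        seed: int = 0) -> list[LabeledExample]:
    """Labeled examples emulating an external distant-supervision dataset."""
    if dimension not in PHRASE_POOLS:
        raise ValueError(f"unknown dimension id {dimension!r}")
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be nonnegative")
    rng = np.random.default_rng(seed)
    vocab = load_background_vocab()
    other_dims = [d for d in DIMENSIONS if d != dimension]
    out: list[LabeledExample] = []
    cfg = SynthConfig(seed=seed)
    for _ in range(n_pos):
        out.append(LabeledExample(
            _positive_text(rng, (dimension,), cfg, vocab), 1, f"synthetic:{dimension}"))
    for j in range(n_neg):
        if j % 2 == 0:
            text = _assemble(rng, _background_chunks(rng, vocab, int(rng.integers(8, 18))))
        else:
            text = _positive_text(rng, (str(rng.choice(other_dims)),), cfg, vocab)
        out.append(LabeledExample(text, 0, "synthetic:background"))
    return out


# ---------------------------------------------------------------------------
# Responses


def template_responder(post: Post, templates: Sequence[str], seed: int = 0) -> str:
    """Deterministic template response with post content filled into slots.

    Emulates a low-diversity automated responder: the template is chosen by
    a hash of (seed, post id) and every ``{topic}`` slot is filled with the
    longest content word of the post — high semantic similarity and style
    match, low pool diversity.
    """
    if not templates:
        raise ValueError("template list must be nonempty")
    from .embed import fnv1a_32
    idx = fnv1a_32(f"{seed}:{post.id}".encode()) % len(templates)
    content = [t for t in word_tokens(post.body) if t not in STOPWORDS]
    topic = max(content, key=lambda w: (len(w), w)) if content else "this"
    return templates[idx].format(topic=topic)


_OC_OPENERS = ["honestly", "listen", "hey", "truly", "friend", "please know"]
# informal, contraction-heavy narrative fragments: community responses carry
# the conversational register the formality contrast expects
_OC_SUPPORT = [
    "i went through something similar last year and it slowly got better",
    "talking to my sister helped me more than i expected",
    "you deserve people around you who actually listen",
    "some days are heavier than others and that's okay",
    "a counselor finally gave me words for what i felt",
    "small moments of relief kept me going back then",
    "i kept a journal and it took some of the weight off",
    "your story reminded me of my own worst winter",
    "idk if this helps but you're not the only one",
    "it's gonna take time, don't rush yourself",
    "i don't have answers, just wanna say i hear you",
    "can't promise much but it won't always feel like this",
]


def _community_response(rng: np.random.Generator, group: str, config: SynthConfig,
                        vocab: Sequence[str], lexicon_words: Mapping[str, Sequence[str]],
                        ) -> str:
    parts = [str(rng.choice(_OC_OPENERS)),
             str(rng.choice(_OC_SUPPORT)),
             " ".join(rng.choice(vocab, size=int(rng.integers(4, 10)), replace=True))]
    # planted discriminative n-grams: the lethal response pool over-samples
    # its terms by the configured enrichment factor
    base_rate = 0.08
    for pool_name, terms in config.planted_terms.items():
        rate = base_rate * config.planted_enrichment if (
            (pool_name == "lethal") == (group == "lethal")) else base_rate
        for term in terms:
            if rng.random() < rate:
                parts.append(term)
    # group-dependent psycholinguistic category usage
    for category, words in lexicon_words.items():
        mult = config.category_rates.get(group, {}).get(category, 1.0)
        k = rng.poisson(0.5 * mult)
        if k > 0:
            parts.extend(str(w) for w in rng.choice(list(words), size=min(k, 4)))
    order = rng.permutation(len(parts) - 1) + 1
    text = parts[0] + ". " + ". ".join(parts[i] for i in order) + "."
    return text


def _post_group(truth_row: Mapping[str, bool]) -> str:
    if truth_row["lethal"]:
        return "lethal"
    for rf in ("thwarted_belongingness", "perceived_burdensomeness", "acquired_capability"):
        if truth_row[rf]:
            return rf
    return "none"


def gen_threads_with_responses(config: SynthConfig,
                               modalities: Sequence[str] = ("OC", "AI-1", "AI-2", "AI-3"),
                               lexicon_words: Mapping[str, Sequence[str]] | None = None,
                               ) -> pd.DataFrame:
    """One response per post per modality: community narratives vs templates.

    Returns a tidy frame (post_id, group, modality, post_text,
    response_text). AI modalities share the template responder (distinct
    seeds per setting); the community modality draws from a diverse
    narrative pool honoring planted-term enrichment and group-dependent
    category rates.
    """
    ai_modalities = [m for m in modalities if m.startswith("AI")]
    if ai_modalities and not config.response_templates:
        raise ValueError("AI modality requested but response_templates is empty")
    corpus, truth = gen_ipts_posts(config)
    rng = np.random.default_rng(config.seed + 1)
    vocab = load_background_vocab(config.background_vocab_size)
    lexicon_words = lexicon_words or {}

    rows = []
    for post in corpus.posts:
        group = _post_group(truth.loc[post.id])
        for modality in modalities:
            if modality == "OC":
                resp = _community_response(rng, group, config, vocab, lexicon_words)
            else:
                setting = int(modality.split("-")[1]) if "-" in modality else 1
                resp = template_responder(post, config.response_templates,
                                          seed=config.seed + setting)
            rows.append({"post_id": post.id, "group": group, "modality": modality,
                         "post_text": post.body, "response_text": resp})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Themed documents for the topic stage


def gen_themed_corpus(n_themes: int = 6, docs_per_theme: int = 60, seed: int = 0,
                      theme_vocab_size: int = 20, rare_vocab_size: int = 400,
                      theme_words_per_doc: tuple[int, int] = (6, 10),
                      rare_words_per_doc: tuple[int, int] = (3, 4),
                      ) -> tuple[list[str], np.ndarray]:
    """Documents with well-separated planted theme vocabularies.

    Each theme owns a disjoint slice of the neutral vocabulary; a document
    samples a subset of its theme's words plus a few rare idiosyncratic
    tokens from a large shared pool (compounds of two vocabulary words,
    emulating author-specific vocabulary). Merging two themes mixes
    never-co-occurring keyword sets (strongly negative pairwise
    association); over-splitting a theme lets rare tokens, which almost
    never co-occur, into the sub-clusters' top keywords — so coherence
    genuinely peaks at the planted number of themes.

    Returns (documents, theme labels).
    """
    vocab = load_background_vocab()
    if n_themes * theme_vocab_size > len(vocab):
        raise ValueError("theme vocabularies exceed the shipped word list")
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(vocab))
    themes = [shuffled[i * theme_vocab_size:(i + 1) * theme_vocab_size]
              for i in range(n_themes)]
    rare_pool = []
    while len(rare_pool) < rare_vocab_size:
        a, b = rng.choice(vocab, size=2, replace=False)
        if (a + b) not in rare_pool:
            rare_pool.append(a + b)

    docs: list[str] = []
    labels = np.repeat(np.arange(n_themes), docs_per_theme)
    for theme_id in labels:
        k_theme = int(rng.integers(theme_words_per_doc[0], theme_words_per_doc[1] + 1))
        k_rare = int(rng.integers(rare_words_per_doc[0], rare_words_per_doc[1] + 1))
        words = list(rng.choice(themes[theme_id], size=k_theme, replace=False))
        for rare in rng.choice(rare_pool, size=k_rare, replace=False):
            # repeated signature tokens: concentrated rare mass is what
            # over-split clusters surface, degrading their coherence
            words += [str(rare)] * int(rng.integers(1, 4))
        docs.append(" ".join(rng.permutation(words)))
    return docs, labels
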