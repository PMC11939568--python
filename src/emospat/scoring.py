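"""Lexicon-based emotion scoring of short social-media texts.

The score of a sentence is the sum, over every matched emotion word, of

    (product of the weights of the contiguous run of negation/degree
     modifiers immediately to the word's left) × polarity_sign × intensity.

Negation weights are negative, so a single negation flips the sign of the
word it modifies and double negation restores it; degree adverbs scale the
contribution multiplicatively.  Only the maximal run of modifier tokens
directly left-adjacent to an emotion word counts — a modifier separated
from the emotion word by any other token (including a previous emotion
word) contributes nothing.

A post is split into sentences at terminal punctuation; the post score is
the sum of its sentence scores, and its valence is the sign of that score
(exactly zero, including no-match posts, is neutral — an optional dead band
``neutral_eps`` widens the neutral zone).

Tokenisation is pluggable: any callable ``text -> list[str]`` works.  The
default :class:`VocabularyTokenizer` is a deterministic longest-match
segmenter over a protected vocabulary (lexicon + modifiers + any extra
words), suitable for unspaced CJK text; words present in the vocabulary are
never split.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import pandas as pd

from .lexicon import Lexicon, ModifierSet

#: Sentence-terminal punctuation (configurable per call).
DEFAULT_SENTENCE_BREAKS = "。！？!?；;"

_URL_RE = re.compile(r"https?://\S+|www\.\S+")
_MENTION_RE = re.compile(r"@[\w一-鿿\-]+")
_DEFAULT_FILLERS = ("转发微博", "repost", "转发", "嗯", "呃", "um", "uh")

_CJK_RE = re.compile(r"[一-鿿]")


def preprocess(
    text: str,
    emoji_map: dict[str, str] | None = None,
    fillers: Sequence[str] = _DEFAULT_FILLERS,
) -> str:
    """Strip mentions, URLs, repost markers and fillers; map emojis to text.

    Deterministic and idempotent on already-clean text; an empty result is
    allowed.  Emoji shortcodes (e.g. ``[拳头]``) found in *emoji_map* are
    replaced by their textual interpretation; unknown bracketed codes are
    dropped.
    """
    if not text:
        return ""
    out = _URL_RE.sub(" ", text)
    out = _MENTION_RE.sub(" ", out)
    if emoji_map:
        for emoji, repl in emoji_map.items():
            out = out.replace(emoji, " " + repl + " ")
    # unknown bracketed emoji shortcodes carry no scoreable content
    out = re.sub(r"\[[^\[\]\s]{1,8}\]", " ", out)
    for filler in sorted(fillers, key=len, reverse=True):
        out = out.replace(filler, " ")
    out = out.replace("：", " ").replace(":", " ")
    return re.sub(r"\s+", " ", out).strip()


class VocabularyTokenizer:
    """Deterministic longest-match segmenter over a protected vocabulary.

    At each position the longest vocabulary word starting there is emitted
    as one token; elsewhere, runs of non-vocabulary CJK characters fall back
    to single-character tokens and non-CJK runs split on whitespace.
    Vocabulary words are therefore never split, and token order follows
    text order.
    """

    def __init__(self, vocabulary: Iterable[str]):
        vocab = {w for w in vocabulary if w}
        self._vocab = vocab
        self._maxlen = max((len(w) for w in vocab), default=1)

    def __call__(self, text: str) -> list[str]:
        tokens: list[str] = []
        buf: list[str] = []  # pending non-vocabulary, non-CJK characters

        def flush():
            if buf:
                tokens.extend("".join(buf).split())
                buf.clear()

        i, n = 0, len(text)
        while i < n:
            match = None
            for L in range(min(self._maxlen, n - i), 0, -1):
                cand = text[i : i + L]
                if cand in self._vocab:
                    match = cand
                    break
            if match is not None:
                flush()
                tokens.append(match)
                i += len(match)
            else:
                ch = text[i]
                if _CJK_RE.match(ch):
                    flush()
                    tokens.append(ch)
                else:
                    buf.append(ch)
                i += 1
        flush()
        return tokens


def build_tokenizer(
    lexicon: Lexicon,
    modifiers: ModifierSet | None = None,
    extra_vocab: Iterable[str] = (),
) -> VocabularyTokenizer:
    """Tokenizer whose protected vocabulary covers everything the scorer matches."""
    vocab = set(lexicon.words)
    if modifiers is not None:
        vocab.update(modifiers.words)
    vocab.update(extra_vocab)
    return VocabularyTokenizer(vocab)


def score_sentence(
    tokens: Sequence[str],
    lexicon: Lexicon,
    modifiers: ModifierSet,
) -> tuple[float, list[tuple[str, float]]]:
    """Score one tokenised sentence; returns ``(score, matches)``.

    ``matches`` lists each matched emotion word with its final weight, so
    ``score == sum(w for _, w in matches)`` exactly.  A sentence without
    emotion words scores 0 with empty matches.  Words of zero signed weight
    (neutral/ambiguous polarity) are excluded from matching; like any other
    non-modifier token they terminate a modifier run.
    """
    score = 0.0
    matches: list[tuple[str, float]] = []
    run_product = 1.0  # product over the current contiguous modifier run
    in_run = False
    for tok in tokens:
        entry = lexicon.get(tok)
        if entry is not None and entry.sign != 0.0:
            w = (run_product if in_run else 1.0) * entry.signed_weight
            matches.append((tok, w))
            score += w
            run_product, in_run = 1.0, False
        elif tok in modifiers:
            run_product = (run_product if in_run else 1.0) * modifiers.weight(tok)
            in_run = True
        else:
            run_product, in_run = 1.0, False
    return score, matches


def split_sentences(text: str, breaks: str = DEFAULT_SENTENCE_BREAKS) -> list[str]:
    """Split at terminal punctuation; text with none is a single sentence."""
    if not text:
        return []
    parts = re.split("[" + re.escape(breaks) + "]+", text)
    return [p for p in (s.strip() for s in parts) if p]


def classify_valence(score: float, neutral_eps: float = 0.0) -> str:
    """positive if score > eps, negative if score < −eps, else neutral."""
    if score > neutral_eps:
        return "positive"
    if score < -neutral_eps:
        return "negative"
    return "neutral"


@dataclass
class ScoringConfig:
    """Everything the scorer needs besides the text itself."""

    lexicon: Lexicon
    modifiers: ModifierSet
    emoji_map: dict[str, str] | None = None
    tokenizer: Callable[[str], list[str]] | None = None
    sentence_breaks: str = DEFAULT_SENTENCE_BREAKS
    neutral_eps: float = 0.0
    fillers: Sequence[str] = _DEFAULT_FILLERS

    def __post_init__(self):
        if self.tokenizer is None:
            self.tokenizer = build_tokenizer(self.lexicon, self.modifiers)


@dataclass(frozen=True)
class ScoredPost:
    post_id: object
    score: float
    valence: str
    matches: tuple = field(default_factory=tuple)


def score_text(text: str, config: ScoringConfig) -> tuple[float, list[tuple[str, float]]]:
    """Preprocess, sentence-split, tokenize and score a raw text."""
    clean = preprocess(text, config.emoji_map, config.fillers)
    total = 0.0
    matches: list[tuple[str, float]] = []
    for sentence in split_sentences(clean, config.sentence_breaks):
        s, m = score_sentence(config.tokenizer(sentence), config.lexicon, config.modifiers)
        total += s
        matches.extend(m)
    return total, matches


def score_post(post_id, text: str, config: ScoringConfig) -> ScoredPost:
    score, matches = score_text(text, config)
    return ScoredPost(post_id, score, classify_valence(score, config.neutral_eps),
                      tuple(matches))


def score_posts(posts: pd.DataFrame, config: ScoringConfig) -> pd.DataFrame:
    """Score a post table; returns it with ``score``/``valence``/``n_matches`` added.

    *posts* must carry ``post_id``, ``timestamp``, ``region_code`` and
    ``text`` columns; extra columns (likes, comments) pass through.
    """
    required = {"post_id", "timestamp", "region_code", "text"}
    missing = required - set(posts.columns)
    if missing:
        raise ValueError(f"post table missing column(s): {sorted(missing)}")
    scores, valences, n_matches = [], [], []
    for text in posts["text"].astype(str):
        s, m = score_text(text, config)
        scores.append(s)
        valences.append(classify_valence(s, config.neutral_eps))
        n_matches.append(len(m))
    out = posts.copy()
    out["score"] = scores
    out["valence"] = valences
    out["n_matches"] = n_matches
    out["timestamp"] = pd.to_datetime(out["timestamp"])
    return out
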