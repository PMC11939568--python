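"""Emotion lexicons, modifier lists and emoji maps.

The scorer matches text against three vocabularies:

* an **emotion lexicon** — words annotated with an emotion category (the
  seven-class joy/like/anger/sadness/fear/disgust/surprise taxonomy plus a
  free subcategory tag), an ordinal intensity in {1, 3, 5, 7, 9}, and a
  polarity (positive / negative / neutral / ambiguous);
* a **modifier list** — negation words (negative weights, conventionally −1)
  and degree adverbs (positive multipliers, e.g. 2.0 for the strongest
  intensifiers, 0.5 for diminishers);
* an **emoji map** — emoji shortcodes replaced by emotion-bearing text
  before tokenisation.

Only polarity × intensity enters scoring; the category columns are carried
for bookkeeping and per-category summaries downstream of this package.

All three files are UTF-8 TSV with a header row.  A base lexicon can be
merged with a domain *extension* (e.g. newly coined crisis vocabulary); on a
word collision the extension wins and the override is recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from ._errors import LexiconParseError, ValidationError

logger = logging.getLogger(__name__)

#: The seven primary emotion classes of the ontology the lexicon follows.
PRIMARY_CATEGORIES = frozenset(
    {"joy", "like", "anger", "sadness", "fear", "disgust", "surprise"}
)

VALID_INTENSITIES = frozenset({1, 3, 5, 7, 9})
VALID_POLARITIES = frozenset({"positive", "negative", "neutral", "ambiguous"})

_POLARITY_SIGN = {"positive": 1.0, "negative": -1.0, "neutral": 0.0, "ambiguous": 0.0}


@dataclass(frozen=True)
class LexiconEntry:
    """One emotion word with its annotation triple."""

    word: str
    category: str
    subcategory: str
    intensity: int
    polarity: str
    source: str = "base"

    def __post_init__(self):
        if not self.word:
            raise ValidationError("lexicon word must be a non-empty string")
        if self.intensity not in VALID_INTENSITIES:
            raise ValidationError(
                f"intensity {self.intensity!r} for {self.word!r} not in "
                f"{sorted(VALID_INTENSITIES)}"
            )
        if self.polarity not in VALID_POLARITIES:
            raise ValidationError(
                f"polarity {self.polarity!r} for {self.word!r} not one of "
                f"{sorted(VALID_POLARITIES)}"
            )

    @property
    def sign(self) -> float:
        """+1 for positive, −1 for negative, 0 for neutral/ambiguous words."""
        return _POLARITY_SIGN[self.polarity]

    @property
    def signed_weight(self) -> float:
        """The word's unmodified contribution: sign × intensity."""
        return self.sign * self.intensity


@dataclass(frozen=True)
class ModifierEntry:
    """A negation word or degree adverb with its multiplicative weight."""

    word: str
    kind: str  # "negation" | "degree"
    weight: float

    def __post_init__(self):
        if not self.word:
            raise ValidationError("modifier word must be a non-empty string")
        if self.kind not in ("negation", "degree"):
            raise ValidationError(f"modifier kind {self.kind!r} invalid")
        if self.kind == "negation" and not self.weight < 0:
            raise ValidationError(
                f"negation {self.word!r} must carry a negative weight, got {self.weight}"
            )
        if self.kind == "degree" and not self.weight > 0:
            raise ValidationError(
                f"degree word {self.word!r} must carry a positive weight, got {self.weight}"
            )


class Lexicon:
    """An immutable word → :class:`LexiconEntry` mapping with fast lookup."""

    def __init__(self, entries: Iterable[LexiconEntry]):
        self._entries: dict[str, LexiconEntry] = {}
        dupes = []
        for e in entries:
            if e.word in self._entries:
                dupes.append(e.word)
            self._entries[e.word] = e
        if dupes:
            raise ValidationError(
                "duplicate lexicon word(s): " + ", ".join(sorted(set(dupes)))
            )

    def __contains__(self, word: str) -> bool:
        return word in self._entries

    def __getitem__(self, word: str) -> LexiconEntry:
        return self._entries[word]

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def get(self, word, default=None):
        return self._entries.get(word, default)

    @property
    def words(self) -> list[str]:
        return list(self._entries)

    def scorable(self) -> "Lexicon":
        """Subset with a nonzero signed weight (ambiguous/neutral excluded)."""
        return Lexicon(e for e in self if e.sign != 0.0)


@dataclass
class ModifierSet:
    """Negation and degree vocabularies keyed by word."""

    negation: dict[str, ModifierEntry] = field(default_factory=dict)
    degree: dict[str, ModifierEntry] = field(default_factory=dict)

    def __contains__(self, word: str) -> bool:
        return word in self.negation or word in self.degree

    def weight(self, word: str) -> float:
        if word in self.negation:
            return self.negation[word].weight
        return self.degree[word].weight

    @property
    def words(self) -> list[str]:
        return list(self.negation) + list(self.degree)

    def __len__(self) -> int:
        return len(self.negation) + len(self.degree)


def _read_tsv(path, expected_cols):
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in expected_cols if c not in header]
        if missing:
            raise LexiconParseError(
                path, 1, f"missing required column(s): {', '.join(missing)}"
            )
        idx = {c: header.index(c) for c in header}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split("\t")
            if len(cells) < len(expected_cols):
                raise LexiconParseError(
                    path, lineno, f"expected ≥{len(expected_cols)} fields, got {len(cells)}"
                )
            yield lineno, {c: cells[i] if i < len(cells) else "" for c, i in idx.items()}


def load_lexicon(path, source_tag: str = "base") -> Lexicon:
    """Load and validate an emotion lexicon TSV.

    Columns: ``word``, ``category``, ``subcategory`` (optional column),
    ``intensity``, ``polarity``.  Duplicate words within one file are
    rejected; each row is validated against the entry invariants with the
    offending line number in the error.
    """
    entries: dict[str, LexiconEntry] = {}
    for lineno, row in _read_tsv(path, ["word", "category", "intensity", "polarity"]):
        try:
            intensity = int(row["intensity"])
        except ValueError:
            raise LexiconParseError(
                path, lineno, f"intensity {row['intensity']!r} is not an integer"
            ) from None
        try:
            entry = LexiconEntry(
                word=row["word"].strip(),
                category=row["category"].strip(),
                subcategory=row.get("subcategory", "").strip(),
                intensity=intensity,
                polarity=row["polarity"].strip(),
                source=source_tag,
            )
        except ValidationError as exc:
            raise LexiconParseError(path, lineno, str(exc)) from None
        if entry.word in entries:
            raise LexiconParseError(
                path, lineno, f"duplicate word {entry.word!r} in lexicon file"
            )
        entries[entry.word] = entry
    return Lexicon(entries.values())


def load_modifiers(path) -> ModifierSet:
    """Load a modifier TSV with columns ``word``, ``kind``, ``weight``."""
    mods = ModifierSet()
    for lineno, row in _read_tsv(path, ["word", "kind", "weight"]):
        try:
            weight = float(row["weight"])
        except ValueError:
            raise LexiconParseError(
                path, lineno, f"weight {row['weight']!r} is not a number"
            ) from None
        try:
            entry = ModifierEntry(row["word"].strip(), row["kind"].strip(), weight)
        except ValidationError as exc:
            raise LexiconParseError(path, lineno, str(exc)) from None
        table = mods.negation if entry.kind == "negation" else mods.degree
        if entry.word in table:
            raise LexiconParseError(
                path, lineno, f"duplicate {entry.kind} word {entry.word!r}"
            )
        table[entry.word] = entry
    return mods


def load_emoji_map(path) -> dict[str, str]:
    """Load an emoji → replacement-text TSV (columns ``emoji``, ``replacement``)."""
    mapping: dict[str, str] = {}
    for lineno, row in _read_tsv(path, ["emoji", "replacement"]):
        emoji, repl = row["emoji"].strip(), row["replacement"].strip()
        if not repl:
            raise LexiconParseError(path, lineno, f"empty replacement for {emoji!r}")
        if emoji in mapping:
            raise LexiconParseError(path, lineno, f"duplicate emoji {emoji!r}")
        mapping[emoji] = repl
    return mapping


def merge_lexicons(base: Lexicon, extension: Lexicon) -> Lexicon:
    """Union of two lexicons; on a word collision the extension entry wins.

    Every override is logged at INFO level so the provenance of scoring
    decisions stays auditable.
    """
    merged: dict[str, LexiconEntry] = {e.word: e for e in base}
    overridden = []
    for e in extension:
        if e.word in merged:
            overridden.append(e.word)
        merged[e.word] = replace(e, source="extension") if e.source != "extension" else e
    if overridden:
        logger.info(
            "lexicon merge: %d word(s) overridden by extension: %s",
            len(overridden),
            ", ".join(sorted(overridden)),
        )
    return Lexicon(merged.values())


def default_degree_weights() -> Mapping[str, float]:
    """The shipped degree-adverb weight scheme (six strength classes)."""
    return {"most": 2.0, "very": 1.75, "more": 1.5, "over": 1.25,
            "slightly": 0.75, "insufficiently": 0.5}
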