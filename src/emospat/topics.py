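"""Per-stage and per-region ranked term-frequency tables.

These tables are the substrate of the word clouds commonly drawn over
crisis corpora: tokens are counted after stopword removal, ranked by count
with a deterministic lexicographic tie-break, and reported with relative
frequencies (count over all counted tokens in the group, so the listed
frequencies sum to at most 1).
"""

from __future__ import annotations

from collections import Counter
from typing import Callable, Iterable, Sequence

import pandas as pd

from ._errors import UnknownRegionError


def term_frequencies(
    texts: Iterable[str],
    tokenizer: Callable[[str], list[str]],
    stopwords: set[str] | frozenset[str] = frozenset(),
    top_n: int = 100,
) -> pd.DataFrame:
    """Ranked (term, count, freq) over a collection of texts.

    Single-character latin/digit/punctuation tokens are dropped along with
    stopwords; an empty input yields an empty table.
    """
    counts: Counter[str] = Counter()
    for text in texts:
        for tok in tokenizer(str(text)):
            if tok in stopwords:
                continue
            if not any("一" <= ch <= "鿿" or ch.isalpha() for ch in tok):
                continue  # pure punctuation/digit tokens carry no topic
            counts[tok] += 1
    total = sum(counts.values())
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return pd.DataFrame(
        [(term, c, c / total) for term, c in ranked],
        columns=["term", "count", "freq"],
    )


def grouped_term_tables(
    scored: pd.DataFrame,
    partition,
    tokenizer: Callable[[str], list[str]],
    stopwords: set[str] | frozenset[str] = frozenset(),
    regions: Sequence | None = None,
    region_universe: Sequence | None = None,
    top_n: int = 100,
) -> pd.DataFrame:
    """One term table per stage, and per selected region, stacked long.

    Returns columns ``group_kind`` ("stage" or "region"), ``group``,
    ``term``, ``count``, ``freq``.  Groups with no posts yield no rows.
    Requesting a region outside the known universe raises
    :class:`UnknownRegionError`.
    """
    stage = partition.assign(scored["timestamp"])
    frames = []
    for lab, _, _ in partition.intervals:
        sub = scored.loc[stage == lab, "text"]
        tab = term_frequencies(sub, tokenizer, stopwords, top_n)
        tab.insert(0, "group", lab)
        tab.insert(0, "group_kind", "stage")
        frames.append(tab)
    if regions:
        universe = set(region_universe) if region_universe is not None else set(
            scored["region_code"].unique()
        )
        unknown = [r for r in regions if r not in universe]
        if unknown:
            raise UnknownRegionError(unknown)
        for code in regions:
            sub = scored.loc[scored["region_code"] == code, "text"]
            tab = term_frequencies(sub, tokenizer, stopwords, top_n)
            tab.insert(0, "group", code)
            tab.insert(0, "group_kind", "region")
            frames.append(tab)
    if not frames:
        return pd.DataFrame(columns=["group_kind", "group", "term", "count", "freq"])
    return pd.concat(frames, ignore_index=True)
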