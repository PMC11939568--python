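"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive each statistic from its definition
(explicit double loops, explicit modifier-run enumeration) so the fast
implementations are checked against something structurally different.
"""

import numpy as np
import pytest

from emospat import datasets
from emospat.lexicon import Lexicon, LexiconEntry, ModifierEntry, ModifierSet
from emospat.scoring import ScoringConfig


# --------------------------------------------------------------------------
# toy vocabulary (ASCII words so oracle tests read plainly)

@pytest.fixture(scope="session")
def toy_lexicon() -> Lexicon:
    return Lexicon([
        LexiconEntry("goodA", "joy", "", 5, "positive"),
        LexiconEntry("goodB", "like", "", 7, "positive"),
        LexiconEntry("goodC", "joy", "", 1, "positive"),
        LexiconEntry("badA", "sadness", "", 5, "negative"),
        LexiconEntry("badB", "anger", "", 3, "negative"),
        LexiconEntry("badC", "fear", "", 9, "negative"),
        LexiconEntry("meh", "surprise", "", 3, "ambiguous"),
    ])


@pytest.fixture(scope="session")
def toy_modifiers() -> ModifierSet:
    mods = ModifierSet()
    for w in ("not", "never"):
        mods.negation[w] = ModifierEntry(w, "negation", -1.0)
    for w, wt in (("most", 2.0), ("very", 1.75), ("slightly", 0.75), ("barely", 0.5)):
        mods.degree[w] = ModifierEntry(w, "degree", wt)
    return mods


@pytest.fixture(scope="session")
def toy_config(toy_lexicon, toy_modifiers) -> ScoringConfig:
    return ScoringConfig(lexicon=toy_lexicon, modifiers=toy_modifiers,
                         tokenizer=str.split)


@pytest.fixture(scope="session")
def packaged_lexicon():
    return datasets.synthetic_lexicon()


@pytest.fixture(scope="session")
def packaged_modifiers():
    return datasets.synthetic_modifiers()


# --------------------------------------------------------------------------
# oracles

def brute_force_score(tokens, lexicon, modifiers):
    """Reference scorer: enumerate each emotion word's modifier run explicitly."""
    total = 0.0
    matches = []
    is_mod = [t in modifiers and t not in lexicon._entries for t in tokens]
    # NB: a token that is both emotion word and modifier cannot occur in the
    # fixtures; lexicon membership wins in the implementation.
    for p, tok in enumerate(tokens):
        entry = lexicon.get(tok)
        if entry is None or entry.sign == 0.0:
            continue
        # walk left over the maximal contiguous run of modifiers
        j = p
        while j > 0 and is_mod[j - 1]:
            j -= 1
        weight = 1.0
        for q in range(j, p):
            weight *= modifiers.weight(tokens[q])
        w = weight * entry.sign * entry.intensity
        matches.append((tok, w))
        total += w
    return total, matches


def brute_force_global_moran(x, W):
    """Double-loop evaluation of the global Moran's I definition."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xbar = x.mean()
    s2 = sum((xi - xbar) ** 2 for xi in x) / n
    num = 0.0
    s0 = 0.0
    M = W.matrix
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num += M[i, j] * (x[i] - xbar) * (x[j] - xbar)
            s0 += M[i, j]
    return num / (s2 * s0)


def brute_force_local_moran(x, W):
    """Double-loop evaluation of the local Moran's I definition."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xbar = x.mean()
    s2 = sum((xi - xbar) ** 2 for xi in x) / n
    M = W.matrix
    out = np.zeros(n)
    for i in range(n):
        lag = 0.0
        for j in range(n):
            lag += M[i, j] * (x[j] - xbar)
        out[i] = (x[i] - xbar) * lag / s2
    return out


def random_weights(rng, n, k):
    """A random k-NN weight structure from random coordinates."""
    from emospat.spatial import RegionSet, knn_weights

    codes = tuple(f"R{i:02d}" for i in range(n))
    regions = RegionSet(codes, rng.uniform(-170, 170, n), rng.uniform(-80, 80, n))
    return knn_weights(regions, k)


@pytest.fixture(scope="session")
def paired_regions():
    """4 regions in two far-apart close pairs: each unit's 1-NN is its pair."""
    from emospat.spatial import RegionSet

    return RegionSet(("A", "B", "C", "D"),
                     lon=np.array([0.0, 0.2, 90.0, 90.2]),
                     lat=np.array([0.0, 0.0, 10.0, 10.0]))
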