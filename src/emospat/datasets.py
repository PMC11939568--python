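"""Packaged fixture data.

The shipped lexicon, modifier list and emoji map are **synthetic**: a small
hand-authored vocabulary following the seven-class / {1,3,5,7,9}-intensity
annotation scheme, sufficient to exercise the whole pipeline and the test
suite.  They are not, and do not contain, any licensed lexicon's content.
The province table carries approximate (rounded) centroid coordinates for
the 31 mainland province-level regions; only inter-centroid distances enter
the analysis, so rounding is immaterial.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .lexicon import Lexicon, ModifierSet, load_emoji_map, load_lexicon, load_modifiers
from .spatial import RegionSet

_DATA = files("emospat") / "data"


def data_path(name: str):
    """Filesystem path of a packaged data file."""
    return _DATA / name


def synthetic_lexicon() -> Lexicon:
    """The shipped synthetic emotion lexicon (45 positive, 45 negative words)."""
    return load_lexicon(data_path("synthetic_lexicon.tsv"))


def synthetic_modifiers() -> ModifierSet:
    """The shipped negation (4) and degree-adverb (6) lists."""
    return load_modifiers(data_path("synthetic_modifiers.tsv"))


def synthetic_emoji_map() -> dict[str, str]:
    return load_emoji_map(data_path("synthetic_emoji_map.tsv"))


def default_stopwords() -> set[str]:
    text = data_path("stopwords.txt").read_text(encoding="utf-8")
    return {w for w in text.split() if w}


def china_province_centroids() -> RegionSet:
    """31 mainland province-level regions with approximate centroids."""
    return RegionSet.from_frame(pd.read_csv(data_path("china_province_centroids.csv")))


#: Stage-characteristic topic vocabulary used by the synthetic generator:
#: crisis-source terms early, containment terms mid-crisis, recovery terms late.
STAGE_TOPICS = {
    "T1": ("酒吧", "北京", "核酸", "疫情", "口罩", "朝阳", "传播", "病例", "封控"),
    "T2": ("隔离", "防疫", "防控", "检测", "排查", "居家", "政策", "通知", "疫情"),
    "T3": ("结束", "正常", "生活", "恢复", "日常", "出行", "疫情", "北京"),
}

#: Topic words common to every stage.
GENERAL_TOPICS = ("疫情", "北京", "大家", "今天", "消息")
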