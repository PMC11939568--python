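"""End-to-end model: posts + regions + lexicon → fitted spatiotemporal results.

:class:`EmotionSpatialModel` bundles the data (a post table, a region set,
an emotion lexicon with modifiers) and the configuration; :meth:`fit` runs
the full analysis —

1. lexicon scoring of every post (signed score + valence),
2. daily aggregation and stage segmentation (T1 emergency / T2 contagion /
   T3 resolution),
3. per-(region, stage) emotion heat, ``ln(1 + count of emotion-bearing
   posts)``,
4. k-NN spatial weights and global Moran's I permutation tests per stage
   (including the whole window, stage "T"),
5. local Moran (LISA) tests with HH/LL/HL/LH cluster typing,
6. per-stage valence shares, per-(region, stage) valence dominance, and
   per-stage term-frequency tables —

and returns an :class:`EmotionSpatialResults` carrying every table, with a
``summary()`` in the spirit of a regression results printout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import datasets, spatial, staging, topics
from .lexicon import Lexicon, ModifierSet, load_emoji_map, load_lexicon, load_modifiers
from .scoring import ScoringConfig, build_tokenizer, score_posts
from .spatial import RegionSet


class EmotionSpatialModel:
    """Spatiotemporal public-emotion analysis of a geotagged post table.

    Parameters
    ----------
    posts
        One row per post with columns ``post_id``, ``timestamp``,
        ``region_code``, ``text`` (extra columns pass through).
    regions
        The region universe with centroid coordinates.
    lexicon, modifiers
        The emotion vocabulary the scorer matches.  Default: the packaged
        synthetic fixtures.
    emoji_map, stopwords, extra_vocab
        Optional preprocessing resources; ``extra_vocab`` protects extra
        domain words (e.g. crisis neologisms) from being split by the
        tokenizer.
    """

    def __init__(
        self,
        posts: pd.DataFrame,
        regions: RegionSet | None = None,
        lexicon: Lexicon | None = None,
        modifiers: ModifierSet | None = None,
        emoji_map: dict[str, str] | None = None,
        stopwords: set[str] | None = None,
        extra_vocab: Iterable[str] = (),
        neutral_eps: float = 0.0,
    ):
        self.posts = posts
        self.regions = regions if regions is not None else datasets.china_province_centroids()
        self.lexicon = lexicon if lexicon is not None else datasets.synthetic_lexicon()
        self.modifiers = modifiers if modifiers is not None else datasets.synthetic_modifiers()
        self.emoji_map = emoji_map
        self.stopwords = stopwords if stopwords is not None else datasets.default_stopwords()
        self.extra_vocab = tuple(extra_vocab)
        self.tokenizer = build_tokenizer(self.lexicon, self.modifiers, self.extra_vocab)
        self.scoring_config = ScoringConfig(
            lexicon=self.lexicon, modifiers=self.modifiers, emoji_map=self.emoji_map,
            tokenizer=self.tokenizer, neutral_eps=neutral_eps,
        )
        # fail early on unknown regions rather than mid-fit
        self.regions.index_of(posts["region_code"].unique())

    @classmethod
    def from_csv(
        cls,
        posts_path,
        regions_path=None,
        lexicon_path=None,
        modifiers_path=None,
        emoji_map_path=None,
        **kwargs,
    ) -> "EmotionSpatialModel":
        posts = pd.read_csv(posts_path)
        regions = RegionSet.from_csv(regions_path) if regions_path else None
        lexicon = load_lexicon(lexicon_path) if lexicon_path else None
        modifiers = load_modifiers(modifiers_path) if modifiers_path else None
        emoji_map = load_emoji_map(emoji_map_path) if emoji_map_path else None
        return cls(posts, regions, lexicon, modifiers, emoji_map, **kwargs)

    def fit(
        self,
        k: int = 9,
        n_perm: int = 999,
        seed: int | None = 0,
        alpha: float = 0.05,
        smooth_days: int = 3,
        persist_days: int = 3,
        trailing_days: int = 7,
        manual_breaks: tuple | None = None,
        heat_transform: str = "log_count",
        top_n_terms: int = 100,
        term_regions: Sequence | None = None,
    ) -> "EmotionSpatialResults":
        """Run the full pipeline and return the fitted results.

        ``seed`` drives every permutation test (global and local, each
        stage getting an independent stream); ``k`` is the number of
        nearest neighbours in the spatial weights; ``manual_breaks``
        overrides the automatic stage rule with explicit
        ``(t2_start, t3_start)`` dates.
        """
        scored = score_posts(self.posts, self.scoring_config)
        daily = staging.daily_aggregate(scored)
        partition = staging.segment_stages(
            daily, smooth_days=smooth_days, persist_days=persist_days,
            trailing_days=trailing_days, manual_breaks=manual_breaks,
        )
        shares = staging.valence_shares(daily, partition)
        heat = spatial.compute_heat(scored, partition, self.regions, heat_transform)
        weights = spatial.knn_weights(self.regions, k)
        base_seed = 0 if seed is None else seed
        stage_labels = ["T"] + [lab for lab, _, _ in partition.intervals]
        global_results = {}
        local_results = {}
        for i, lab in enumerate(stage_labels):
            x = spatial.heat_vector(heat, self.regions, lab)
            # independent, reproducible stream per (stage, test)
            global_results[lab] = spatial.global_moran_test(
                x, weights, method="permutation", n_perm=n_perm,
                seed=np.random.default_rng(np.random.SeedSequence((base_seed, 2 * i))),
            )
            local_results[lab] = spatial.local_moran_test(
                x, weights, n_perm=n_perm,
                seed=np.random.default_rng(np.random.SeedSequence((base_seed, 2 * i + 1))),
                alpha=alpha,
            )
        dominance = spatial.valence_dominance(scored, partition, self.regions)
        term_tables = topics.grouped_term_tables(
            scored, partition, self.tokenizer, self.stopwords,
            regions=term_regions, region_universe=self.regions.codes,
            top_n=top_n_terms,
        )
        return EmotionSpatialResults(
            model=self, scored=scored, daily=daily, partition=partition,
            valence_shares=shares, heat=heat, weights=weights,
            global_moran=global_results, local_moran=local_results,
            dominance=dominance, term_tables=term_tables,
            k=k, n_perm=n_perm, seed=seed, alpha=alpha,
        )


@dataclass
class EmotionSpatialResults:
    """Fitted tables and statistics; see the attributes' own docstrings."""

    model: EmotionSpatialModel
    scored: pd.DataFrame
    daily: pd.DataFrame
    partition: staging.StagePartition
    valence_shares: pd.DataFrame
    heat: pd.DataFrame
    weights: spatial.SpatialWeights
    global_moran: dict
    local_moran: dict
    dominance: pd.DataFrame
    term_tables: pd.DataFrame
    k: int
    n_perm: int
    seed: int | None
    alpha: float

    @property
    def global_table(self) -> pd.DataFrame:
        """Per-stage global Moran's I, E(I), VAR(I), Z and p (one row per stage)."""
        rows = {lab: res.to_dict() for lab, res in self.global_moran.items()}
        return pd.DataFrame.from_dict(rows, orient="index")

    @property
    def lisa_table(self) -> pd.DataFrame:
        """Per-(stage, region) local Moran's I, Z, p and cluster label."""
        frames = []
        for lab, res in self.local_moran.items():
            f = res.to_frame()
            f.insert(0, "stage", lab)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    @property
    def lisa_counts(self) -> pd.DataFrame:
        """HH/LL/HL/LH/NS counts per stage (rows sum to the number of regions)."""
        return spatial.lisa_summary(self.local_moran)

    def summary(self) -> str:
        n = len(self.scored)
        lines = [
            "Spatiotemporal public-emotion analysis",
            "=" * 54,
            f"posts: {n}   regions: {len(self.model.regions)}   "
            f"k-NN: {self.k}   permutations: {self.n_perm}   seed: {self.seed}",
            "",
            "Stage partition",
            "-" * 54,
        ]
        for lab, s, e in self.partition.intervals:
            sh = self.valence_shares.loc[lab]
            lines.append(
                f"  {lab}: {s.date()} .. {e.date()}   "
                f"pos {sh.share_pos:5.1%}  neg {sh.share_neg:5.1%}  "
                f"neu {sh.share_neu:5.1%}  (n={int(sh.n_total)})"
            )
        lines += ["", "Global Moran's I (emotion heat, permutation test)", "-" * 54,
                  f"  {'stage':<6}{'I':>8}{'E(I)':>9}{'Z':>8}{'p':>8}"]
        for lab, res in self.global_moran.items():
            lines.append(
                f"  {lab:<6}{res.I:8.3f}{res.E_I:9.4f}{res.Z:8.3f}{res.p:8.3f}"
            )
        lines += ["", "LISA cluster counts", "-" * 54,
                  "  " + self.lisa_counts.to_string().replace("\n", "\n  ")]
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write every result table as CSV under *outdir*."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.scored.to_csv(outdir / "scored_posts.csv", index=False)
        self.daily.to_csv(outdir / "daily_series.csv")
        self.partition.to_frame().to_csv(outdir / "stages.csv", index=False)
        self.valence_shares.to_csv(outdir / "valence_shares.csv")
        self.heat.to_csv(outdir / "heat.csv", index=False)
        self.weights.to_triplets().to_csv(outdir / "weights.csv", index=False)
        self.global_table.to_csv(outdir / "global_moran.csv", index_label="stage")
        self.lisa_table.to_csv(outdir / "lisa.csv", index=False)
        self.dominance.to_csv(outdir / "valence_dominance.csv", index=False)
        self.term_tables.to_csv(outdir / "term_tables.csv", index=False)

    def plot_daily(self, ax=None):
        """Daily mean emotion score with stage shading (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3.5))
        ax.plot(self.daily.index, self.daily["mean_score"], lw=1.2)
        ax.axhline(0, color="k", lw=0.6)
        shade = {"T1": "#f4cccc", "T2": "#fff2cc", "T3": "#d9ead3"}
        for lab, s, e in self.partition.intervals:
            ax.axvspan(s, e + pd.Timedelta(days=1), color=shade[lab], alpha=0.5)
            ax.text(s, ax.get_ylim()[1], lab, va="top")
        ax.set_ylabel("mean emotion score")
        return ax
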