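"""Synthetic geotagged-post scenarios with known ground truth.

The generator emulates the statistical structure of a crisis-period
microblog corpus so every pipeline stage is testable without any real
download:

* ~31 province-level regions with centroids (the packaged approximate
  centroid table by default, or a jittered grid);
* a 70-day study window split into three planned stages with
  stage-dependent valence mixes — negative-dominant in the emergency stage
  T1 (default 55% negative / 15% positive / 30% neutral), positive-dominant
  later (T2 25/45/30, T3 10/60/30);
* heavy-tailed per-region posting volumes (lognormal region effects) with
  declining stage volume factors as public attention decays;
* planted high-heat spatial clusters — by default the outbreak region and
  its 7 nearest neighbours post at a multiple of their base rate during the
  emergency and contagion stages;
* post text composed from the synthetic lexicon with known negation/degree
  semantics, so the drawn valence of every post is preserved under scoring
  by construction (a negated positive word only ever realises a
  negative-valence post).

Identical seeds produce byte-identical output.  Every scenario carries its
:class:`GroundTruth` (true rates, mixes, cluster flags, planted stage
boundaries) so recovery can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import ValidationError
from . import datasets
from .spatial import RegionSet, haversine_matrix

DEFAULT_MIXES = {
    "T1": {"positive": 0.15, "negative": 0.55, "neutral": 0.30},
    "T2": {"positive": 0.45, "negative": 0.25, "neutral": 0.30},
    "T3": {"positive": 0.60, "negative": 0.10, "neutral": 0.30},
}

#: Stage volume factors: attention spikes in the emergency stage and decays.
DEFAULT_VOLUME_FACTORS = {"T1": 3.0, "T2": 1.0, "T3": 0.4}

#: Stage lengths in days over the default 70-day window.
DEFAULT_STAGE_DAYS = {"T1": 10, "T2": 25, "T3": 35}


@dataclass(frozen=True)
class PlantedCluster:
    """A set of regions posting at ``multiplier`` × base rate in some stages."""

    regions: tuple
    multiplier: float
    stages: tuple = ("T1", "T2")

    def __post_init__(self):
        if self.multiplier < 1:
            raise ValidationError(f"cluster multiplier must be ≥ 1, got {self.multiplier}")


@dataclass(frozen=True)
class SyntheticScenario:
    seed: int
    regions: RegionSet
    start: pd.Timestamp
    stage_days: Mapping[str, int]
    mixes: Mapping[str, Mapping[str, float]]
    volume_factors: Mapping[str, float]
    base_rates: np.ndarray  # posts/day per region before stage/cluster factors
    clusters: tuple  # of PlantedCluster
    outbreak_region: str

    def __post_init__(self):
        for lab, mix in self.mixes.items():
            s = sum(mix.values())
            if abs(s - 1.0) > 1e-9:
                raise ValidationError(f"valence mix for {lab} sums to {s}, not 1")
        codes = set(self.regions.codes)
        for cl in self.clusters:
            extra = set(cl.regions) - codes
            if extra:
                raise ValidationError(f"cluster region(s) not in region set: {sorted(extra)}")

    @property
    def n_days(self) -> int:
        return sum(self.stage_days.values())

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n_days, freq="D")

    def stage_of_day(self, day_index: int) -> str:
        cum = 0
        for lab, length in self.stage_days.items():
            cum += length
            if day_index < cum:
                return lab
        raise IndexError(day_index)

    @property
    def stage_boundaries(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        """Planted (T2 start, T3 start) dates."""
        t2 = self.start + pd.Timedelta(days=self.stage_days["T1"])
        t3 = t2 + pd.Timedelta(days=self.stage_days["T2"])
        return t2, t3

    def cluster_regions(self) -> set:
        out: set = set()
        for cl in self.clusters:
            out |= set(cl.regions)
        return out


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery scoring."""

    region_stage: pd.DataFrame  # region_code, stage, true_rate, mix_*, cluster
    t2_start: pd.Timestamp
    t3_start: pd.Timestamp
    cluster_regions: tuple
    region_codes: tuple


def _jittered_grid_regions(n: int, rng: np.random.Generator) -> RegionSet:
    """n regions on a jittered grid over a China-sized bounding box."""
    ncol = int(np.ceil(np.sqrt(n)))
    nrow = int(np.ceil(n / ncol))
    lon = np.linspace(82.0, 128.0, ncol)
    lat = np.linspace(22.0, 48.0, nrow)
    pts = [(x, y) for y in lat for x in lon][:n]
    lons = np.array([p[0] for p in pts]) + rng.uniform(-1.5, 1.5, n)
    lats = np.array([p[1] for p in pts]) + rng.uniform(-1.0, 1.0, n)
    codes = tuple(f"R{i:02d}" for i in range(1, n + 1))
    return RegionSet(codes, lons, lats)


def make_scenario(
    seed: int = 0,
    regions: RegionSet | None = None,
    n_regions: int = 31,
    grid: bool = False,
    start: str = "2022-06-09",
    stage_days: Mapping[str, int] | None = None,
    mixes: Mapping[str, Mapping[str, float]] | None = None,
    volume_factors: Mapping[str, float] | None = None,
    rate_median: float = 2.5,
    rate_sigma: float = 0.35,
    cluster_size: int = 8,
    cluster_multiplier: float = 3.0,
    cluster_stages: Sequence[str] = ("T1", "T2"),
    cluster_regions: Sequence | None = None,
    outbreak_region: str | None = None,
) -> SyntheticScenario:
    """Resolve a fully-specified scenario, reproducible from ``seed``.

    Region base rates are lognormal (median ``rate_median`` posts/day,
    log-scale sigma ``rate_sigma``).  Unless ``cluster_regions`` is given,
    the planted cluster is the outbreak region plus its ``cluster_size``−1
    nearest neighbours by great-circle distance.
    """
    ss = np.random.SeedSequence(seed)
    rng_regions, rng_rates = (np.random.default_rng(c) for c in ss.spawn(2))
    if regions is None:
        if grid:
            regions = _jittered_grid_regions(n_regions, rng_regions)
        else:
            regions = datasets.china_province_centroids()
            if n_regions < len(regions):
                regions = RegionSet(regions.codes[:n_regions],
                                    regions.lon[:n_regions], regions.lat[:n_regions])
    if outbreak_region is None:
        outbreak_region = "BJ" if "BJ" in regions.codes else regions.codes[0]
    base_rates = rate_median * np.exp(rng_rates.normal(0.0, rate_sigma, len(regions)))
    if cluster_regions is None:
        if cluster_size > len(regions):
            raise ValidationError("cluster_size exceeds the number of regions")
        D = haversine_matrix(regions.lon, regions.lat)
        i0 = regions.index_of([outbreak_region])[0]
        order = np.argsort(D[i0], kind="stable")
        picked = [regions.codes[j] for j in order if j != i0][: cluster_size - 1]
        cluster_regions = (outbreak_region, *picked)
    clusters = (PlantedCluster(tuple(cluster_regions), cluster_multiplier,
                               tuple(cluster_stages)),)
    return SyntheticScenario(
        seed=seed,
        regions=regions,
        start=pd.Timestamp(start),
        stage_days=dict(stage_days or DEFAULT_STAGE_DAYS),
        mixes={k: dict(v) for k, v in (mixes or DEFAULT_MIXES).items()},
        volume_factors=dict(volume_factors or DEFAULT_VOLUME_FACTORS),
        base_rates=base_rates,
        clusters=clusters,
        outbreak_region=outbreak_region,
    )


def _compose_text(valence: str, stage: str, rng: np.random.Generator,
                  pos_words, neg_words, negations, degrees) -> str:
    """Compose a post whose score sign under the scorer equals ``valence``.

    Emotion content is built in self-contained chunks: an emotion word of
    the drawn sign, optionally degree-intensified, or an opposite-sign word
    under a single negation (which flips it back to the drawn sign).
    Neutral posts carry topic words only.
    """
    topics_pool = datasets.STAGE_TOPICS[stage] + datasets.GENERAL_TOPICS
    n_topic = int(rng.integers(1, 4))
    chunks = [topics_pool[i] for i in rng.integers(0, len(topics_pool), n_topic)]
    if valence != "neutral":
        same = pos_words if valence == "positive" else neg_words
        opposite = neg_words if valence == "positive" else pos_words
        n_emo = int(rng.integers(1, 5))
        for _ in range(n_emo):
            use_negation = rng.random() < 0.2
            word_pool = opposite if use_negation else same
            word = word_pool[int(rng.integers(0, len(word_pool)))]
            prefix = ""
            if use_negation:
                prefix = negations[int(rng.integers(0, len(negations)))]
            if rng.random() < 0.3:
                prefix += degrees[int(rng.integers(0, len(degrees)))]
            chunks.append(prefix + word)
    order = rng.permutation(len(chunks))
    text = "，".join(chunks[i] for i in order)
    return text + "。"


def generate_posts(scenario: SyntheticScenario) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the post table and its ground truth from a scenario.

    Per (region, day): post count ~ Poisson(base rate × stage volume factor
    × cluster multiplier where applicable); each post's valence follows the
    stage mix and its text realises that valence by construction.
    Timestamps are uniform within the day.  Identical scenarios (same seed)
    give byte-identical tables.
    """
    ss = np.random.SeedSequence(np.random.SeedSequence(scenario.seed).entropy + 1)
    rng = np.random.default_rng(ss)
    lex = datasets.synthetic_lexicon()
    pos_words = sorted(e.word for e in lex if e.polarity == "positive")
    neg_words = sorted(e.word for e in lex if e.polarity == "negative")
    if not pos_words or not neg_words:
        raise ValidationError("lexicon must supply both positive and negative words")
    mods = datasets.synthetic_modifiers()
    negations = sorted(mods.negation)
    degrees = sorted(mods.degree)

    regions = scenario.regions
    cluster_lookup = {
        (code, stage): cl.multiplier
        for cl in scenario.clusters
        for code in cl.regions
        for stage in cl.stages
    }
    valences = np.array(["positive", "negative", "neutral"])
    rows = []
    truth_rows = []
    pid = 0
    dates = scenario.dates
    for r, code in enumerate(regions.codes):
        for d, date in enumerate(dates):
            stage = scenario.stage_of_day(d)
            rate = (scenario.base_rates[r]
                    * scenario.volume_factors[stage]
                    * cluster_lookup.get((code, stage), 1.0))
            count = int(rng.poisson(rate))
            mix = scenario.mixes[stage]
            probs = np.array([mix["positive"], mix["negative"], mix["neutral"]])
            for _ in range(count):
                valence = str(valences[int(rng.choice(3, p=probs))])
                text = _compose_text(valence, stage, rng, pos_words, neg_words,
                                     negations, degrees)
                second = int(rng.integers(0, 86400))
                ts = date + pd.Timedelta(seconds=second)
                pid += 1
                rows.append((
                    f"P{pid:06d}", ts.isoformat(), code, text,
                    int(rng.poisson(3.0)), int(rng.poisson(1.0)), valence,
                ))
    posts = pd.DataFrame(rows, columns=[
        "post_id", "timestamp", "region_code", "text", "likes", "comments",
        "true_valence",
    ]).sort_values("timestamp", kind="stable").reset_index(drop=True)

    for code in regions.codes:
        r = regions.index_of([code])[0]
        for stage, length in scenario.stage_days.items():
            mult = cluster_lookup.get((code, stage), 1.0)
            mix = scenario.mixes[stage]
            truth_rows.append((
                code, stage,
                scenario.base_rates[r] * scenario.volume_factors[stage] * mult,
                mix["positive"], mix["negative"], mix["neutral"],
                mult > 1.0,
            ))
    truth = GroundTruth(
        region_stage=pd.DataFrame(truth_rows, columns=[
            "region_code", "stage", "true_rate", "mix_pos", "mix_neg",
            "mix_neu", "cluster",
        ]),
        t2_start=scenario.stage_boundaries[0],
        t3_start=scenario.stage_boundaries[1],
        cluster_regions=tuple(sorted(scenario.cluster_regions())),
        region_codes=tuple(regions.codes),
    )
    return posts, truth


def make_sign_change_series(
    seed: int,
    n_days: int = 70,
    t2_day: int = 10,
    t3_day: int = 35,
    mean_t1: float = -1.0,
    mean_t2: float = 1.0,
    mean_t3: float = 2.0,
    sigma: float = 0.4,
    posts_per_day: int = 30,
    start: str = "2022-06-09",
) -> tuple[pd.DataFrame, pd.Timestamp, pd.Timestamp]:
    """A daily-series frame with a planted sign change, for staging tests.

    Returns ``(series, planted_t2_start, planted_t3_start)`` in the format
    :func:`emospat.staging.daily_aggregate` produces.
    """
    rng = np.random.default_rng(seed)
    mu = np.where(np.arange(n_days) < t2_day, mean_t1,
                  np.where(np.arange(n_days) < t3_day, mean_t2, mean_t3))
    means = rng.normal(mu, sigma)
    idx = pd.date_range(start, periods=n_days, freq="D")
    n_total = np.full(n_days, posts_per_day)
    series = pd.DataFrame({
        "mean_score": means,
        "n_pos": n_total // 3, "n_neg": n_total // 3,
        "n_neu": n_total - 2 * (n_total // 3),
        "n_total": n_total,
    }, index=idx)
    series.index.name = "date"
    return series, idx[t2_day], idx[t3_day]


def evaluate_recovery(
    truth: GroundTruth,
    partition=None,
    lisa_result=None,
    global_result=None,
) -> dict:
    """Compare pipeline outputs against the planted ground truth.

    Any subset of the outputs may be supplied; the report contains the
    corresponding entries.  ``lisa_result`` is scored against the cluster
    membership flags (HH sensitivity/specificity); ``partition`` against the
    planted stage boundaries (absolute errors in days); ``global_result``
    contributes its Z sign and p-value.
    """
    report: dict = {}
    if partition is not None:
        (_, t2s, _), (_, t3s, _) = partition.intervals[1], partition.intervals[2]
        report["t2_boundary_error_days"] = abs((t2s - truth.t2_start).days)
        report["t3_boundary_error_days"] = abs((t3s - truth.t3_start).days)
    if lisa_result is not None:
        if set(lisa_result.codes) != set(truth.region_codes):
            raise ValidationError("LISA result and ground truth cover different regions")
        cluster = set(truth.cluster_regions)
        labels = dict(zip(lisa_result.codes, lisa_result.cluster))
        tp = sum(labels[c] == "HH" for c in cluster)
        fp = sum(labels[c] == "HH" for c in labels if c not in cluster)
        n_neg = len(labels) - len(cluster)
        report["hh_sensitivity"] = tp / len(cluster) if cluster else float("nan")
        report["hh_specificity"] = 1.0 - fp / n_neg if n_neg else float("nan")
    if global_result is not None:
        report["global_I"] = global_result.I
        report["global_Z"] = global_result.Z
        report["global_p"] = global_result.p
        report["global_significant"] = bool(global_result.p < 0.05)
    return report
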