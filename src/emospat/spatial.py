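"""Spatial autocorrelation of regional emotion heat.

Given a per-region scalar ``x`` (here: log-standardised emotion heat,
``ln(1 + count of emotion-bearing posts)``) and a binary k-nearest-neighbour
weight matrix ``W`` over region centroids, this module computes

* **global Moran's I**

      I = Σ_i Σ_{j≠i} w_ij (x_i − x̄)(x_j − x̄)  /  (S² Σ_i Σ_{j≠i} w_ij)

  with the population variance S² = Σ(x_i − x̄)²/n.  I > 0 indicates that
  similar heat values cluster in space, I < 0 that they alternate, and the
  null expectation is E(I) = −1/(n−1);

* a **significance test** for I, either by random permutation of the
  values over the regions (pseudo p-value) or by the analytic
  randomization moments, both summarised as Z = (I − E(I))/√VAR(I);

* **local Moran's I** (LISA), I_i = (x_i − x̄) Σ_j w_ij (x_j − x̄) / S²,
  with per-region conditional-permutation inference and the usual cluster
  typing — HH hotspots, LL coldspots, HL/LH spatial outliers, NS where not
  significant at the chosen level.

Weights are binary and intentionally not row-standardised (each region's k
nearest neighbours get weight one); with that convention Σ_i I_i = I · S0
where S0 = Σ_ij w_ij = n·k.  Distances between centroids are great-circle
(haversine).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import DegenerateInputError, UnknownRegionError

EARTH_RADIUS_KM = 6371.0088

CLUSTER_LABELS = ("HH", "LL", "HL", "LH", "NS")


@dataclass(frozen=True)
class RegionSet:
    """Ordered region codes with centroid coordinates (decimal degrees)."""

    codes: tuple
    lon: np.ndarray
    lat: np.ndarray
    names: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "lon", np.asarray(self.lon, dtype=float))
        object.__setattr__(self, "lat", np.asarray(self.lat, dtype=float))
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("region codes must be unique")
        if len(self.codes) < 2:
            raise ValueError("need at least 2 regions")
        if not (len(self.codes) == self.lon.size == self.lat.size):
            raise ValueError("codes/lon/lat length mismatch")
        if np.abs(self.lat).max() > 90 or np.abs(self.lon).max() > 180:
            raise ValueError("coordinates outside WGS84 bounds")

    def __len__(self):
        return len(self.codes)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionSet":
        names = tuple(df["name"]) if "name" in df.columns else None
        return cls(tuple(df["region_code"]), df["lon"].to_numpy(),
                   df["lat"].to_numpy(), names)

    @classmethod
    def from_csv(cls, path) -> "RegionSet":
        return cls.from_frame(pd.read_csv(path))

    def index_of(self, codes: Sequence) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.codes)}
        unknown = {c for c in codes if c not in lookup}
        if unknown:
            raise UnknownRegionError(unknown)
        return np.array([lookup[c] for c in codes], dtype=int)


def haversine_matrix(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (km) between points on the sphere."""
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class SpatialWeights:
    """k-NN weight matrix over a region set.

    Binary by construction (each row sums to exactly k, diagonal zero,
    generally asymmetric).  :meth:`row_standardised` returns the
    row-stochastic variant; the statistics accept either, but the binary
    convention is the default throughout.
    """

    matrix: np.ndarray  # (n, n), zero diagonal
    k: int
    codes: tuple
    standardised: bool = False

    def __post_init__(self):
        W = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", W)
        n = W.shape[0]
        if W.shape != (n, n) or n != len(self.codes):
            raise ValueError("weight matrix shape inconsistent with region codes")
        if np.any(np.diag(W) != 0):
            raise ValueError("weight matrix must have a zero diagonal")
        target = 1.0 if self.standardised else self.k
        if not np.allclose(W.sum(axis=1), target):
            raise ValueError(f"every row must sum to {target}")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def s0(self) -> float:
        return float(self.matrix.sum())

    def row_standardised(self) -> "SpatialWeights":
        return SpatialWeights(self.matrix / self.matrix.sum(axis=1, keepdims=True),
                              self.k, self.codes, standardised=True)

    def to_triplets(self) -> pd.DataFrame:
        i, j = np.nonzero(self.matrix)
        return pd.DataFrame({
            "i": [self.codes[a] for a in i],
            "j": [self.codes[b] for b in j],
            "w": self.matrix[i, j],
        })


def knn_weights(regions: RegionSet, k: int) -> SpatialWeights:
    """Binary k-nearest-neighbour weights on great-circle centroid distance.

    Distance ties are broken by region order (the order of ``regions.codes``),
    so the construction is fully deterministic; each row sums to exactly k.
    """
    n = len(regions)
    if not (0 < k < n):
        raise ValueError(f"k must satisfy 0 < k < n ({n}), got {k}")
    D = haversine_matrix(regions.lon, regions.lat)
    W = np.zeros((n, n))
    order_idx = np.arange(n)
    for i in range(n):
        d = D[i].copy()
        d[i] = np.inf  # never self-neighbour
        # stable sort on (distance, region order) → deterministic tie-break
        nearest = np.lexsort((order_idx, d))[:k]
        W[i, nearest] = 1.0
    return SpatialWeights(W, k, tuple(regions.codes))


def _deviations(x: np.ndarray) -> tuple[np.ndarray, float]:
    x = np.asarray(x, dtype=float)
    z = x - x.mean()
    s2 = float(np.mean(z ** 2))  # population variance, per the I definition
    if s2 == 0.0:
        raise DegenerateInputError("degenerate input: zero variance")
    return z, s2


def global_moran(x: np.ndarray, W: SpatialWeights) -> float:
    """Global Moran's I with binary weights and population-variance scaling."""
    z, s2 = _deviations(x)
    M = W.matrix
    return float(z @ M @ z / (s2 * M.sum()))


def local_moran(x: np.ndarray, W: SpatialWeights) -> np.ndarray:
    """Local Moran's I_i = (x_i − x̄) · Σ_j w_ij (x_j − x̄) / S²."""
    z, s2 = _deviations(x)
    return z * (W.matrix @ z) / s2


def _analytic_moments(x: np.ndarray, W: SpatialWeights) -> tuple[float, float]:
    """E(I) and VAR(I) under the randomization (permutation) null."""
    M = W.matrix
    n = W.n
    z, _ = _deviations(x)
    s0 = M.sum()
    s1 = 0.5 * np.sum((M + M.T) ** 2)
    s2 = np.sum((M.sum(axis=1) + M.sum(axis=0)) ** 2)
    e_i = -1.0 / (n - 1)
    m2 = np.mean(z ** 2)
    b2 = np.mean(z ** 4) / m2 ** 2
    num = (n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
           - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0))
    var = num / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - e_i ** 2
    return e_i, float(var)


def _permutation_replicates(z: np.ndarray, W: SpatialWeights, n_perm: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Moran's I for n_perm random permutations of the (centred) values."""
    M = W.matrix
    s0 = M.sum()
    n = z.size
    ss = float(np.sum(z ** 2))
    # (n_perm, n) permutation index matrix; argsort of uniforms is a uniform
    # random permutation per row
    perm = np.argsort(rng.random((n_perm, n)), axis=1)
    Zp = z[perm]
    lag = Zp @ M.T
    return (Zp * lag).sum(axis=1) * n / (s0 * ss)


@dataclass(frozen=True)
class GlobalMoranResult:
    """Global Moran's I with its null moments, Z-score and p-value."""

    I: float
    E_I: float
    VAR_I: float
    Z: float
    p: float
    method: str
    n: int
    s0: float
    n_perm: int | None = None
    alternative: str = "greater"
    perm_replicates: np.ndarray | None = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {"I": self.I, "E_I": self.E_I, "VAR_I": self.VAR_I, "Z": self.Z,
                "p": self.p, "method": self.method, "n": self.n, "s0": self.s0}


def global_moran_test(
    x: np.ndarray,
    W: SpatialWeights,
    method: str = "permutation",
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    alternative: str = "greater",
) -> GlobalMoranResult:
    """Test global Moran's I against the no-autocorrelation null.

    ``method="permutation"`` permutes the values over the regions
    (``n_perm`` seeded draws) and reports the pseudo p-value
    ``(1 + #{I_perm ≥ I_obs}) / (n_perm + 1)`` for ``alternative="greater"``
    (mirrored for ``"less"``, folded and doubled for ``"two-sided"``), with
    E(I) and VAR(I) estimated from the replicates.
    ``method="randomization_analytic"`` uses E(I) = −1/(n−1) and the
    closed-form randomization variance, with a normal-approximation p.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    observed = global_moran(x, W)
    z, _ = _deviations(x)
    if method == "randomization_analytic":
        e_i, var_i = _analytic_moments(x, W)
        zscore = (observed - e_i) / np.sqrt(var_i)
        if alternative == "greater":
            p = stats.norm.sf(zscore)
        elif alternative == "less":
            p = stats.norm.cdf(zscore)
        else:
            p = 2.0 * stats.norm.sf(abs(zscore))
        return GlobalMoranResult(observed, e_i, var_i, float(zscore), float(p),
                                 method, W.n, W.s0, None, alternative)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    if n_perm < 99:
        import warnings

        warnings.warn(f"n_perm={n_perm} is small; pseudo p-values are coarse",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    reps = _permutation_replicates(z, W, n_perm, rng)
    e_i = float(reps.mean())
    var_i = float(reps.var())
    zscore = (observed - e_i) / np.sqrt(var_i) if var_i > 0 else np.nan
    n_ge = int(np.sum(reps >= observed))
    n_le = int(np.sum(reps <= observed))
    if alternative == "greater":
        p = (1 + n_ge) / (n_perm + 1)
    elif alternative == "less":
        p = (1 + n_le) / (n_perm + 1)
    else:
        p = min(1.0, 2.0 * (1 + min(n_ge, n_le)) / (n_perm + 1))
    return GlobalMoranResult(observed, e_i, var_i, float(zscore), float(p),
                             method, W.n, W.s0, n_perm, alternative, reps)


@dataclass(frozen=True)
class LocalMoranResult:
    """Per-region LISA statistics and cluster labels."""

    codes: tuple
    I_i: np.ndarray
    Z_i: np.ndarray
    p_i: np.ndarray
    cluster: tuple
    alpha: float
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "region_code": self.codes,
            "I_i": self.I_i,
            "Z_i": self.Z_i,
            "p_i": self.p_i,
            "cluster": self.cluster,
        })

    def counts(self) -> dict[str, int]:
        return {lab: int(sum(c == lab for c in self.cluster)) for lab in CLUSTER_LABELS}


def local_moran_test(
    x: np.ndarray,
    W: SpatialWeights,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
    fdr: bool = False,
) -> LocalMoranResult:
    """Conditional-permutation LISA test with cluster typing.

    For each region i, x_i is held fixed and the remaining n−1 values are
    randomly reassigned to its neighbours (``n_perm`` seeded draws),
    yielding permutation moments for I_i, a Z-score, and a two-sided pseudo
    p-value.  Significant regions are typed by the quadrant of
    (x_i − x̄, Σ_j w_ij (x_j − x̄)): (+,+) HH, (−,−) LL, (+,−) HL, (−,+) LH;
    everything else is NS.  A region whose permutation distribution is
    degenerate (sd 0) is flagged NS.
    """
    rng = np.random.default_rng(seed)
    z, s2 = _deviations(x)
    M = W.matrix
    n = W.n
    I_obs = z * (M @ z) / s2
    lag_obs = M @ z
    Z_i = np.full(n, np.nan)
    p_i = np.full(n, np.nan)
    for i in range(n):
        others = np.delete(z, i)
        nonzero = np.nonzero(M[i])[0]
        w_row = M[i, nonzero]
        k_i = nonzero.size
        # each row: a fresh permutation of the other n−1 values; the lag
        # only needs the k_i values that land on i's neighbours
        perm = np.argsort(rng.random((n_perm, n - 1)), axis=1)[:, :k_i]
        lag_perm = others[perm] @ w_row
        I_perm = z[i] * lag_perm / s2
        mu, sd = float(I_perm.mean()), float(I_perm.std())
        if sd == 0.0:
            continue  # degenerate null → NS with NaN diagnostics
        Z_i[i] = (I_obs[i] - mu) / sd
        if I_obs[i] >= mu:
            p_one = (1 + int(np.sum(I_perm >= I_obs[i]))) / (n_perm + 1)
        else:
            p_one = (1 + int(np.sum(I_perm <= I_obs[i]))) / (n_perm + 1)
        p_i[i] = min(1.0, 2.0 * p_one)
    p_label = p_i.copy()
    if fdr:
        ok = ~np.isnan(p_i)
        p_label[ok] = stats.false_discovery_control(p_i[ok], method="bh")
    cluster = ["NS"] * n
    for i in range(n):
        if np.isnan(p_label[i]) or p_label[i] >= alpha:
            continue
        hi_self = z[i] > 0
        hi_lag = lag_obs[i] > 0
        cluster[i] = ("HH" if hi_lag else "HL") if hi_self else ("LH" if hi_lag else "LL")
    return LocalMoranResult(tuple(W.codes), I_obs, Z_i, p_i, tuple(cluster),
                            alpha, n_perm)


def lisa_summary(results: dict[str, LocalMoranResult]) -> pd.DataFrame:
    """Counts of HH/LL/HL/LH/NS per stage; rows always sum to n."""
    rows = {stage: res.counts() for stage, res in results.items()}
    return pd.DataFrame.from_dict(rows, orient="index")[list(CLUSTER_LABELS)]


def compute_heat(
    scored: pd.DataFrame,
    partition,
    regions: RegionSet,
    transform: str = "log_count",
    include_overall: bool = True,
) -> pd.DataFrame:
    """Per-(region, stage) emotion heat.

    ``raw_count`` is the number of emotion-bearing (non-neutral) posts in
    the cell; the default transform is ``ln(1 + raw_count)``, which keeps
    zero-post regions well defined at heat 0 and removes the
    orders-of-magnitude spread in regional posting volume.  The
    ``abs_score`` transform uses ``ln(1 + Σ|score|)`` instead.  Stage "T"
    (the whole window) is included alongside T1–T3 by default.
    """
    if transform not in ("log_count", "abs_score"):
        raise ValueError(f"unknown transform {transform!r}")
    regions.index_of(scored["region_code"].unique())  # raises on offenders
    stage = partition.assign(scored["timestamp"])
    emo = scored[scored["valence"] != "neutral"]
    rows = []
    stage_keys = [lab for lab, _, _ in partition.intervals]
    if include_overall:
        stage_keys = ["T"] + stage_keys
    for lab in stage_keys:
        sub = emo if lab == "T" else emo[stage.loc[emo.index] == lab]
        counts = sub.groupby("region_code").size()
        sums = sub.groupby("region_code")["score"].apply(lambda s: float(np.abs(s).sum()))
        for code in regions.codes:
            raw = int(counts.get(code, 0))
            if transform == "log_count":
                heat = float(np.log1p(raw))
            else:
                heat = float(np.log1p(sums.get(code, 0.0)))
            rows.append((code, lab, raw, heat))
    return pd.DataFrame(rows, columns=["region_code", "stage", "raw_count", "heat"])


def heat_vector(heat: pd.DataFrame, regions: RegionSet, stage: str) -> np.ndarray:
    """Heat values for one stage, aligned to the region ordering."""
    sub = heat[heat["stage"] == stage].set_index("region_code")["heat"]
    return sub.reindex(list(regions.codes)).to_numpy(dtype=float)


def valence_dominance(
    scored: pd.DataFrame,
    partition,
    regions: RegionSet,
    include_overall: bool = True,
) -> pd.DataFrame:
    """Dominant valence per (region, stage), ignoring neutral posts.

    ``none`` where a cell has no emotion-bearing posts, ``tie`` on equal
    positive and negative counts.
    """
    regions.index_of(scored["region_code"].unique())
    stage = partition.assign(scored["timestamp"])
    emo = scored[scored["valence"] != "neutral"]
    stage_keys = [lab for lab, _, _ in partition.intervals]
    if include_overall:
        stage_keys = ["T"] + stage_keys
    rows = []
    for lab in stage_keys:
        sub = emo if lab == "T" else emo[stage.loc[emo.index] == lab]
        ct = pd.crosstab(sub["region_code"], sub["valence"])
        for code in regions.codes:
            n_pos = int(ct.at[code, "positive"]) if code in ct.index and "positive" in ct.columns else 0
            n_neg = int(ct.at[code, "negative"]) if code in ct.index and "negative" in ct.columns else 0
            if n_pos == n_neg == 0:
                dom = "none"
            elif n_pos == n_neg:
                dom = "tie"
            else:
                dom = "positive" if n_pos > n_neg else "negative"
            rows.append((code, lab, n_pos, n_neg, dom))
    return pd.DataFrame(rows, columns=["region_code", "stage", "n_pos", "n_neg", "dominant"])
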