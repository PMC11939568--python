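"""Daily aggregation and crisis-stage segmentation of the emotion series.

Public-opinion research on sudden public-health events commonly divides the
response into an **emergency** stage (T1, negative emotion dominates), a
**contagion** stage (T2, the daily mean emotion crosses zero and fluctuates
above it) and a **resolution** stage (T3, a sustained, elevated positive
level).  This module codifies that qualitative description as a
reproducible sign-persistence rule on the smoothed daily mean score:

* the series is smoothed with a centred moving average of ``smooth_days``
  (zero-post days are interpolated linearly first and can never start a
  persistence run);
* **T1** runs from the window start to the day before the first day on
  which the smoothed mean is ≥ 0 for ``persist_days`` consecutive days;
* **T3** starts at the first later day from which the smoothed mean stays
  ≥ 0 through the end of the window *and* whose preceding
  ``trailing_days``-day mean exceeds the whole-window mean (the trailing
  window ends the day before the candidate, so T3 begins where the level
  has already risen);
* **T2** is the remainder.

Manual break dates always override the rule — segmentation of a single
observed crisis is ultimately a judgement call, and the automatic rule is a
default, not a verdict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._errors import StageSegmentationError

STAGE_LABELS = ("T1", "T2", "T3")


@dataclass(frozen=True)
class StagePartition:
    """Contiguous, exhaustive T1/T2/T3 intervals over the study window."""

    intervals: tuple  # ((label, start_date, end_date), ...)

    def __post_init__(self):
        labels = tuple(lab for lab, _, _ in self.intervals)
        if labels != STAGE_LABELS:
            raise ValueError(f"stage labels must be {STAGE_LABELS} in order, got {labels}")
        for (_, s, e) in self.intervals:
            if e < s:
                raise ValueError(f"empty stage interval {s}..{e}")
        for (_, _, e_prev), (_, s_next, _) in zip(self.intervals, self.intervals[1:]):
            if s_next != e_prev + pd.Timedelta(days=1):
                raise ValueError("stage intervals must be contiguous and non-overlapping")

    @classmethod
    def from_breaks(cls, window_start, window_end, t2_start, t3_start) -> "StagePartition":
        """Build a partition from the window and the two stage-onset dates."""
        t2_start, t3_start = pd.Timestamp(t2_start), pd.Timestamp(t3_start)
        window_start, window_end = pd.Timestamp(window_start), pd.Timestamp(window_end)
        if not (window_start < t2_start < t3_start <= window_end):
            raise ValueError(
                f"breaks {t2_start.date()}, {t3_start.date()} must fall strictly "
                f"inside {window_start.date()}..{window_end.date()} in order"
            )
        day = pd.Timedelta(days=1)
        return cls((
            ("T1", window_start, t2_start - day),
            ("T2", t2_start, t3_start - day),
            ("T3", t3_start, window_end),
        ))

    @property
    def start(self):
        return self.intervals[0][1]

    @property
    def end(self):
        return self.intervals[-1][2]

    def label_of(self, when) -> str:
        when = pd.Timestamp(when).normalize()
        for lab, s, e in self.intervals:
            if s <= when <= e:
                return lab
        raise KeyError(f"{when.date()} outside the study window")

    def assign(self, timestamps: pd.Series) -> pd.Series:
        """Vectorised stage label per timestamp."""
        days = pd.to_datetime(timestamps).dt.normalize()
        out = pd.Series(pd.NA, index=days.index, dtype="object")
        for lab, s, e in self.intervals:
            out[(days >= s) & (days <= e)] = lab
        if out.isna().any():
            bad = days[out.isna()].dt.date.unique()
            raise KeyError(f"timestamp(s) outside the study window: {list(bad)[:5]}")
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(lab, s.date(), e.date()) for lab, s, e in self.intervals],
            columns=["label", "start", "end"],
        )


def daily_aggregate(
    scored: pd.DataFrame,
    window: tuple | None = None,
) -> pd.DataFrame:
    """Aggregate scored posts into a contiguous daily series.

    Returns a frame indexed by date with columns ``mean_score``, ``n_pos``,
    ``n_neg``, ``n_neu``, ``n_total``.  Days without posts are carried with
    ``n_total`` 0 and ``mean_score`` NaN (the undefined-mean flag).
    """
    ts = pd.to_datetime(scored["timestamp"]) if len(scored) else pd.Series(dtype="datetime64[ns]")
    days = ts.dt.normalize()
    if window is None:
        if len(scored) == 0:
            raise ValueError("empty post table needs an explicit window")
        window = (days.min(), days.max())
    start, end = pd.Timestamp(window[0]).normalize(), pd.Timestamp(window[1]).normalize()
    if len(scored) and ((days < start) | (days > end)).any():
        raise ValueError("posts fall outside the stated window")
    idx = pd.date_range(start, end, freq="D")
    out = pd.DataFrame(index=idx)
    if len(scored):
        grp = scored.groupby(days)
        out["mean_score"] = grp["score"].mean()
        ct = pd.crosstab(days, scored["valence"]).reindex(idx, fill_value=0)
        for col, lab in (("n_pos", "positive"), ("n_neg", "negative"), ("n_neu", "neutral")):
            out[col] = ct[lab] if lab in ct.columns else 0
        out["n_total"] = grp.size().reindex(idx, fill_value=0)
    else:
        out["mean_score"] = np.nan
        out[["n_pos", "n_neg", "n_neu", "n_total"]] = 0
    out[["n_pos", "n_neg", "n_neu", "n_total"]] = (
        out[["n_pos", "n_neg", "n_neu", "n_total"]].fillna(0).astype(int)
    )
    out.index.name = "date"
    return out


def _smoothed_means(series: pd.DataFrame, smooth_days: int) -> np.ndarray:
    means = series["mean_score"].to_numpy(dtype=float)
    filled = pd.Series(means).interpolate(limit_direction="both").to_numpy()
    if np.isnan(filled).any():
        raise StageSegmentationError("no day in the window has any posts")
    if smooth_days <= 1:
        return filled
    return (
        pd.Series(filled)
        .rolling(window=smooth_days, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def segment_stages(
    series: pd.DataFrame,
    smooth_days: int = 3,
    persist_days: int = 3,
    trailing_days: int = 7,
    manual_breaks: tuple | None = None,
) -> StagePartition:
    """Segment the daily series into T1/T2/T3 (see module docstring).

    ``manual_breaks`` — a ``(t2_start, t3_start)`` date pair — bypasses the
    automatic rule entirely.  Raises :class:`StageSegmentationError`, with a
    pointer to ``manual_breaks``, whenever the rule cannot place both
    boundaries.
    """
    idx = series.index
    if manual_breaks is not None:
        return StagePartition.from_breaks(idx[0], idx[-1], *manual_breaks)
    if len(series) < 3:
        raise StageSegmentationError(
            "need at least 3 days of data; supply manual_breaks for shorter windows"
        )
    smoothed = _smoothed_means(series, smooth_days)
    n_total = series["n_total"].to_numpy()
    n = len(smoothed)

    nonneg = smoothed >= 0
    t2_i = None
    for s in range(n):
        if n_total[s] == 0:
            continue  # zero-post days never start a persistence run
        run = nonneg[s : s + persist_days]
        if len(run) == persist_days and run.all():
            t2_i = s
            break
    if t2_i is None:
        raise StageSegmentationError(
            "no sustained sign change found (no T1/T2 boundary); "
            "supply manual_breaks=(t2_start, t3_start)"
        )
    if t2_i == 0:
        raise StageSegmentationError(
            "series is non-negative from the start — no T1 boundary found; "
            "supply manual_breaks=(t2_start, t3_start)"
        )

    observed = series["mean_score"].to_numpy(dtype=float)
    global_mean = np.nanmean(observed)
    t3_i = None
    for t in range(t2_i + 1, n):
        if not nonneg[t:].all():
            continue
        lo = max(0, t - trailing_days)
        trailing = observed[lo:t]
        trailing = trailing[~np.isnan(trailing)]
        if trailing.size and trailing.mean() > global_mean:
            t3_i = t
            break
    if t3_i is None:
        raise StageSegmentationError(
            "no sustained elevated tail found (no T2/T3 boundary); "
            "supply manual_breaks=(t2_start, t3_start)"
        )
    return StagePartition.from_breaks(idx[0], idx[-1], idx[t2_i], idx[t3_i])


def valence_shares(series: pd.DataFrame, partition: StagePartition) -> pd.DataFrame:
    """Per-stage proportions of positive/negative/neutral posts.

    Shares sum to 1 per stage; a stage without posts is flagged with NaN
    shares rather than dropped.
    """
    rows = []
    for lab, s, e in partition.intervals:
        sub = series.loc[s:e]
        total = int(sub["n_total"].sum())
        if total == 0:
            rows.append((lab, np.nan, np.nan, np.nan, 0))
        else:
            rows.append((
                lab,
                sub["n_pos"].sum() / total,
                sub["n_neg"].sum() / total,
                sub["n_neu"].sum() / total,
                total,
            ))
    return pd.DataFrame(rows, columns=["stage", "share_pos", "share_neg", "share_neu", "n_total"]).set_index("stage")
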