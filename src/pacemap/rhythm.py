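"""Heart-rate, sinus-pause, and beat-variability statistics, with the
Wilcoxon rank-sum test (exact enumeration or continuity-corrected normal
approximation) for two-group comparisons of per-embryo rates."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .activation import BeatWindow


@dataclass
class BeatSeries:
    """Ordered beat times (ms) from videography or voltage mapping."""

    beat_times: np.ndarray
    source: str = "voltage_map"

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.beat_times)

    @classmethod
    def from_windows(cls, windows: list[BeatWindow],
                     source: str = "voltage_map") -> "BeatSeries":
        return cls(beat_times=np.array([w.upstroke_ms for w in windows]),
                   source=source)


@dataclass
class GroupComparison:
    groups: dict            # label -> {"n", "mean_bpm", "sem_bpm"}
    statistic: float        # rank-sum W of the first group
    p_value: float
    method: str             # "exact" or "normal_continuity"
    significant: bool = False
    alpha: float = 0.01


def heart_rate_bpm(series: BeatSeries) -> float:
    """60000 / mean inter-beat interval (ms); NaN below 2 beats."""
    if series.beat_times.size < 2:
        return np.nan
    return 60000.0 / float(np.mean(series.intervals))


def detect_pauses(series: BeatSeries, k: float = 2.0
                  ) -> list[tuple[float, float]]:
    """Intervals longer than ``k`` × the median interval, reported as
    (start ms, duration ms).  The median is robust to the pauses it is
    meant to flag."""
    intervals = series.intervals
    if intervals.size < 4:
        raise ValueError("need at least 4 intervals to call pauses")
    med = float(np.median(intervals))
    out = []
    for i, iv in enumerate(intervals):
        if iv > k * med:
            out.append((float(series.beat_times[i]), float(iv)))
    return out


def interval_variability(series: BeatSeries) -> tuple[float, float]:
    """(sample SD of intervals in ms, coefficient of variation)."""
    intervals = series.intervals
    if intervals.size < 3:
        return (np.nan, np.nan)
    sd = float(np.std(intervals, ddof=1))
    return sd, sd / float(np.mean(intervals))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _exact_null_cdf(nx: int, ny: int) -> tuple[tuple[int, ...], tuple[float, ...]]:
    """Null distribution of the rank-sum W of a size-``nx`` group among
    ``nx + ny`` tie-free observations, by full enumeration."""
    n = nx + ny
    counts: dict[int, int] = {}
    for combo in itertools.combinations(range(1, n + 1), nx):
        w = sum(combo)
        counts[w] = counts.get(w, 0) + 1
    total = math.comb(n, nx)
    ws = sorted(counts)
    probs = [counts[w] / total for w in ws]
    return tuple(ws), tuple(probs)


def _exact_p(w: float, nx: int, ny: int) -> float:
    ws, probs = _exact_null_cdf(nx, ny)
    lo = sum(p for wv, p in zip(ws, probs) if wv <= w + 1e-9)
    hi = sum(p for wv, p in zip(ws, probs) if wv >= w - 1e-9)
    return min(1.0, 2.0 * min(lo, hi))


def _exact_p_with_ties(ranks_x, all_ranks) -> float:
    """Permutation p over all assignments of the observed midranks."""
    nx = len(ranks_x)
    w_obs = float(np.sum(ranks_x))
    lo = hi = total = 0
    for combo in itertools.combinations(range(len(all_ranks)), nx):
        w = float(np.sum(all_ranks[list(combo)]))
        total += 1
        if w <= w_obs + 1e-9:
            lo += 1
        if w >= w_obs - 1e-9:
            hi += 1
    return min(1.0, 2.0 * min(lo / total, hi / total))


def rank_sum_test(x, y, continuity: bool = True, mode: str = "auto"
                  ) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank sum of ``x`` (midranks for ties).
    ``mode="exact"`` enumerates all rank assignments; ``"normal"`` uses
    the tie-corrected normal approximation with optional continuity
    correction; ``"auto"`` picks exact for small tie-free samples
    (n ≤ 12) and the normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 1 or ny < 1:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    w = float(ranks[:nx].sum())
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if mode == "auto":
        mode = "exact" if (nx + ny <= 12 and not has_ties) else "normal"
    if mode == "exact":
        if has_ties:
            return w, _exact_p_with_ties(ranks[:nx], ranks)
        return w, _exact_p(w, nx, ny)
    if mode != "normal":
        raise ValueError(f"unknown mode {mode!r}")

    n = nx + ny
    mu = nx * (n + 1) / 2.0
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (n * (n - 1.0))
    sigma2 = nx * ny / 12.0 * ((n + 1.0) - tie_term)
    if sigma2 <= 0:
        return w, 1.0  # all observations identical
    z = (abs(w - mu) - (0.5 if continuity else 0.0)) / math.sqrt(sigma2)
    z = max(z, 0.0)
    return w, min(1.0, 2.0 * float(norm.sf(z)))


def compare_groups(rate_table: pd.DataFrame, alpha: float = 0.01,
                   mode: str = "auto") -> GroupComparison:
    """Two-group comparison of per-embryo rates (columns: group, bpm):
    per-group n / mean / SEM and the rank-sum p, flagged at the display
    threshold α = 0.01."""
    labels = list(pd.unique(rate_table["group"]))
    if len(labels) != 2:
        raise ValueError("exactly 2 groups required; compare pairs separately")
    samples = {}
    summary = {}
    for lab in labels:
        vals = rate_table.loc[rate_table["group"] == lab, "bpm"].to_numpy(float)
        if vals.size < 2:
            raise ValueError(f"group {lab!r} needs n >= 2")
        samples[lab] = vals
        summary[lab] = {"n": int(vals.size), "mean_bpm": float(vals.mean()),
                        "sem_bpm": float(vals.std(ddof=1) / np.sqrt(vals.size))}
    x, y = samples[labels[0]], samples[labels[1]]
    used_mode = mode
    if mode == "auto":
        pooled = np.concatenate([x, y])
        tie_free = np.unique(pooled).size == pooled.size
        used_mode = "exact" if (pooled.size <= 12 and tie_free) else "normal"
    w, p = rank_sum_test(x, y, mode=used_mode)
    return GroupComparison(groups=summary, statistic=w, p_value=p,
                           method=("exact" if used_mode == "exact"
                                   else "normal_continuity"),
                           significant=bool(p <= alpha), alpha=alpha)
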