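"""Beat detection, activation-time maps, isochrones, and origin calls.

Activation time is the moment of maximal upstroke rate (max dV/dt) of
the voltage-proxy trace, the standard fiducial in cardiac optical
mapping.  Per-beat maps report times relative to the earliest activated
in-mask pixel, so the map minimum is exactly 0 and isochrones are bands
of equal delay behind the wavefront origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .extract import Mask, RatioStack


@dataclass
class BeatWindow:
    beat_index: int
    start_frame: int
    end_frame: int          # exclusive
    upstroke_ms: float      # reference upstroke time of the mask-mean trace


@dataclass
class ActivationMap:
    beat_index: int
    times: np.ndarray       # (H, W) ms, NaN outside mask / undetected
    quality: np.ndarray     # (H, W) max dV/dt per pixel
    low_quality: bool = False


@dataclass
class OriginCall:
    """Early-activation sites of one beat, sorted by activation time; the
    earliest is the primary origin, any others are ectopic foci."""
    sites: list[tuple[int, int, float, int]]  # (row, col, time_ms, cluster size)
    classification: list[str] = field(default_factory=list)


def spatial_mean_trace(stack: np.ndarray | RatioStack, mask: Mask) -> np.ndarray:
    frames = stack.frames if isinstance(stack, RatioStack) else stack
    sub = frames[:, mask.values]
    if sub.shape[1] == 0:
        raise ValueError("empty mask")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(sub, axis=1)


def upstroke_rate(trace: np.ndarray, frame_rate: float,
                  smoothing: tuple[int, int] | None = None) -> np.ndarray:
    """Central-difference dV/dt in units/ms, optionally after local
    polynomial (Savitzky–Golay) smoothing with (window, order)."""
    trace = np.asarray(trace, dtype=float)
    if smoothing is not None:
        window, order = smoothing
        if window % 2 == 0:
            raise ValueError("smoothing window must be odd")
        if trace.size < window:
            raise ValueError("trace shorter than the smoothing window")
        trace = savgol_filter(trace, window, order)
    return np.gradient(trace) * frame_rate / 1000.0


def detect_beats(trace: np.ndarray, frame_rate: float,
                 min_interval_ms: float = 150.0,
                 prominence: float = 0.3) -> list[BeatWindow]:
    """Upstroke-peak detection on d(trace)/dt.

    ``prominence`` is a fraction of the derivative's dynamic range; peaks
    closer together than ``min_interval_ms`` are suppressed (refractory
    rule).  Windows span midway between consecutive upstrokes.
    """
    trace = np.asarray(trace, dtype=float)
    min_frames = max(int(round(min_interval_ms * frame_rate / 1000.0)), 1)
    if trace.size <= 2 * min_frames:
        raise ValueError("trace too short for the requested minimum interval")
    deriv = np.gradient(trace)
    span = np.nanmax(deriv) - np.nanmin(deriv)
    if not np.isfinite(span) or span == 0:
        return []
    peaks, _ = find_peaks(deriv, prominence=prominence * span,
                          distance=min_frames)
    if peaks.size == 0:
        return []
    bounds = ((peaks[:-1] + peaks[1:]) // 2).tolist()
    gap = int(np.median(np.diff(peaks))) if peaks.size > 1 else 2 * min_frames
    starts = [max(0, peaks[0] - gap // 2)] + bounds
    ends = bounds + [min(trace.size, peaks[-1] + gap // 2 + 1)]
    return [BeatWindow(beat_index=i, start_frame=s, end_frame=e,
                       upstroke_ms=p / frame_rate * 1000.0)
            for i, (s, e, p) in enumerate(zip(starts, ends, peaks))]


def _parabolic_offset(y_prev, y_peak, y_next):
    denom = y_prev - 2.0 * y_peak + y_next
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 0.5 * (y_prev - y_next) / denom
    return np.clip(np.where(np.isfinite(delta), delta, 0.0), -0.5, 0.5)


def activation_time(trace: np.ndarray, window: BeatWindow, frame_rate: float,
                    refine: bool = True) -> float:
    """Activation time (ms) of one pixel in one beat window: the frame of
    maximal upstroke rate, ties broken toward the earlier frame, with
    optional sub-frame parabolic interpolation."""
    deriv = upstroke_rate(trace, frame_rate)
    seg = deriv[window.start_frame:window.end_frame]
    if seg.size == 0 or np.all(~np.isfinite(seg)):
        return np.nan
    i = int(np.nanargmax(seg))
    frame = window.start_frame + i
    t = float(frame)
    if refine and 0 < i < seg.size - 1 and np.all(np.isfinite(seg[i - 1:i + 2])):
        t += float(_parabolic_offset(seg[i - 1], seg[i], seg[i + 1]))
    return t / frame_rate * 1000.0


def build_activation_map(stack: RatioStack | np.ndarray, mask: Mask,
                         windows: list[BeatWindow],
                         frame_rate: float | None = None,
                         refine: bool = True,
                         quality_floor: float | None = None,
                         low_quality_fraction: float = 0.1
                         ) -> list[ActivationMap]:
    """Per-beat activation maps over all in-mask pixels (vectorized).

    Pixels whose maximal dV/dt falls below a quality floor — by default
    3× the per-pixel derivative noise SD, estimated robustly from the
    whole trace (upstrokes occupy a small fraction of frames) — are set
    NaN.  Each map is shifted so its minimum is exactly 0.
    """
    if not windows:
        raise ValueError("at least one beat window required")
    if isinstance(stack, RatioStack):
        frames, fr = stack.frames, stack.frame_rate
    else:
        frames, fr = stack, frame_rate
        if fr is None:
            raise ValueError("frame_rate required for a bare array stack")
    deriv = np.gradient(frames, axis=0) * fr / 1000.0  # units/ms
    if quality_floor is None:
        med = np.nanmedian(deriv, axis=0)
        mad = np.nanmedian(np.abs(deriv - med), axis=0)
        floor2d = 3.0 * 1.4826 * mad
    else:
        floor2d = np.full(frames.shape[1:], float(quality_floor))

    maps = []
    for w in windows:
        seg = deriv[w.start_frame:w.end_frame]
        finite = np.isfinite(seg)
        any_finite = finite.any(axis=0)
        seg_f = np.where(finite, seg, -np.inf)
        idx = seg_f.argmax(axis=0)
        quality = np.take_along_axis(seg_f, idx[None], axis=0)[0]
        t_frame = idx.astype(float)
        if refine:
            interior = (idx > 0) & (idx < seg.shape[0] - 1)
            prev_ = np.take_along_axis(seg_f, np.clip(idx - 1, 0, None)[None], axis=0)[0]
            next_ = np.take_along_axis(
                seg_f, np.clip(idx + 1, None, seg.shape[0] - 1)[None], axis=0)[0]
            ok = interior & np.isfinite(prev_) & np.isfinite(next_)
            delta = _parabolic_offset(prev_, quality, next_)
            t_frame = np.where(ok, t_frame + delta, t_frame)
        times = (w.start_frame + t_frame) / fr * 1000.0
        valid = mask.values & any_finite & (quality >= floor2d)
        times = np.where(valid, times, np.nan)
        quality = np.where(mask.values & any_finite, quality, np.nan)
        n_valid = int(np.isfinite(times).sum())
        low_q = n_valid < low_quality_fraction * mask.values.sum()
        if n_valid:
            times = times - np.nanmin(times)
        maps.append(ActivationMap(beat_index=w.beat_index, times=times,
                                  quality=quality, low_quality=low_q))
    return maps


def isochrone_levels(amap: ActivationMap, step_ms: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Contour levels 0, step, 2·step, … up to the map maximum, plus a
    banded label image (band index per pixel, −1 outside the map)."""
    if step_ms <= 0:
        raise ValueError("step must be > 0")
    t = amap.times
    if not np.isfinite(t).any():
        raise ValueError("all-NaN activation map")
    tmax = float(np.nanmax(t))
    levels = np.arange(0.0, tmax + step_ms, step_ms)
    bands = np.full(t.shape, -1, dtype=int)
    finite = np.isfinite(t)
    bands[finite] = np.minimum((t[finite] // step_ms).astype(int), len(levels) - 1)
    return levels, bands


def _nan_smooth(t: np.ndarray, size: int = 3) -> np.ndarray:
    """NaN-aware local mean; NaN pixels stay NaN."""
    from scipy.ndimage import uniform_filter

    valid = np.isfinite(t)
    filled = np.where(valid, t, 0.0)
    num = uniform_filter(filled, size, mode="nearest")
    den = uniform_filter(valid.astype(float), size, mode="nearest")
    out = np.where(den > 0, num / np.maximum(den, 1e-12), np.nan)
    return np.where(valid, out, np.nan)


def find_origins(amap: ActivationMap, early_quantile: float = 0.05,
                 merge_radius: float = 3.0, presmooth: bool = True) -> OriginCall:
    """Cluster the earliest-activating pixels into candidate origin sites.

    Pixels within ``early_quantile`` of the activation-time distribution
    are grouped by connectivity; clusters whose earliest pixels lie within
    ``merge_radius`` are merged.  The temporally first site is the primary
    origin; the rest are ectopic foci.  ``presmooth`` applies a 3×3
    NaN-aware local mean first: near the origin, inter-pixel time
    differences are comparable to the per-pixel timing noise, and the
    raw minimum-time pixel wanders.
    """
    from skimage.measure import label as cc_label

    t = amap.times
    if presmooth:
        t = _nan_smooth(t)
        if np.isfinite(t).any():
            t = t - np.nanmin(t)
    finite = np.isfinite(t)
    if not finite.any():
        raise ValueError("empty activation map")
    thr = np.nanquantile(t, early_quantile)
    early = finite & (t <= thr)
    labels = cc_label(early, connectivity=2)
    reps = []  # (time, row, col, size)
    for lab in range(1, labels.max() + 1):
        rs, cs = np.nonzero(labels == lab)
        ts = t[rs, cs]
        k = int(np.argmin(ts))
        reps.append([float(ts[k]), int(rs[k]), int(cs[k]), len(rs)])
    # union–find merge of representatives within merge_radius
    parent = list(range(len(reps)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(len(reps)):
        for b in range(a + 1, len(reps)):
            if np.hypot(reps[a][1] - reps[b][1], reps[a][2] - reps[b][2]) <= merge_radius:
                parent[find(a)] = find(b)
    merged: dict[int, list] = {}
    for a, rep in enumerate(reps):
        root = find(a)
        if root not in merged:
            merged[root] = list(rep)
        else:
            m = merged[root]
            m[3] += rep[3]
            if rep[0] < m[0]:
                m[:3] = rep[:3]
    sites = sorted(([r, c, tm, sz] for tm, r, c, sz in
                    ((m[0], m[1], m[2], m[3]) for m in merged.values())),
                   key=lambda s: s[2])
    call = OriginCall(sites=[(r, c, tm, sz) for r, c, tm, sz in sites])
    call.classification = ["primary"] + ["ectopic"] * (len(call.sites) - 1)
    return call


def consensus_origin(maps: list[ActivationMap], early_quantile: float = 0.05,
                     merge_radius: float = 3.0
                     ) -> tuple[float, float, list[tuple[int, int]]]:
    """Run-level primary-origin estimate: the mean position of the
    per-beat primary sites.  Per-beat calls jitter by ~1–2 pixels when
    the timing noise matches the inter-pixel conduction delay; beats are
    independent, so averaging across them tightens the estimate."""
    calls = []
    for amap in maps:
        if not np.isfinite(amap.times).any() or amap.low_quality:
            continue
        site = find_origins(amap, early_quantile, merge_radius).sites[0]
        calls.append((site[0], site[1]))
    if not calls:
        raise ValueError("no usable activation maps")
    arr = np.asarray(calls, dtype=float)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean()), calls


def estimate_conduction_velocity(amap: ActivationMap, pixel_size_um: float
                                 ) -> float:
    """Wavefront speed (µm/ms) from a least-squares plane fit
    t(x, y) = a·x + b·y + c over valid pixels; speed = pixel_size/√(a²+b²).
    Returns NaN for (near-)simultaneous activation or degenerate fits."""
    t = amap.times
    rs, cs = np.nonzero(np.isfinite(t))
    if rs.size < 20:
        raise ValueError("need at least 20 valid pixels for a plane fit")
    A = np.column_stack([cs, rs, np.ones_like(rs)]).astype(float)
    coef, _, rank, _ = np.linalg.lstsq(A, t[rs, cs], rcond=None)
    if rank < 3:
        return np.nan
    grad = float(np.hypot(coef[0], coef[1]))  # ms per pixel
    if grad < 1e-9:
        return np.nan
    return pixel_size_um / grad
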