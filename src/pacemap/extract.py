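"""Ratiometric voltage extraction from two-channel FRET movies.

Processing chain (each step shape-preserving over (T, H, W)):

1. split the split-frame camera image into donor and acceptor stacks;
2. register the acceptor half onto the donor half (integer shift);
3. pixelwise ratio R = acceptor / donor, oriented so depolarization
   increases R;
4. adaptive local-statistics (Wiener) spatial filtering, 3×3 window,
   applied frame by frame;
5. region segmentation (supplied mask, or automatic from the temporal
   signal amplitude);
6. per-pixel normalization through time to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .simulate import TwoChannelMovie, LAYOUT_SPLIT, LAYOUT_SEPARATE


@dataclass
class RatioStack:
    """Dimensionless ratio frames plus a processing log."""

    frames: np.ndarray          # (T, H, W) float
    frame_rate: float
    provenance: list[dict] = field(default_factory=list)

    def log(self, step: str, **params) -> "RatioStack":
        self.provenance.append({"step": step, **params})
        return self


@dataclass
class Mask:
    values: np.ndarray          # (H, W) bool
    label: str = "atrium"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if not self.values.any():
            raise ValueError("mask must contain at least one pixel")


def split_channels(movie: TwoChannelMovie) -> tuple[np.ndarray, np.ndarray]:
    """Un-pack the camera frames into (donor, acceptor) stacks of
    identical shape; no resampling."""
    if movie.layout == LAYOUT_SEPARATE:
        donor, acceptor = movie.frames[0], movie.frames[1]
        if donor.shape != acceptor.shape:
            raise ValueError("channel stacks differ in shape")
        return np.asarray(donor, float), np.asarray(acceptor, float)
    if movie.layout == LAYOUT_SPLIT:
        width = movie.frames.shape[2]
        if width % 2:
            raise ValueError("split layout requires an even frame width")
        half = width // 2
        return (np.asarray(movie.frames[:, :, :half], float),
                np.asarray(movie.frames[:, :, half:], float))
    raise ValueError(f"unknown layout {movie.layout!r}")


def register_channels(donor: np.ndarray, acceptor: np.ndarray,
                      max_shift: int = 3, shift_penalty: float = 1e-3,
                      min_correlation: float = 0.3
                      ) -> tuple[np.ndarray, tuple[int, int]]:
    """Align the acceptor stack to the donor by the integer (row, col)
    translation maximizing the magnitude of the Pearson correlation of
    the time-mean images within ±``max_shift``.  Returns (aligned
    acceptor, shift).  The magnitude matters because FRET channel pairs
    are anti-correlated by construction (donor dims where acceptor
    brightens), so a co-registered pair scores near −1.

    A small quadratic penalty (``shift_penalty`` per pixel²) regularizes
    the search toward zero shift: on low-contrast mean images the
    correlation landscape is flat and would otherwise be decided by
    noise.  If the best correlation magnitude stays below
    ``min_correlation`` the images carry too little structure to
    register and the shift is left at zero with a warning.  The shift is
    applied circularly; splitter misalignments are a few pixels, so
    wrap-around touches border pixels only.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    mean_d = donor.mean(axis=0)
    mean_a = acceptor.mean(axis=0)
    if mean_d.std() == 0 or mean_a.std() == 0:
        warnings.warn("constant reference image; registration skipped")
        return acceptor, (0, 0)
    best, best_shift = -np.inf, (0, 0)
    d0 = mean_d - mean_d.mean()
    for dr in range(-max_shift, max_shift + 1):
        for dc in range(-max_shift, max_shift + 1):
            shifted = np.roll(mean_a, (dr, dc), axis=(0, 1))
            s0 = shifted - shifted.mean()
            denom = np.sqrt((d0 ** 2).sum() * (s0 ** 2).sum())
            score = abs((d0 * s0).sum()) / denom if denom > 0 else -np.inf
            score -= shift_penalty * (dr * dr + dc * dc)
            if score > best:
                best, best_shift = score, (dr, dc)
    if best < min_correlation:
        warnings.warn("correlation landscape too weak to register "
                      f"(|r| = {max(best, 0):.2f} < {min_correlation}); "
                      "leaving channels unshifted")
        return acceptor, (0, 0)
    if max_shift > 0 and (abs(best_shift[0]) == max_shift or
                          abs(best_shift[1]) == max_shift):
        warnings.warn(f"best shift {best_shift} lies on the ±{max_shift} "
                      "search boundary; true offset may be larger")
    aligned = np.roll(acceptor, best_shift, axis=(1, 2))
    return aligned, best_shift


def compute_ratio(acceptor: np.ndarray, donor: np.ndarray, frame_rate: float,
                  floor: float = 1.0, mask: np.ndarray | None = None) -> RatioStack:
    """R = acceptor / max(donor, floor), per pixel per frame.

    Depolarization brightens the acceptor and dims the donor, so R rises
    on the action-potential upstroke.
    """
    if acceptor.shape != donor.shape:
        raise ValueError("channel shapes differ")
    if floor <= 0:
        raise ValueError("floor must be > 0")
    floored = donor < floor
    check = floored if mask is None else floored[:, mask]
    if check.mean() > 0.05:
        warnings.warn("more than 5% of donor pixels at the floor value")
    ratio = acceptor / np.maximum(donor, floor)
    rs = RatioStack(frames=ratio, frame_rate=frame_rate)
    return rs.log("compute_ratio", floor=floor,
                  floored_fraction=float(check.mean()))


def wiener_filter_frame(frame: np.ndarray, window: tuple[int, int] = (3, 3),
                        noise_variance: float | None = None) -> np.ndarray:
    """Pixelwise adaptive linear noise-removal (Wiener) filter.

    Over each ``window`` the local mean μ and variance σ² are estimated
    (borders replicate the edge pixel, so constant frames stay constant);
    with noise power ν² (the image mean of σ² when not supplied) the
    output is ``μ + max(σ² − ν², 0)/σ² · (x − μ)``, and exactly μ where
    σ² = 0 — so constant frames pass unchanged everywhere.
    """
    wr, wc = window
    if wr % 2 == 0 or wc % 2 == 0:
        raise ValueError("window must be odd in both dimensions")
    x = np.asarray(frame, dtype=float)
    mu = uniform_filter(x, size=window, mode="nearest")
    m2 = uniform_filter(x * x, size=window, mode="nearest")
    var = np.clip(m2 - mu * mu, 0.0, None)
    nu = float(var.mean()) if noise_variance is None else float(noise_variance)
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(var > 0, np.clip(var - nu, 0.0, None) / var, 0.0)
    return mu + gain * (x - mu)


def wiener_filter_stack(stack: RatioStack, window: tuple[int, int] = (3, 3),
                        noise_variance: float | None = None) -> RatioStack:
    """Apply :func:`wiener_filter_frame` to every frame of a ratio stack."""
    out = np.empty_like(stack.frames, dtype=float)
    for t in range(stack.frames.shape[0]):
        out[t] = wiener_filter_frame(stack.frames[t], window, noise_variance)
    rs = RatioStack(frames=out, frame_rate=stack.frame_rate,
                    provenance=list(stack.provenance))
    return rs.log("wiener_filter", window=list(window),
                  noise_variance=noise_variance)


def segment_region(stack: np.ndarray, method: str = "threshold_auto",
                   mask: np.ndarray | None = None,
                   label: str = "atrium") -> Mask:
    """Region mask, either supplied (``method="mask_file"``) or automatic:
    Otsu threshold on the per-pixel temporal amplitude (max − min), keeping
    the largest connected component."""
    if method == "mask_file":
        if mask is None:
            raise ValueError("mask_file method requires a mask array")
        return Mask(values=mask, label=label)
    if method != "threshold_auto":
        raise ValueError(f"unknown method {method!r}")
    amplitude = stack.max(axis=0) - stack.min(axis=0)
    if amplitude.max() == amplitude.min():
        raise ValueError("flat movie: no signal to segment")
    thr = threshold_otsu(amplitude)
    binary = amplitude > thr
    if not binary.any():
        raise ValueError("automatic segmentation produced an empty mask")
    labels = cc_label(binary, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return Mask(values=labels == largest, label=label)


def normalize_pixelwise(stack: RatioStack, mask: Mask,
                        lo_percentile: float = 0.0,
                        hi_percentile: float = 100.0) -> RatioStack:
    """Per-pixel min–max (or percentile) normalization through time.

    In-mask pixels are scaled to [0, 1] (clipped); out-of-mask and flat
    pixels become NaN, since background and vessel pixels carry no
    voltage signal.
    """
    if hi_percentile <= lo_percentile:
        raise ValueError("hi_percentile must exceed lo_percentile")
    frames = stack.frames
    out = np.full_like(frames, np.nan, dtype=float)
    m = mask.values
    sub = frames[:, m]  # (T, n_pixels)
    q_lo = np.percentile(sub, lo_percentile, axis=0)
    q_hi = np.percentile(sub, hi_percentile, axis=0)
    span = q_hi - q_lo
    flat = span <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.clip((sub - q_lo) / span, 0.0, 1.0)
    norm[:, flat] = np.nan
    if flat.any():
        warnings.warn(f"{int(flat.sum())} flat in-mask pixels set to NaN")
    out[:, m] = norm
    rs = RatioStack(frames=out, frame_rate=stack.frame_rate,
                    provenance=list(stack.provenance))
    return rs.log("normalize_pixelwise", lo=lo_percentile, hi=hi_percentile,
                  flat_pixels=int(flat.sum()))


def extract_voltage(movie: TwoChannelMovie, mask: np.ndarray | None = None,
                    max_shift: int = 3, wiener_window: tuple[int, int] = (3, 3),
                    donor_floor: float = 1.0,
                    lo_percentile: float = 0.0,
                    hi_percentile: float = 100.0) -> tuple[RatioStack, Mask]:
    """Full chain: split → register → ratio → Wiener → segment → normalize.

    Returns the normalized voltage-proxy stack (NaN outside the mask) and
    the mask used.
    """
    donor, acceptor = split_channels(movie)
    acceptor, shift = register_channels(donor, acceptor, max_shift=max_shift)
    ratio = compute_ratio(acceptor, donor, movie.frame_rate, floor=donor_floor)
    ratio.log("register_channels", shift=list(shift))
    ratio = wiener_filter_stack(ratio, window=wiener_window)
    if mask is None:
        region = segment_region(ratio.frames, method="threshold_auto")
    else:
        region = segment_region(ratio.frames, method="mask_file", mask=mask)
    return normalize_pixelwise(ratio, region, lo_percentile, hi_percentile), region
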