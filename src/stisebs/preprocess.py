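"""NDVI computation and time-series cleaning.

The cleaning chain mirrors standard practice for satellite vegetation
index series: values outside the physically meaningful [-1, 1] range are
removed (not clamped), the resulting gaps are filled with a centered
exponentially weighted moving average, and the filled series is smoothed
with a Savitzky-Golay filter, optionally iterated toward the upper
envelope in the style of Chen et al.'s cloud-contamination correction.

All operators act per pixel along the time axis and are independent of
pixel order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_coeffs

from .grid import TimeSeriesGrid

__all__ = [
    "PreprocessConfig",
    "compute_ndvi",
    "clip_valid_range",
    "fill_gaps",
    "smooth_savitzky_golay",
    "preprocess_stack",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Cleaning-chain parameters.

    fill_window : half-width, in periods, of the centered gap-fill window.
    fill_decay : geometric decay per step of distance; weight at lag d is
        ``decay ** (|d| - 1)``, so immediate neighbours weigh 1.
    sg_window : odd Savitzky-Golay window length in periods.
    sg_order : local polynomial degree (< sg_window).
    chen_iterations : number of upper-envelope refits (0 disables).
    """

    fill_window: int = 3
    fill_decay: float = 0.5
    sg_window: int = 7
    sg_order: int = 2
    chen_iterations: int = 0


def compute_ndvi(nir: TimeSeriesGrid, red: TimeSeriesGrid) -> TimeSeriesGrid:
    """Normalized-difference vegetation index (NIR - Red)/(NIR + Red).

    Cells where NIR + Red = 0 become missing (NaN) for later gap fill.
    """
    if nir.geometry.shape != red.geometry.shape:
        raise ValueError("NIR and Red grids have different shapes")
    if nir.times != red.times:
        raise ValueError("NIR and Red grids have different time axes")
    if not np.array_equal(nir.valid_mask, red.valid_mask):
        raise ValueError("NIR and Red grids have different masks")
    denom = nir.values + red.values
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(denom != 0.0, (nir.values - red.values) / denom, np.nan)
    return nir.with_values(ndvi)


def clip_valid_range(grid: TimeSeriesGrid, lo: float = -1.0, hi: float = 1.0) -> TimeSeriesGrid:
    """Turn values outside the closed [lo, hi] interval into gaps."""
    vals = grid.values.copy()
    with np.errstate(invalid="ignore"):
        bad = (vals < lo) | (vals > hi)
    vals[bad] = np.nan
    return grid.with_values(vals)


def fill_gaps(grid: TimeSeriesGrid, window: int = 3, decay: float = 0.5) -> TimeSeriesGrid:
    """Fill missing values with a centered exponential moving average.

    A gap at period t is replaced by the weighted mean of the available
    observations at lags d in [-window, window], d != 0, with weight
    ``decay ** (|d| - 1)`` normalized over the neighbours actually
    present.  Pixels with gaps that no window can fill are masked out of
    the returned grid (downstream stages need complete vectors).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    vals = grid.masked_values()
    finite = np.isfinite(vals)
    num = np.zeros_like(vals)
    den = np.zeros_like(vals)
    obs = np.where(finite, vals, 0.0)
    t_axis = 2
    for d in range(1, window + 1):
        w = decay ** (d - 1)
        for shift in (d, -d):
            shifted = np.roll(obs, shift, axis=t_axis)
            smask = np.roll(finite, shift, axis=t_axis)
            # roll wraps around the series ends; cut the wrapped slice
            if shift > 0:
                shifted[..., :shift] = 0.0
                smask[..., :shift] = False
            else:
                shifted[..., shift:] = 0.0
                smask[..., shift:] = False
            num += w * shifted * smask
            den += w * smask
    with np.errstate(invalid="ignore", divide="ignore"):
        filled = np.where(den > 0, num / den, np.nan)
    out = np.where(finite, vals, filled)
    still_missing = ~np.all(np.isfinite(out), axis=t_axis)
    new_mask = grid.valid_mask & ~still_missing
    out[~new_mask] = np.nan
    return grid.with_values(out, valid_mask=new_mask)


def _shrunk_window_matrix(t: int, window: int, order: int) -> np.ndarray:
    """Dense (T, T) Savitzky-Golay smoother with shrinking end windows.

    Interior rows are the classic symmetric SG convolution; near the
    series ends the window is truncated to what exists and the local
    polynomial is refit on it (degree reduced if the truncated window is
    too short), instead of padding with invented data.
    """
    half = window // 2
    s = np.zeros((t, t))
    cache: dict[tuple[int, int], np.ndarray] = {}
    for i in range(t):
        lo = max(0, i - half)
        hi = min(t - 1, i + half)
        key = (lo - i, hi - i)
        row = cache.get(key)
        if row is None:
            m = hi - lo + 1
            deg = min(order, m - 1)
            if m == window:
                row = savgol_coeffs(window, deg, pos=i - lo, use="dot")
            else:
                # hat-matrix row of the LSQ polynomial fit on the window
                x = np.arange(lo, hi + 1) - i
                a = np.vander(x, deg + 1, increasing=True)
                h = a @ np.linalg.pinv(a)
                row = h[i - lo]
            cache[key] = row
        s[i, lo : hi + 1] = row
    return s


def smooth_savitzky_golay(
    grid: TimeSeriesGrid,
    window: int = 7,
    order: int = 2,
    chen_iterations: int = 0,
    clip: bool = True,
) -> TimeSeriesGrid:
    """Per-pixel Savitzky-Golay smoothing of complete series.

    With ``chen_iterations > 0`` the filter is iterated toward the upper
    envelope: points below the fitted curve are replaced by the fit and
    the series re-smoothed, which treats negatively biased dropouts
    (clouds) as noise while trusting high observations.  Output is
    clipped back to [-1, 1] unless ``clip`` is False.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    if order >= window:
        raise ValueError("polynomial order must be < window")
    t = grid.n_periods
    if window > t:
        raise ValueError(f"window {window} exceeds series length {t}")
    vals = grid.masked_values()
    if not np.all(np.isfinite(vals[grid.valid_mask])):
        raise ValueError("series must be gap-free before smoothing")
    s = _shrunk_window_matrix(t, window, order)
    smoothed = vals @ s.T
    for _ in range(int(chen_iterations)):
        envelope = np.maximum(vals, smoothed)
        smoothed = envelope @ s.T
    if clip:
        smoothed = np.clip(smoothed, -1.0, 1.0)
    smoothed[~grid.valid_mask] = np.nan
    return grid.with_values(smoothed)


def preprocess_stack(grid: TimeSeriesGrid, config: PreprocessConfig | None = None) -> TimeSeriesGrid:
    """Full cleaning chain: range filter, gap fill, SG smoothing."""
    cfg = config or PreprocessConfig()
    out = clip_valid_range(grid)
    out = fill_gaps(out, window=cfg.fill_window, decay=cfg.fill_decay)
    out = smooth_savitzky_golay(
        out,
        window=cfg.sg_window,
        order=cfg.sg_order,
        chen_iterations=cfg.chen_iterations,
    )
    return out
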