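"""Small shared smoothing / adaptive-level helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["moving_average", "gaussian_smooth", "rolling_percentile",
           "adaptive_threshold"]


def moving_average(x: np.ndarray, fs: float, width_s: float) -> np.ndarray:
    """Centred boxcar moving average of width ``width_s`` seconds.

    The window length is forced odd so the kernel is symmetric and
    extrema of symmetric pulses stay in place.
    """
    x = np.asarray(x, dtype=float)
    w = max(1, int(round(width_s * fs)))
    if w % 2 == 0:
        w += 1
    if w <= 1:
        return x.copy()
    kernel = np.ones(w) / w
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")


def gaussian_smooth(x: np.ndarray, fs: float, sigma_s: float) -> np.ndarray:
    """Gaussian smoothing (kernel SD ``sigma_s`` s, truncated at 4 SD).

    Unlike a boxcar, a Gaussian kernel leaves no flat plateaus around
    narrow pulses, so a broad wave next to a sharp peak keeps a distinct
    maximum at its own centre.
    """
    x = np.asarray(x, dtype=float)
    s = sigma_s * fs
    if s <= 0:
        return x.copy()
    half = max(1, int(round(4 * s)))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / s) ** 2)
    k /= k.sum()
    xp = np.pad(x, half, mode="edge")
    return np.convolve(xp, k, mode="valid")


def rolling_percentile(x: np.ndarray, fs: float, window_s: float,
                       q: float, target_rate: float = 50.0) -> np.ndarray:
    """Centred rolling percentile, computed on a decimated copy.

    Adaptive thresholds only need to track slow level changes, so the
    percentile is evaluated at ~``target_rate`` Hz and linearly
    interpolated back to the full grid.
    """
    x = np.asarray(x, dtype=float)
    step = max(1, int(round(fs / target_rate)))
    xd = x[::step]
    win = max(3, int(round(window_s * fs / step)))
    level = (pd.Series(xd)
             .rolling(win, center=True, min_periods=1)
             .quantile(q)
             .to_numpy())
    idx_d = np.arange(len(xd)) * step
    return np.interp(np.arange(len(x)), idx_d, level)


def adaptive_threshold(env: np.ndarray, fs: float, window_s: float,
                       frac: float, q: float = 0.95,
                       global_floor: float = 0.7) -> np.ndarray:
    """Envelope threshold: rolling median + frac * (rolling q-tile - median).

    The median tracks the noise floor between bursts and the upper
    quantile the burst level, so the threshold sits a fixed fraction of
    the way between them regardless of absolute scale.  The local
    threshold is floored at ``global_floor`` times the whole-record
    threshold, so it does not decay to the noise floor during
    burst-free stretches (e.g. a trailing gap).
    """
    med = rolling_percentile(env, fs, window_s, 0.5)
    hi = rolling_percentile(env, fs, window_s, q)
    thr = med + frac * np.maximum(hi - med, 0.0)
    g_med = float(np.median(env))
    g_hi = float(np.quantile(env, q))
    g_thr = g_med + frac * max(g_hi - g_med, 0.0)
    return np.maximum(thr, global_floor * g_thr)
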