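"""ECG fiducial detection: R peaks, Q waves, T peaks.

The ECG Q and R waves are the timing reference for every GCG interval.
R detection is a lightweight squared-derivative envelope method in the
Pan-Tompkins tradition: differentiate, square, smooth, threshold at an
adaptive fraction of the local envelope level, then refine each
candidate to the ECG maximum.  Q is the local minimum in a short window
before R; T the maximum in a mid-diastolic window.  Ties in any
extremum search resolve to the earliest sample (the package-wide rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal

from ._smoothing import adaptive_threshold, gaussian_smooth, moving_average
from .io import EcgFiducials

__all__ = [
    "RPeakConfig",
    "detect_r_peaks",
    "locate_q_wave",
    "locate_t_peak",
    "detect_ecg_fiducials",
]


@dataclass(frozen=True)
class RPeakConfig:
    qrs_band_hz: tuple[float, float] = (5.0, 20.0)  # QRS-selective band-pass
    smooth_s: float = 0.12         # envelope moving-average width
    threshold_frac: float = 0.4    # fraction of the rolling level
    level_window_s: float = 2.0    # rolling 95th-percentile window
    level_q: float = 0.95
    refractory_s: float = 0.25
    refine_s: float = 0.05         # half-width of the R refinement window


def detect_r_peaks(ecg: np.ndarray, fs: float,
                   cfg: RPeakConfig | None = None) -> np.ndarray:
    """Detect R peaks; strictly increasing sample indices.

    Raises ``ValueError`` for signals shorter than 2 s.  An all-zero (or
    pulse-free) signal yields an empty array.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 2 * fs:
        raise ValueError("need at least 2 s of ECG")
    cfg = cfg or RPeakConfig()
    sos = signal.butter(2, cfg.qrs_band_hz, btype="bandpass",
                        output="sos", fs=fs)
    qrs = signal.sosfiltfilt(sos, ecg)
    env = moving_average(np.gradient(qrs) ** 2, fs, cfg.smooth_s)
    thr = adaptive_threshold(env, fs, cfg.level_window_s,
                             cfg.threshold_frac, cfg.level_q)
    dist = max(1, int(round(cfg.refractory_s * fs)))
    cand, _ = signal.find_peaks(env, distance=dist)
    cand = cand[env[cand] > thr[cand]]
    # envelope and threshold are unreliable hard against the record ends
    cand = cand[(cand >= dist) & (cand < len(ecg) - dist)]
    # Refine to the ECG maximum near each envelope peak.
    half = int(round(cfg.refine_s * fs))
    peaks = []
    for c in cand:
        a, b = max(0, c - half), min(len(ecg), c + half + 1)
        peaks.append(a + int(np.argmax(ecg[a:b])))
    peaks = np.unique(peaks)
    if peaks.size:  # enforce refractory after refinement
        keep = [int(peaks[0])]
        for pk in peaks[1:]:
            if pk - keep[-1] >= dist:
                keep.append(int(pk))
            elif ecg[pk] > ecg[keep[-1]]:
                keep[-1] = int(pk)
        peaks = np.asarray(keep)
    return np.asarray(peaks, dtype=int)


def locate_q_wave(ecg: np.ndarray, r_idx: int, fs: float,
                  window_s: float = 0.05,
                  fallback_s: float = 0.033,
                  smooth_s: float = 0.005) -> Optional[int]:
    """Q wave: minimum of the ECG in [r_idx - 50 ms, r_idx).

    The search runs on a lightly smoothed copy (Gaussian sigma
    ``smooth_s``) so a lone noise spike cannot masquerade as the Q dip.
    Returns the window minimum when it is strictly interior (a true
    local minimum); a monotone window falls back to ``r_idx - 33 ms``.
    Returns ``None`` when the window would start before the record.
    """
    ecg = np.asarray(ecg, dtype=float)
    w = int(round(window_s * fs))
    a = r_idx - w
    if a < 0 or r_idx > len(ecg):
        return None
    if smooth_s > 0:
        lo = max(0, a - int(4 * smooth_s * fs))
        hi = min(len(ecg), r_idx + int(4 * smooth_s * fs))
        win = gaussian_smooth(ecg[lo:hi], fs, smooth_s)[a - lo:a - lo + w]
    else:
        win = ecg[a:r_idx]
    if len(win) < 3:
        return None
    i = int(np.argmin(win))
    if 0 < i < len(win) - 1:
        return a + i
    return r_idx - int(round(fallback_s * fs))


def locate_t_peak(ecg: np.ndarray, r_idx: int, fs: float,
                  window_s: tuple[float, float] = (0.15, 0.45),
                  smooth_s: float = 0.02) -> Optional[int]:
    """T peak: maximum of the ECG in [r_idx + 150 ms, r_idx + 450 ms].

    The T wave is broad, so the search runs on a lightly smoothed copy
    (Gaussian sigma ``smooth_s``), which stops single noise spikes from
    hijacking the maximum.  Returns ``None`` when the window is
    truncated by the record end.  Used only to centre the g_K/g_L
    search on the GCG x-axis.
    """
    ecg = np.asarray(ecg, dtype=float)
    a = r_idx + int(round(window_s[0] * fs))
    b = r_idx + int(round(window_s[1] * fs))
    if b >= len(ecg) or a < 0:
        return None
    if smooth_s > 0:
        lo = max(0, a - int(4 * smooth_s * fs))
        win = gaussian_smooth(ecg[lo:b + 1], fs, smooth_s)[a - lo:]
    else:
        win = ecg[a:b + 1]
    return a + int(np.argmax(win))


def detect_ecg_fiducials(ecg: np.ndarray, fs: float,
                         cfg: RPeakConfig | None = None) -> EcgFiducials:
    """R peaks plus per-beat Q and T locations."""
    r = detect_r_peaks(ecg, fs, cfg)
    q = [locate_q_wave(ecg, int(ri), fs) for ri in r]
    t = [locate_t_peak(ecg, int(ri), fs) for ri in r]
    return EcgFiducials(r_peaks=r, q_onsets=q, t_peaks=t)
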