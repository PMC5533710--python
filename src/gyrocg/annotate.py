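"""GCG fiducial-point annotation.

Within each beat (anchored on the ECG R peak) six points are located:

* ``g_J`` — the dominant y-axis maximum just after R (aortic opening);
* ``g_I`` — the fast downward y-axis notch before g_J (mitral closure);
* ``SPV`` — the broad positive y-axis lobe after g_J (systolic peak
  velocity), located on a 50 ms-smoothed copy because it is a wide wave
  rather than a sharp peak;
* the x-axis "wedge" (almost ``^`` shaped) wave around the second heart
  sound, whose flanking notches are ``g_K`` (aortic closure) and ``g_L``
  (mitral opening);
* ``DPV`` — the minor V-shaped y-axis dip soon after g_L (diastolic
  peak velocity).

Search windows are centred on where these events fall in healthy
resting adults (wedge near R + 360 ms, or on the ECG T peak when one is
available) with widths of roughly +-3 population SDs; all are
configurable.  Each fiducial is the windowed extremum and must be
strictly interior to its window, otherwise it is reported absent — a
windowed global extremum is used rather than nearest-local-extremum
scanning because it is far more robust to noise wiggles while agreeing
with the local-extremum description on clean morphology.

The angular displacement (time integral of the y-axis) is linearly
detrended per beat before its maximum is located: integrating a
band-passed, noisy signal drifts, and detrending makes the maximum
well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks

from ._smoothing import gaussian_smooth
from .beatdetect import DEFAULT_WINDOW_S, segment_beats
from .io import EcgFiducials, GcgFiducials, Recording

__all__ = [
    "AnnotationConfig",
    "annotate_beat",
    "annotate_recording",
    "angular_displacement",
    "locate_max_ang_disp",
]


@dataclass(frozen=True)
class AnnotationConfig:
    """Search windows in ms (relative to R unless noted)."""

    g_j_win_ms: tuple[float, float] = (-20.0, 95.0)
    g_i_span_ms: float = 80.0      # [g_J - span, g_J)
    g_i_min_prominence: float = 0.25  # of the g_I window's dynamic range
    spv_span_ms: float = 120.0     # (g_J, g_J + span]
    spv_smooth_ms: float = 50.0    # Gaussian kernel width (sigma = half)
    kx_center_ms: float = 360.0    # wedge-window centre when no T peak
    kx_half_ms: float = 120.0      # wedge-peak window: centre +- half
    #: With a T peak available the wedge is searched in
    #: [T + lo, T + hi]: the wave sits just after the T wave, so an
    #: asymmetric window excludes the flat pre-T region entirely.
    kx_rel_t_ms: tuple[float, float] = (20.0, 150.0)
    g_k_span_ms: float = 80.0      # [wedge - span, wedge)
    g_l_span_ms: float = 120.0     # (wedge, wedge + span]
    dpv_span_ms: float = 120.0     # (g_L, g_L + span]
    wedge_smooth_ms: float = 20.0  # Gaussian width for the wedge-peak
    #                                search (sigma = half); the wedge is a
    #                                broad arch, the flanking notches are
    #                                searched on the raw x-axis


def _most_prominent_peak(x: np.ndarray, a: int, b: int) -> Optional[int]:
    """Most prominent interior local maximum of x[a:b] (ties -> earliest).

    Used for the broad SPV lobe: the decaying smoothed flank of the g_J
    spike can exceed the lobe in *value* near the window start, but it is
    monotone there and forms no peak, so prominence selects the lobe.
    """
    a = max(a, 0)
    b = min(b, len(x))
    if b - a < 3:
        return None
    peaks, props = find_peaks(x[a:b], prominence=0.0)
    if peaks.size == 0:
        return None
    return a + int(peaks[int(np.argmax(props["prominences"]))])


def _window_extremum(x: np.ndarray, a: int, b: int,
                     mode: str) -> Optional[int]:
    """Extremum of x[a:b]; None unless strictly interior to the window.

    Ties resolve to the earliest sample.
    """
    a = max(a, 0)
    b = min(b, len(x))
    if b - a < 3:
        return None
    win = x[a:b]
    i = int(np.argmax(win) if mode == "max" else np.argmin(win))
    if i == 0 or i == len(win) - 1:
        return None
    return a + i


def annotate_beat(seg: dict[str, np.ndarray], r_idx: int, fs: float,
                  cfg: AnnotationConfig | None = None,
                  t_peak_idx: Optional[int] = None
                  ) -> dict[str, Optional[int]]:
    """Annotate one beat segment; indices are local to the segment.

    ``seg`` must contain ``gyro_y`` and ``gyro_x``; ``r_idx`` is the R
    position within the segment and ``t_peak_idx`` the optional ECG T
    peak used to centre the wedge search.  Absent fiducials are None.
    """
    cfg = cfg or AnnotationConfig()
    gy = np.asarray(seg["gyro_y"], dtype=float)
    gx = np.asarray(seg["gyro_x"], dtype=float)
    if len(gy) != len(gx):
        raise ValueError("gyro_x/gyro_y segments differ in length")
    n_min = r_idx + int(round(cfg.g_j_win_ms[1] / 1000 * fs))
    if len(gy) <= n_min:
        raise ValueError("segment too short for the configured windows")

    def s(ms: float) -> int:
        return int(round(ms / 1000.0 * fs))

    out: dict[str, Optional[int]] = {k: None for k in
                                     ("g_i", "g_j", "g_k", "g_l",
                                      "spv", "dpv")}
    g_j = _window_extremum(gy, r_idx + s(cfg.g_j_win_ms[0]),
                           r_idx + s(cfg.g_j_win_ms[1]) + 1, "max")
    out["g_j"] = g_j
    if g_j is not None:
        g_i = _window_extremum(gy, g_j - s(cfg.g_i_span_ms), g_j, "min")
        # The g_I notch must be a genuine downward notch: when MVC and AO
        # (nearly) merge there is no local dip to find, and the window
        # minimum is a noise wiggle.  Require the dip's prominence to be
        # a fraction of the window's dynamic range.
        if g_i is not None:
            a = max(g_j - s(cfg.g_i_span_ms), 0)
            win = -gy[a:g_j]
            peaks, props = find_peaks(win, prominence=0.0)
            prom = {a + int(pk): pr
                    for pk, pr in zip(peaks, props["prominences"])}
            need = cfg.g_i_min_prominence * float(np.ptp(gy[a:g_j + 1]))
            if prom.get(g_i, 0.0) < need:
                g_i = None
        out["g_i"] = g_i
        gy_s = gaussian_smooth(gy, fs, cfg.spv_smooth_ms / 2000.0)
        out["spv"] = _most_prominent_peak(gy_s, g_j + 1,
                                          g_j + s(cfg.spv_span_ms) + 1)

    gx_s = gaussian_smooth(gx, fs, cfg.wedge_smooth_ms / 2000.0)
    if t_peak_idx is not None:
        w0 = t_peak_idx + s(cfg.kx_rel_t_ms[0])
        w1 = t_peak_idx + s(cfg.kx_rel_t_ms[1])
    else:
        center = r_idx + s(cfg.kx_center_ms)
        w0, w1 = center - s(cfg.kx_half_ms), center + s(cfg.kx_half_ms)
    wedge = _window_extremum(gx_s, w0, w1 + 1, "max")
    if wedge is not None:
        out["g_k"] = _window_extremum(gx, wedge - s(cfg.g_k_span_ms), wedge,
                                      "min")
        out["g_l"] = _window_extremum(gx, wedge + 1,
                                      wedge + s(cfg.g_l_span_ms) + 1, "min")
    if out["g_l"] is not None:
        out["dpv"] = _window_extremum(gy, out["g_l"] + 1,
                                      out["g_l"] + s(cfg.dpv_span_ms) + 1,
                                      "min")
    return out


def angular_displacement(gyro_y: np.ndarray, fs: float) -> np.ndarray:
    """Cumulative trapezoidal integral of the y-axis, in degrees."""
    gyro_y = np.asarray(gyro_y, dtype=float)
    return cumulative_trapezoid(gyro_y, dx=1.0 / fs, initial=0.0)


def locate_max_ang_disp(disp: np.ndarray, bounds: tuple[int, int],
                        q_idx: int) -> Optional[int]:
    """Maximum of the per-beat detrended displacement after the Q wave.

    ``bounds`` delimit the beat (half-open); a straight line fitted over
    the beat is removed, then the argmax over (q_idx, end] is returned
    (ties -> earliest).  None when the search window is empty.
    """
    a, b = bounds
    a = max(a, 0)
    b = min(b, len(disp))
    if b - a < 3 or not a <= q_idx < b - 1:
        return None
    seg = np.asarray(disp[a:b], dtype=float)
    t = np.arange(len(seg))
    coef = np.polynomial.polynomial.polyfit(t, seg, 1)
    resid = seg - np.polynomial.polynomial.polyval(t, coef)
    lo = q_idx - a + 1
    return a + lo + int(np.argmax(resid[lo:]))


def annotate_recording(rec: Recording, ecg_fid: EcgFiducials,
                       cfg: AnnotationConfig | None = None,
                       window_s: tuple[float, float] = DEFAULT_WINDOW_S
                       ) -> GcgFiducials:
    """Annotate every beat of a preprocessed recording.

    Beats are anchored on the ECG R peaks; anchors whose window overruns
    the record edges are skipped.  Returns absolute sample indices.
    """
    segs = segment_beats(rec, ecg_fid.r_peaks, window_s)
    pre = segs.pre_samples
    kept = set(int(a) for a in segs.anchors)
    disp = angular_displacement(rec.gyro_y, rec.fs)

    fid = GcgFiducials(beat_anchor=[int(a) for a in segs.anchors])
    k = 0
    for j, r in enumerate(ecg_fid.r_peaks):
        if int(r) not in kept:
            continue
        a0 = int(r) - pre
        seg = {"gyro_x": segs.segments["gyro_x"][k],
               "gyro_y": segs.segments["gyro_y"][k]}
        t_peak = None
        if ecg_fid.t_peaks and ecg_fid.t_peaks[j] is not None:
            tp = int(ecg_fid.t_peaks[j]) - a0
            if 0 <= tp < seg["gyro_y"].shape[0]:
                t_peak = tp
        beat = annotate_beat(seg, pre, rec.fs, cfg, t_peak_idx=t_peak)
        for name in ("g_i", "g_j", "g_k", "g_l", "spv", "dpv"):
            v = beat[name]
            getattr(fid, name)[k] = None if v is None else a0 + v
        q = ecg_fid.q_onsets[j] if ecg_fid.q_onsets else None
        if q is not None:
            end = int(r) + int(round(window_s[1] * rec.fs))
            fid.max_ang_disp[k] = locate_max_ang_disp(disp, (a0, end), int(q))
        k += 1
    return fid
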