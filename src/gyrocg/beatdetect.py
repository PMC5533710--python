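"""ECG-free heartbeat detection on the GCG y-axis, segmentation, averaging.

Beats are found from the Hilbert envelope of the y-axis angular-velocity
signal: the systolic g_I/g_J complex is the sharpest, largest structure
in each cycle, so a high-passed copy of the signal (default 12 Hz, which
keeps the fast valve transients and rejects the slow systolic/diastolic
lobes) gives an envelope with one dominant hump per beat.  Envelope
peaks above an adaptive threshold (rolling median floor plus half the
floor-to-burst excess) and separated by a refractory period become beat
anchors, each refined to the g_J candidate (the y-axis maximum nearby).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal

from ._smoothing import adaptive_threshold, moving_average
from .io import Recording

__all__ = [
    "BeatDetectConfig",
    "BeatSegments",
    "hilbert_envelope",
    "detect_beats_gcg",
    "segment_beats",
    "ensemble_average",
]

#: Default segmentation window (s before anchor, s after anchor); covers
#: Q through MVO for delay means + ~3 SD at resting heart rates.
DEFAULT_WINDOW_S = (0.2, 0.6)


def hilbert_envelope(x: np.ndarray, fs: float,
                     smooth_s: float = 0.1) -> np.ndarray:
    """Magnitude of the analytic signal, smoothed by a moving average.

    The 100 ms default smoothing merges the per-beat burst of systolic
    oscillations into a single hump.  Invariant under sign flips of x.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 16:
        raise ValueError("need at least 16 samples")
    env = np.abs(signal.hilbert(x))
    if smooth_s > 0:
        env = moving_average(env, fs, smooth_s)
    return env


@dataclass(frozen=True)
class BeatDetectConfig:
    transient_high_hz: Optional[float] = 12.0  # high-pass before the envelope
    smooth_s: float = 0.1
    threshold_frac: float = 0.5   # of the way from the floor to the bursts
    level_window_s: float = 3.0
    level_q: float = 0.95
    refractory_s: float = 0.3
    refine_s: float = 0.06        # half-width of the g_J refinement window
    #: Candidate vetting: after refinement an anchor must reach this
    #: fraction of the median anchor amplitude.  True anchors sit on the
    #: dominant g_J peak; spurious envelope crossings refine onto minor
    #: diastolic lobes far below it.
    amp_gate_frac: float = 0.45


def detect_beats_gcg(gyro_y: np.ndarray, fs: float,
                     cfg: BeatDetectConfig | None = None) -> np.ndarray:
    """Detect heartbeats from the (preprocessed) gyroscope y-axis.

    Returns strictly increasing anchor indices, each at the beat's g_J
    candidate (local y-axis maximum).  Raises for < 2 s of signal; a
    flat signal yields an empty array.
    """
    gyro_y = np.asarray(gyro_y, dtype=float)
    if len(gyro_y) < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    cfg = cfg or BeatDetectConfig()
    x = gyro_y
    if cfg.transient_high_hz:
        sos = signal.butter(2, cfg.transient_high_hz, btype="highpass",
                            output="sos", fs=fs)
        x = signal.sosfiltfilt(sos, x)
    env = hilbert_envelope(x, fs, cfg.smooth_s)
    thr = adaptive_threshold(env, fs, cfg.level_window_s,
                             cfg.threshold_frac, cfg.level_q)
    dist = max(1, int(round(cfg.refractory_s * fs)))
    cand, _ = signal.find_peaks(env, distance=dist)
    cand = cand[env[cand] > thr[cand]]
    # envelope and threshold are unreliable hard against the record ends
    cand = cand[(cand >= dist) & (cand < len(gyro_y) - dist)]
    half = int(round(cfg.refine_s * fs))
    anchors = []
    for c in cand:
        a, b = max(0, c - half), min(len(gyro_y), c + half + 1)
        anchors.append(a + int(np.argmax(gyro_y[a:b])))
    anchors = np.unique(anchors)
    if anchors.size:
        gate = cfg.amp_gate_frac * float(np.median(gyro_y[anchors]))
        anchors = anchors[gyro_y[anchors] >= gate]
    if anchors.size:
        keep = [int(anchors[0])]
        for pk in anchors[1:]:
            if pk - keep[-1] >= dist:
                keep.append(int(pk))
            elif gyro_y[pk] > gyro_y[keep[-1]]:
                keep[-1] = int(pk)
        anchors = np.asarray(keep)
    return np.asarray(anchors, dtype=int)


@dataclass
class BeatSegments:
    """Equal-length per-beat slices of every channel.

    ``segments[channel]`` is an (n_beats, n_samples) array; ``anchors``
    are the kept anchors and ``n_dropped`` counts anchors whose window
    overran the record edges.
    """

    anchors: np.ndarray
    window_s: tuple[float, float]
    fs: float
    segments: dict[str, np.ndarray] = field(default_factory=dict)
    n_dropped: int = 0

    @property
    def pre_samples(self) -> int:
        return int(round(self.window_s[0] * self.fs))

    def __len__(self) -> int:
        return len(self.anchors)


def segment_beats(rec: Recording, anchors: np.ndarray,
                  window_s: tuple[float, float] = DEFAULT_WINDOW_S
                  ) -> BeatSegments:
    """Slice all channels around each anchor; edge-overrunning anchors
    are dropped (their count is reported on the result)."""
    anchors = np.asarray(anchors, dtype=int)
    if anchors.size == 0:
        raise ValueError("no anchors to segment")
    pre = int(round(window_s[0] * rec.fs))
    post = int(round(window_s[1] * rec.fs))
    ok = (anchors - pre >= 0) & (anchors + post <= rec.n)
    kept = anchors[ok]
    segs = {name: np.stack([ch[a - pre:a + post] for a in kept])
            if kept.size else np.empty((0, pre + post))
            for name, ch in rec.channels().items()}
    return BeatSegments(anchors=kept, window_s=window_s, fs=rec.fs,
                        segments=segs, n_dropped=int(np.sum(~ok)))


def ensemble_average(segs: BeatSegments
                     ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Pointwise per-channel mean beat and SD across beats."""
    if len(segs) < 2:
        raise ValueError("need at least 2 segments to average")
    mean = {k: v.mean(axis=0) for k, v in segs.segments.items()}
    sd = {k: v.std(axis=0, ddof=1) for k, v in segs.segments.items()}
    return mean, sd
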