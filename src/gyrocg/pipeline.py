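"""End-to-end convenience pipeline: raw recording -> per-beat intervals."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .annotate import AnnotationConfig, annotate_recording
from .beatdetect import BeatDetectConfig, detect_beats_gcg
from .ecg import RPeakConfig, detect_ecg_fiducials
from .intervals import compute_intervals, heart_rate
from .io import EcgFiducials, GcgFiducials, IntervalRecord, Recording
from .preprocess import PreprocessConfig, preprocess_recording

__all__ = ["PipelineResult", "process_recording"]


@dataclass
class PipelineResult:
    """Everything the pipeline extracts from one recording."""

    recording: Recording              # preprocessed copy
    ecg_fiducials: EcgFiducials
    gcg_fiducials: GcgFiducials
    intervals: list[IntervalRecord]
    gcg_anchors: np.ndarray           # ECG-free beat anchors (g_J candidates)

    def gcg_heart_rate(self) -> list[Optional[float]]:
        """Beat-to-beat heart rate from the ECG-free GCG anchors."""
        return heart_rate(self.gcg_anchors, self.recording.fs)


def process_recording(rec: Recording,
                      preprocess_cfg: PreprocessConfig | None = None,
                      rpeak_cfg: RPeakConfig | None = None,
                      annot_cfg: AnnotationConfig | None = None,
                      beat_cfg: BeatDetectConfig | None = None,
                      qs2_end: str = "g_k") -> PipelineResult:
    """Filter, detect, annotate and convert one recording to intervals.

    ECG R peaks anchor the annotation; the ECG-free GCG beat detector is
    run alongside for heart-rate estimation without the reference lead.
    """
    pre = preprocess_recording(rec, preprocess_cfg)
    ef = detect_ecg_fiducials(pre.ecg, pre.fs, rpeak_cfg)
    gf = annotate_recording(pre, ef, annot_cfg)
    iv = compute_intervals(gf, ef, pre.fs, qs2_end=qs2_end)
    anchors = detect_beats_gcg(pre.gyro_y, pre.fs, beat_cfg)
    return PipelineResult(recording=pre, ecg_fiducials=ef, gcg_fiducials=gf,
                          intervals=iv, gcg_anchors=anchors)
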