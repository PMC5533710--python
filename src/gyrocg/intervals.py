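"""Per-beat cardiac time intervals and cohort summaries.

The GCG fiducials map onto systolic/diastolic time intervals via the
valve-event hypothesis (g_I=MVC, g_J=AVO, g_K=AVC, g_L=MVO):

* PEP  = Q -> g_J (pre-ejection period)
* LVET = g_J -> g_K (left-ventricular ejection time)
* QS2  = Q -> g_K (total electromechanical systole)
* IVCT = g_I -> g_J, IVRT = g_K -> g_L

QS2's far endpoint is g_K interpreted as *aortic closure*: one textual
description labels the QS2 endpoint "g_K (AVO)", which contradicts both
the g_K <-> aortic-closure hypothesis and the physiological definition
of QS2 (Q to the second heart sound); the "(AVO)" reading is treated as
a typo, and ``qs2_end="g_l"`` is available for anyone wanting the
alternative endpoint.  All outputs are milliseconds; intervals with a
missing endpoint are None.

Cohort summaries are two-stage (mean/SD of per-subject means), matching
how subject-level statistics are reported for small cohorts.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import EcgFiducials, GcgFiducials, IntervalRecord, INTERVAL_FIELDS

__all__ = ["compute_intervals", "heart_rate", "summarize_cohort"]


def _ms(a: Optional[int], b: Optional[int], fs: float) -> Optional[float]:
    if a is None or b is None:
        return None
    return (b - a) / fs * 1000.0


def heart_rate(anchors: Sequence[int], fs: float) -> list[Optional[float]]:
    """Instantaneous heart rate, bpm, assigned to the later beat of each
    RR pair; the first beat gets None.  Fewer than 2 anchors -> empty."""
    anchors = np.asarray(anchors, dtype=float)
    if anchors.size < 2:
        return []
    rr = np.diff(anchors) / fs
    return [None] + [60.0 / r for r in rr]


def compute_intervals(gf: GcgFiducials, ef: EcgFiducials, fs: float,
                      qs2_end: str = "g_k") -> list[IntervalRecord]:
    """Per-beat intervals from matched GCG and ECG fiducials.

    Beats are matched on the anchor R peak; an anchor missing from the
    ECG fiducials raises.  The arithmetic identities ivct = r_avo-r_mvc,
    ivrt = r_mvo-r_avc, lvet = r_avc-r_avo and qs2 = pep+lvet hold
    exactly whenever all endpoints are present.
    """
    if qs2_end not in ("g_k", "g_l"):
        raise ValueError("qs2_end must be 'g_k' or 'g_l'")
    r_index = {int(r): j for j, r in enumerate(ef.r_peaks)}
    hrs = heart_rate(gf.beat_anchor, fs)
    out = []
    for i in range(len(gf)):
        r = int(gf.beat_anchor[i])
        if r not in r_index:
            raise ValueError(f"beat anchor {r} has no matching ECG R peak")
        j = r_index[r]
        q = ef.q_onsets[j] if ef.q_onsets else None
        b = gf.beat(i)
        s2 = b[qs2_end]
        rec = IntervalRecord(
            r_mvc=_ms(r, b["g_i"], fs),
            r_avo=_ms(r, b["g_j"], fs),
            r_avc=_ms(r, b["g_k"], fs),
            r_mvo=_ms(r, b["g_l"], fs),
            ivct=_ms(b["g_i"], b["g_j"], fs),
            ivrt=_ms(b["g_k"], b["g_l"], fs),
            lvet=_ms(b["g_j"], b["g_k"], fs),
            pep=_ms(q, b["g_j"], fs),
            qs2=_ms(q, s2, fs),
            q_spv=_ms(q, b["spv"], fs),
            q_dpv=_ms(q, b["dpv"], fs),
            q_max_ang_disp=_ms(q, b["max_ang_disp"], fs),
            hr=hrs[i] if hrs else None,
        )
        out.append(rec)
    return out


def subject_means(records: Sequence[IntervalRecord]) -> dict[str, float]:
    """Mean of each interval over a subject's beats (absent values
    excluded); intervals absent in every beat are omitted."""
    out = {}
    for name in INTERVAL_FIELDS:
        vals = [getattr(r, name) for r in records
                if getattr(r, name) is not None]
        if vals:
            out[name] = float(np.mean(vals))
    return out


def summarize_cohort(per_subject: Sequence[Sequence[IntervalRecord]]
                     ) -> pd.DataFrame:
    """Two-stage cohort summary: mean and sample SD of subject means.

    Returns a DataFrame indexed by interval name with columns
    ``mean``, ``sd``, ``n_subjects`` (subjects contributing at least one
    beat) and ``n_beats`` (total beats with the interval present).
    """
    if not per_subject:
        raise ValueError("need at least one subject")
    means = [subject_means(recs) for recs in per_subject]
    rows = {}
    for name in INTERVAL_FIELDS:
        vals = [m[name] for m in means if name in m]
        n_beats = sum(sum(getattr(r, name) is not None for r in recs)
                      for recs in per_subject)
        if vals:
            rows[name] = {
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "n_subjects": len(vals),
                "n_beats": n_beats,
            }
        else:
            rows[name] = {"mean": np.nan, "sd": np.nan,
                          "n_subjects": 0, "n_beats": 0}
    return pd.DataFrame.from_dict(rows, orient="index")
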