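"""Shared helpers for comparing detections against simulator truth."""

import numpy as np

FIDUCIAL_TRUTH = {
    "g_i": "t_mvc", "g_j": "t_ao", "spv": "t_spv", "g_k": "t_ac",
    "g_l": "t_mvo", "dpv": "t_dpv", "max_ang_disp": "t_max_disp",
}


def fiducial_errors(fid, gt, fs):
    """Per-fiducial lists of (detected - truth) in samples; None kept."""
    t_r = np.round(gt.t_r * fs).astype(int)
    out = {}
    for name, truth_attr in FIDUCIAL_TRUTH.items():
        truth = getattr(gt, truth_attr)
        errs = []
        for k, anchor in enumerate(fid.beat_anchor):
            j = int(np.argmin(np.abs(t_r - anchor)))
            v = getattr(fid, name)[k]
            errs.append(None if v is None else v - round(truth[j] * fs))
        out[name] = errs
    return out


def finite(errors):
    return np.asarray([e for e in errors if e is not None], dtype=float)
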