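"""Agreement between GCG-derived intervals and the reference truth.

Simulates a 9-subject cohort, measures per-beat intervals with the GCG
pipeline, pairs them with the simulator's ground-truth timings (playing
the role of the echocardiographic reference) and reports Pearson r^2,
RMSE and Bland-Altman bias / 95% limits of agreement per interval.
Small bias and narrow limits mean the two "methods" can be used
interchangeably at the printed precision.
"""

import numpy as np
import pandas as pd

from gyrocg import CohortParams, agreement_report, process_recording, \
    simulate_cohort

cohort = CohortParams(n_subjects=9, duration=60.0, seed=42)
rows_m, rows_r = [], []
for subj, (rec, truth) in enumerate(simulate_cohort(cohort)):
    res = process_recording(rec)
    t_r = np.round(truth.t_r * rec.fs).astype(int)
    for k, anchor in enumerate(res.gcg_fiducials.beat_anchor):
        j = int(np.argmin(np.abs(t_r - anchor)))
        iv = res.intervals[k]
        rows_m.append({"subject": subj, "beat": j, "lvet": iv.lvet,
                       "pep": iv.pep, "ivrt": iv.ivrt})
        rows_r.append({
            "subject": subj, "beat": j,
            "lvet": (truth.t_ac[j] - truth.t_ao[j]) * 1000,
            "pep": (truth.t_ao[j] - truth.t_q[j]) * 1000,
            "ivrt": (truth.t_mvo[j] - truth.t_ac[j]) * 1000,
        })

report = agreement_report(pd.DataFrame(rows_m), pd.DataFrame(rows_r),
                          keys=["subject", "beat"])
print(report[["r2", "rmse", "bias", "loa_low", "loa_high", "cv_pct"]]
      .round(2).to_string())
print("\n|bias| of a few ms means the GCG intervals are nearly unbiased; "
      "r2 is high where the physiologic spread (e.g. LVET, SD ~26 ms) "
      "dominates the few-ms detection noise and lower where it does not.")
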