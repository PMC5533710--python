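"""Paired-method agreement statistics.

For two methods measuring the same quantity on the same beats/subjects:
Pearson r^2, RMSE, and Bland-Altman analysis with bias, 95% limits of
agreement (bias -/+ 1.96*SD of the paired differences), the
reproducibility coefficient RPC = 1.96*SD (the maximum difference likely
to occur between observations), and the coefficient of variation
CV% = 100*SD / overall mean of all observations from both methods.
Sample (n-1) SDs are used throughout, appropriate for small cohorts.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import AgreementReport

__all__ = ["pearson_r2", "rmse", "bland_altman", "agreement_report",
           "plot_agreement"]


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired series must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("paired series must be finite")
    return x, y


def pearson_r2(x, y) -> Optional[float]:
    """Square of the Pearson correlation; None when either series has
    zero variance."""
    x, y = _paired(x, y)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(np.sqrt((xd ** 2).sum()))
    sy = float(np.sqrt((yd ** 2).sum()))
    if sx == 0.0 or sy == 0.0:
        return None
    r = float((xd * yd).sum() / (sx * sy))
    return min(r * r, 1.0)


def rmse(x, y) -> float:
    """Root mean square of the paired differences."""
    x, y = _paired(x, y)
    if len(x) < 1:
        raise ValueError("need at least 1 pair")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def bland_altman(x, y) -> AgreementReport:
    """Bland-Altman agreement of x against y (differences d = x - y)."""
    x, y = _paired(x, y)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    rpc = 1.96 * sd
    overall = float(np.concatenate([x, y]).mean())
    cv = 100.0 * sd / overall if overall != 0.0 else None
    return AgreementReport(r2=pearson_r2(x, y), rmse=rmse(x, y), bias=bias,
                           loa_low=bias - rpc, loa_high=bias + rpc,
                           rpc=rpc, cv_pct=cv, n=len(x))


def agreement_report(measured: pd.DataFrame, reference: pd.DataFrame,
                     keys: Sequence[str],
                     intervals: Optional[Sequence[str]] = None
                     ) -> pd.DataFrame:
    """Per-interval agreement between two interval tables.

    Tables are inner-joined on ``keys`` (e.g. subject and beat ids); for
    every shared interval column (or the explicit ``intervals`` list) a
    Bland-Altman report plus r^2 and RMSE is computed over the pairs
    where both tables have a value.  Raises on an empty join.
    """
    joined = measured.merge(reference, on=list(keys),
                            suffixes=("_m", "_r"))
    if joined.empty:
        raise ValueError("no shared keys between measured and reference")
    if intervals is None:
        intervals = [c for c in measured.columns
                     if c not in keys and c in reference.columns]
    rows = {}
    for name in intervals:
        pair = joined[[f"{name}_m", f"{name}_r"]].dropna()
        if len(pair) < 3:
            continue
        rep = bland_altman(pair[f"{name}_m"].to_numpy(),
                           pair[f"{name}_r"].to_numpy())
        rows[name] = rep.as_dict()
    if not rows:
        raise ValueError("no interval with >= 3 complete pairs")
    return pd.DataFrame.from_dict(rows, orient="index")


def plot_agreement(x, y, name: str, path) -> None:
    """Scatter + Bland-Altman panel for one paired quantity.

    Left: measured vs reference with the identity line and r^2; right:
    difference vs pair mean with bias and 95% limits-of-agreement lines.
    Requires matplotlib (an optional dependency).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y = _paired(x, y)
    rep = bland_altman(x, y)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))

    ax1.plot(y, x, "o", ms=3, alpha=0.6)
    lims = [min(x.min(), y.min()), max(x.max(), y.max())]
    ax1.plot(lims, lims, "k--", lw=1)
    r2txt = "undef" if rep.r2 is None else f"{rep.r2:.2f}"
    ax1.set_xlabel(f"reference {name}")
    ax1.set_ylabel(f"measured {name}")
    ax1.set_title(f"r$^2$ = {r2txt}, RMSE = {rep.rmse:.2f}")

    mean_pair = 0.5 * (x + y)
    ax2.plot(mean_pair, x - y, "o", ms=3, alpha=0.6)
    for level, style in ((rep.bias, "-"), (rep.loa_low, "--"),
                         (rep.loa_high, "--")):
        ax2.axhline(level, color="r", ls=style, lw=1)
    ax2.set_xlabel(f"mean {name}")
    ax2.set_ylabel("difference")
    ax2.set_title(f"bias {rep.bias:.2f}, RPC {rep.rpc:.2f}")

    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
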