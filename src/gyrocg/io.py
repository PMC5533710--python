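"""Shared data model and file formats.

A :class:`Recording` holds synchronized ECG (mV), 3-axis gyroscope
(degrees/s, "dps") and optional 3-axis accelerometer (g) channels sampled
at a common rate.  Axis convention for the chest-mounted sensor: x points
laterally left->right, y head->foot, z back->front.

File formats are plain text: recordings are CSV with a small comment
header (``# fs_hz=...``, ``# units=...``), per-beat interval tables are
TSV with millisecond values at one decimal, and simulator ground truth is
JSON.  Sample indices are 0-based; times are seconds internally and
milliseconds in all reports.  Absent (undetected) fiducials and intervals
are encoded as ``None`` in memory and empty fields / ``null`` on disk,
never as sentinel numbers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HeaderError",
    "FormatError",
    "DataError",
    "Recording",
    "EcgFiducials",
    "GcgFiducials",
    "IntervalRecord",
    "GroundTruth",
    "AgreementReport",
    "read_recording",
    "write_recording",
    "write_intervals",
    "read_intervals",
    "read_groundtruth",
    "write_groundtruth",
    "INTERVAL_FIELDS",
]


class HeaderError(ValueError):
    """Recording header is missing or invalid (e.g. fs <= 0)."""


class FormatError(ValueError):
    """File does not conform to the expected column layout."""


class DataError(ValueError):
    """File parsed but contains invalid data (e.g. non-finite samples)."""


GYRO_CHANNELS = ("gyro_x", "gyro_y", "gyro_z")
ACC_CHANNELS = ("acc_x", "acc_y", "acc_z")


@dataclass
class Recording:
    """Synchronized multichannel chest-motion + ECG recording.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz (> 0). All channels share it.
    ecg : ndarray
        ECG in mV.
    gyro_x, gyro_y, gyro_z : ndarray
        Angular velocity in degrees per second.
    acc_x, acc_y, acc_z : ndarray, optional
        Linear acceleration in g. A gyro-only recording is valid.
    t0 : float
        Start time in seconds (default 0).
    """

    fs: float
    ecg: np.ndarray
    gyro_x: np.ndarray
    gyro_y: np.ndarray
    gyro_z: np.ndarray
    acc_x: Optional[np.ndarray] = None
    acc_y: Optional[np.ndarray] = None
    acc_z: Optional[np.ndarray] = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise HeaderError(f"sampling rate must be > 0, got {self.fs}")
        for name in ("ecg",) + GYRO_CHANNELS + ACC_CHANNELS:
            x = getattr(self, name)
            if x is None:
                continue
            x = np.asarray(x, dtype=float)
            setattr(self, name, x)
            if x.ndim != 1:
                raise DataError(f"channel {name} must be 1-D")
            if x.shape[0] != self.n:
                raise DataError(
                    f"channel {name} has length {x.shape[0]}, expected {self.n}"
                )
            if not np.all(np.isfinite(x)):
                raise DataError(f"channel {name} contains non-finite samples")

    @property
    def n(self) -> int:
        return int(np.asarray(self.ecg).shape[0])

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def has_acc(self) -> bool:
        return all(getattr(self, c) is not None for c in ACC_CHANNELS)

    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def channels(self) -> dict[str, np.ndarray]:
        """Present channels as an ordered name -> array mapping."""
        out = {"ecg": self.ecg}
        for name in GYRO_CHANNELS + ACC_CHANNELS:
            x = getattr(self, name)
            if x is not None:
                out[name] = x
        return out

    def replace(self, **channels: np.ndarray) -> "Recording":
        return dataclasses.replace(self, **channels)


@dataclass
class EcgFiducials:
    """Per-beat ECG reference points (sample indices).

    ``r_peaks`` is strictly increasing; ``q_onsets``/``t_peaks`` hold one
    entry per R peak, ``None`` where the point could not be located.
    """

    r_peaks: np.ndarray
    q_onsets: list[Optional[int]] = field(default_factory=list)
    t_peaks: list[Optional[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r_peaks = np.asarray(self.r_peaks, dtype=int)
        if self.r_peaks.size and np.any(np.diff(self.r_peaks) <= 0):
            raise DataError("r_peaks must be strictly increasing")
        for seq, name, later in ((self.q_onsets, "q_onsets", False),
                                 (self.t_peaks, "t_peaks", True)):
            if seq and len(seq) != len(self.r_peaks):
                raise DataError(f"{name} must have one entry per R peak")
            for i, v in enumerate(seq):
                if v is None:
                    continue
                if later and not v > self.r_peaks[i]:
                    raise DataError("t_peaks must follow their R peak")
                if not later and not v < self.r_peaks[i]:
                    raise DataError("q_onsets must precede their R peak")

    def __len__(self) -> int:
        return len(self.r_peaks)


#: Event order required of the six fiducials when all are present.
_GCG_ORDER = ("g_i", "g_j", "spv", "g_k", "g_l", "dpv")


@dataclass
class GcgFiducials:
    """Detected GCG fiducial points, one entry per beat (sample indices).

    g_I/g_J are the y-axis notch/peak at mitral closure and aortic
    opening; g_K/g_L the x-axis notches at aortic closure and mitral
    opening; SPV/DPV the systolic and diastolic peak-velocity waves;
    ``max_ang_disp`` the maximum of the integrated y-axis (angular
    displacement).  ``beat_anchor`` is the paired ECG R peak (or GCG beat
    anchor).  Undetected points are ``None``.
    """

    beat_anchor: list[int]
    g_i: list[Optional[int]] = field(default_factory=list)
    g_j: list[Optional[int]] = field(default_factory=list)
    g_k: list[Optional[int]] = field(default_factory=list)
    g_l: list[Optional[int]] = field(default_factory=list)
    spv: list[Optional[int]] = field(default_factory=list)
    dpv: list[Optional[int]] = field(default_factory=list)
    max_ang_disp: list[Optional[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        nb = len(self.beat_anchor)
        for name in _GCG_ORDER + ("max_ang_disp",):
            seq = getattr(self, name)
            if not seq:
                setattr(self, name, [None] * nb)
            elif len(seq) != nb:
                raise DataError(f"{name} must have one entry per beat")

    def __len__(self) -> int:
        return len(self.beat_anchor)

    def beat(self, i: int) -> dict[str, Optional[int]]:
        return {name: getattr(self, name)[i]
                for name in _GCG_ORDER + ("max_ang_disp",)}

    def check_order(self) -> None:
        """Raise if any beat with all six fiducials violates
        g_I < g_J <= SPV < g_K < g_L <= DPV."""
        for i in range(len(self)):
            b = self.beat(i)
            if any(b[k] is None for k in _GCG_ORDER):
                continue
            seq = [b[k] for k in _GCG_ORDER]
            ok = (seq[0] < seq[1] <= seq[2] < seq[3] < seq[4] <= seq[5])
            if not ok:
                raise DataError(f"fiducial order violated in beat {i}: {b}")


INTERVAL_FIELDS = (
    "r_mvc", "r_avo", "r_avc", "r_mvo",
    "ivct", "ivrt", "qs2", "lvet", "pep",
    "q_spv", "q_dpv", "q_max_ang_disp", "hr",
)


@dataclass
class IntervalRecord:
    """Cardiac time intervals for one beat, in milliseconds (hr in bpm).

    By construction ivct = r_avo - r_mvc, ivrt = r_mvo - r_avc,
    lvet = r_avc - r_avo and qs2 = pep + lvet whenever all endpoints are
    present.  Fields with a missing endpoint are ``None``.
    """

    r_mvc: Optional[float] = None
    r_avo: Optional[float] = None
    r_avc: Optional[float] = None
    r_mvo: Optional[float] = None
    ivct: Optional[float] = None
    ivrt: Optional[float] = None
    qs2: Optional[float] = None
    lvet: Optional[float] = None
    pep: Optional[float] = None
    q_spv: Optional[float] = None
    q_dpv: Optional[float] = None
    q_max_ang_disp: Optional[float] = None
    hr: Optional[float] = None

    def as_dict(self) -> dict[str, Optional[float]]:
        return {k: getattr(self, k) for k in INTERVAL_FIELDS}


@dataclass
class GroundTruth:
    """Simulator truth: per-beat event times in seconds.

    Event order within each beat: t_q < t_r < t_mvc < t_ao <= t_spv <
    t_ac < t_mvo <= t_dpv.  ``t_max_disp`` (the angular-displacement
    maximum) is unconstrained relative to t_ac/t_mvo.
    """

    t_q: np.ndarray
    t_r: np.ndarray
    t_mvc: np.ndarray
    t_ao: np.ndarray
    t_ac: np.ndarray
    t_mvo: np.ndarray
    t_spv: np.ndarray
    t_dpv: np.ndarray
    t_max_disp: np.ndarray
    mean_hr: float = float("nan")

    _EVENTS = ("t_q", "t_r", "t_mvc", "t_ao", "t_ac", "t_mvo",
               "t_spv", "t_dpv", "t_max_disp")

    def __post_init__(self) -> None:
        for name in self._EVENTS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t_r)
        for name in self._EVENTS:
            if len(getattr(self, name)) != n:
                raise DataError(f"{name} must have one entry per beat")
        ordered = ("t_q", "t_r", "t_mvc", "t_ao", "t_spv")
        for a, b in zip(ordered[:-1], ordered[1:]):
            if np.any(getattr(self, a) >= getattr(self, b)):
                raise DataError(f"event order violated: {a} >= {b}")
        if np.any(self.t_spv >= self.t_ac) or np.any(self.t_ac >= self.t_mvo):
            raise DataError("event order violated around aortic closure")
        if np.any(self.t_mvo > self.t_dpv):
            raise DataError("event order violated: t_mvo > t_dpv")
        if n > 1 and np.any(np.diff(self.t_r) <= 0):
            raise DataError("beats must be non-overlapping/increasing")

    def __len__(self) -> int:
        return len(self.t_r)

    def to_dict(self) -> dict:
        d = {name: getattr(self, name).tolist() for name in self._EVENTS}
        d["mean_hr"] = self.mean_hr
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**{k: np.asarray(v, dtype=float) if k != "mean_hr" else v
                      for k, v in d.items()})


@dataclass
class AgreementReport:
    """Paired-method agreement statistics.

    bias = mean(x - y); loa = bias -/+ 1.96*SD of differences (95% limits
    of agreement); rpc = 1.96*SD (reproducibility coefficient); cv_pct =
    100*SD / overall mean of both methods.  ``r2``/``cv_pct`` are ``None``
    when undefined (zero variance / zero overall mean).
    """

    r2: Optional[float]
    rmse: float
    bias: float
    loa_low: float
    loa_high: float
    rpc: float
    cv_pct: Optional[float]
    n: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Recording CSV

_REQUIRED_COLS = ("t", "ecg", "gyro_x", "gyro_y", "gyro_z")
_UNITS_LINE = "ecg:mV,gyro:dps,acc:g"


def read_recording(path) -> Recording:
    """Read a recording CSV (see :func:`write_recording` for the dialect)."""
    fs = None
    t0 = 0.0
    n_header = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if body.startswith("fs_hz="):
                try:
                    fs = float(body.split("=", 1)[1])
                except ValueError as e:
                    raise HeaderError(f"unparseable fs_hz line: {line!r}") from e
            elif body.startswith("t0_s="):
                t0 = float(body.split("=", 1)[1])
    if fs is None:
        raise HeaderError("missing '# fs_hz=' header line")
    if fs <= 0:
        raise HeaderError(f"fs must be > 0, got {fs}")
    df = pd.read_csv(path, skiprows=n_header)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required columns: {missing}")
    if not df.apply(lambda c: np.all(np.isfinite(c.to_numpy(float))), axis=0).all():
        raise DataError("recording contains non-finite values")
    kw = {}
    for c in ACC_CHANNELS:
        if c in df.columns:
            kw[c] = df[c].to_numpy(float)
    return Recording(fs=fs, t0=t0, ecg=df["ecg"].to_numpy(float),
                     gyro_x=df["gyro_x"].to_numpy(float),
                     gyro_y=df["gyro_y"].to_numpy(float),
                     gyro_z=df["gyro_z"].to_numpy(float), **kw)


def write_recording(rec: Recording, path, precision: int = 9) -> None:
    """Write a recording as CSV.

    Dialect: comment lines ``# fs_hz=<float>``, ``# t0_s=<float>``,
    ``# units=ecg:mV,gyro:dps,acc:g``; then a header row
    ``t,ecg,gyro_x,gyro_y,gyro_z[,acc_x,acc_y,acc_z]`` and one row per
    sample.  Values use ``precision`` significant digits, enough for a
    1e-9 round trip on signals of order unity.
    """
    cols = {"t": rec.time(), **rec.channels()}
    df = pd.DataFrame(cols)
    with open(path, "w", encoding="utf-8") as fh:
        fs = rec.fs
        fh.write(f"# fs_hz={fs:g}\n")
        fh.write(f"# t0_s={rec.t0:g}\n")
        fh.write(f"# units={_UNITS_LINE}\n")
        df.to_csv(fh, index=False, float_format=f"%.{precision}e")


# ---------------------------------------------------------------------------
# Interval TSV

def write_intervals(records: Sequence[IntervalRecord], path) -> None:
    """Write per-beat intervals as TSV, milliseconds with one decimal."""
    if not records:
        raise DataError("no interval records to write")
    rows = []
    for r in records:
        rows.append({k: ("" if v is None else f"{v:.1f}")
                     for k, v in r.as_dict().items()})
    pd.DataFrame(rows, columns=list(INTERVAL_FIELDS)).to_csv(
        path, sep="\t", index=False)


def read_intervals(path) -> list[IntervalRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in INTERVAL_FIELDS if c not in df.columns]
    if missing:
        raise FormatError(f"missing interval columns: {missing}")
    out = []
    for _, row in df.iterrows():
        kw = {k: (None if pd.isna(row[k]) else float(row[k]))
              for k in INTERVAL_FIELDS}
        out.append(IntervalRecord(**kw))
    return out


# ---------------------------------------------------------------------------
# Ground truth JSON

def write_groundtruth(gt: GroundTruth, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(gt.to_dict(), fh, indent=1)


def read_groundtruth(path) -> GroundTruth:
    with open(path, "r", encoding="utf-8") as fh:
        return GroundTruth.from_dict(json.load(fh))
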