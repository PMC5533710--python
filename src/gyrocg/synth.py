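"""Synthetic coupled ECG + GCG (+ SCG) generator with exact ground truth.

The generator is phenomenological: each heartbeat deposits parametric
pulse atoms (Gaussians, a sin^2 arch with flanking notches, and a
compact-support displacement bump) onto the gyroscope axes at the true
valve-event times, so every downstream stage (filtering, beat detection,
fiducial annotation, interval estimation) can be validated against known
per-beat event times without hardware.

Morphology emulated per axis (amplitudes of order a few degrees/second):

* **y-axis** (head->foot): a fast downward notch at mitral valve closure
  (MVC, the g_I point), the dominant positive peak at aortic valve
  opening (AO, g_J), a broad positive systolic lobe (SPV), and a minor
  V-shaped dip at the diastolic peak-velocity wave (DPV), followed by a
  broad shallow recoil lobe scaled so the beat's net y integral is zero;
  the maximum of the integrated y-axis (angular displacement) is then
  pinned by a dedicated compact-support bump atom whose integral peaks
  exactly at the configured Q -> max-displacement delay.
* **x-axis** (left->right): a systolic down-up-down deflection around the
  R wave and, around the second heart sound, an up-down "wedge" wave
  spanning aortic closure (AC, g_K) to mitral opening (MVO, g_L) built as
  a sin^2 arch with negative Gaussian notches centred exactly on AC and
  MVO, so both local minima land on the events.
* **z-axis**: a low-amplitude mixture of the x and y patterns (simulated
  and filtered downstream, never annotated).

Subject-to-subject variation draws cardiac time intervals as a chain of
increments (R->MVC, IVCT, LVET, IVRT, AO->SPV, MVO->DPV, AC->maxdisp)
so the physiological event order holds for every subject by
construction; the default increment distributions reproduce the timing
statistics of pulsed-wave Doppler reference measurements in healthy
adults (HR 59+-12 bpm, R-MVC 20+-6, IVCT 29+-12, LVET 310+-26,
IVRT 68+-14 ms, ...).  Within a subject the increments get small
beat-to-beat jitter (default SD 3 ms); only the RR interval varies by
default.  Respiration enters as multiplicative amplitude modulation of
the motion channels; measurement noise is additive white Gaussian and is
applied after the ground truth is fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import GroundTruth, Recording

__all__ = [
    "ParameterError",
    "SubjectParams",
    "CohortParams",
    "DELAY_MEANS_MS",
    "DELAY_POP_SD_MS",
    "PULSE_AMPLITUDES",
    "PULSE_WIDTHS_MS",
    "beat_template",
    "simulate_subject",
    "simulate_cohort",
    "subject_noise_for_snr",
]


class ParameterError(ValueError):
    """Simulator parameters violate their constraints."""


# Interval-increment means (ms).  q_r is fixed across subjects at
# PEP - R-AVO = 82 - 49 = 33 ms so the PEP and QS2 identities reproduce
# the reference-column values; ac_maxdisp = Q-AC - Q-maxdisp = 392 - 371.
DELAY_MEANS_MS: dict[str, float] = {
    "q_r": 33.0,        # ECG Q to R
    "r_mvc": 20.0,      # R to mitral closure (g_I)
    "ivct": 29.0,       # MVC to AO (g_I to g_J)
    "lvet": 310.0,      # AO to AC (g_J to g_K)
    "ivrt": 68.0,       # AC to MVO (g_K to g_L)
    "ao_spv": 52.0,     # AO to systolic peak velocity (= Q-Sa 134 - PEP 82)
    "mvo_dpv": 7.0,     # MVO to diastolic peak velocity (= Q-Ea 467 - Q-MVO 460)
    "ac_maxdisp": 21.0,  # AC back to angular-displacement maximum (392 - 371)
}

#: Between-subject SDs (ms).  sd(Q-maxdisp) = sqrt(6^2+12^2+26^2+13^2) ~ 32.0,
#: matching the reported 31.9; ao_spv sd = sqrt(20^2 - 10^2) from Q-Sa vs PEP.
DELAY_POP_SD_MS: dict[str, float] = {
    "q_r": 0.0,
    "r_mvc": 6.0,
    "ivct": 12.0,
    "lvet": 26.0,
    "ivrt": 14.0,
    "ao_spv": 17.3,
    "mvo_dpv": 3.0,
    "ac_maxdisp": 13.0,
}

# Physiological floors/caps: healthy-adult intervals never shrink to the
# point where adjacent valve events merge into one unresolvable wave, so
# draws are clipped at morphological resolvability limits (the IVCT floor
# clips ~18% of draws and shifts its mean by ~+1 ms; the rest < 1 ms).
_DELAY_LIMITS_MS: dict[str, tuple[float, float]] = {
    "q_r": (20.0, 60.0),
    "r_mvc": (8.0, math.inf),
    "ivct": (20.0, math.inf),
    "lvet": (150.0, math.inf),
    "ivrt": (45.0, math.inf),
    "ao_spv": (25.0, 115.0),
    "mvo_dpv": (2.0, math.inf),
    "ac_maxdisp": (-math.inf, math.inf),
}

HR_POPULATION = (59.0, 12.0)  # bpm, between-subject
_HR_LIMITS = (35.0, 120.0)

#: Pulse amplitudes.  Gyro atoms in degrees/s, ECG in mV, accelerometer
#: in g; disp_bump_deg is the *height in degrees* of the angular-
#: displacement bump.  A broad shallow "recoil" lobe after DPV is scaled
#: at run time so each beat's net y-axis integral is zero.
PULSE_AMPLITUDES: dict[str, float] = {
    "mvc": -3.3,
    "ao": 4.8,
    "post_ao": -0.875,
    "spv": 1.8,
    "dpv": -1.2,
    "arch": 1.4,
    "notch": -1.8,
    "x_sys_1": -1.0,
    "x_sys_2": 2.0,
    "x_sys_3": -1.2,
    "z_from_y": 0.30,
    "z_from_x": 0.35,
    "disp_bump_deg": 0.07,
    "ecg_q": -0.12,
    "ecg_r": 1.0,
    "ecg_s": -0.25,
    "ecg_t": 0.30,
    "acc_ao": 0.030,
    "acc_ac": 0.015,
}

PULSE_WIDTHS_MS: dict[str, float] = {
    "mvc": 7.0,
    "ao": 7.0,
    "post_ao": 12.0,
    "spv": 18.0,
    "dpv": 14.0,
    "recoil": 35.0,
    "notch": 9.0,
    "x_sys": 8.0,
    "disp_bump_half": 70.0,   # compact half-width of the displacement bump
    "ecg_q": 8.0,
    "ecg_r": 10.0,
    "ecg_s": 8.0,
    "ecg_t": 40.0,
    "acc": 5.0,
}

#: x-axis systolic deflection offsets after R (s); cosmetic, never annotated.
_X_SYS_OFFSETS_S = (0.010, 0.040, 0.070)

_TEMPLATE_SUPPORT_S = (-0.30, 0.80)

_EVENT_ORDER = ("mvc", "ao", "spv", "ac", "mvo", "dpv")


def _gauss(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


#: Recoil-lobe centre: this far after DPV (s), outside every search window.
_RECOIL_OFFSET_S = 0.09
#: The x-axis arch starts/ends this far inside the AC->MVO span (s).
_ARCH_INSET_S = 0.005
#: Arch span at the population-mean IVRT; arch amplitude scales as
#: (reference span / span), conserving the wave's angular impulse when a
#: shorter isovolumetric relaxation narrows it.
_ARCH_REF_SPAN_S = 0.058
#: Post-ejection downstroke: this far after AO (s).  Tightly paired with
#: the AO peak and sized so the systolic complex (MVC dip, AO peak,
#: downstroke) is area-free — oscillatory, as band-limited valve
#: transients are — its heavily smoothed field nearly cancels and the
#: broad SPV lobe keeps a clean maximum.
_POST_AO_OFFSET_S = 0.016
#: Reference smoothing scale (s) at which the SPV lobe is a "wide wave":
#: the lobe centre is solved so the signal smoothed at this scale peaks
#: exactly at the SPV event (the annotator's default smoothing sigma).
_SPV_SMOOTH_REF_S = 0.025


def _recoil_amp(offsets: dict, amps: dict, widths: dict) -> float:
    """Recoil amplitude zeroing the beat's net y-axis integral.

    Gaussian atom area is amp*sigma*sqrt(2pi); sqrt(2pi) cancels, so the
    balance reduces to the signed amp*width sum of the atoms present.
    The displacement bump has zero net integral and does not enter.
    """
    total = sum(amps[ev] * widths[ev] for ev in ("mvc", "ao", "spv", "dpv")
                if ev in offsets)
    if "ao" in offsets:
        total += amps["post_ao"] * widths["post_ao"]
    return -total / widths["recoil"]


def _field_slope(t: float, atoms: list[tuple[float, float, float]],
                 sk2: float) -> float:
    """Slope at time t of a sum of Gaussian atoms smoothed by a Gaussian
    kernel of variance sk2 (closed form; sk2=0 gives the raw field)."""
    slope = 0.0
    for a, c, s in atoms:
        se2 = s * s + sk2
        k = a if sk2 == 0.0 else a * s / math.sqrt(se2)
        g = k * math.exp(-0.5 * (t - c) ** 2 / se2)
        slope += -g * (t - c) / se2
    return slope


def _solve_center(t: float, amp: float, sigma: float,
                  others: list[tuple[float, float, float]],
                  sk2: float = 0.0) -> float:
    """Atom centre such that the (optionally smoothed) total field has a
    critical point exactly at the event time t.

    Neighbouring atom tails pull an extremum off its atom's centre; the
    centre is therefore back-shifted by the fixed-point solution of
    amp_eff * u / se2 * exp(-u^2/(2 se2)) = slope_others(t).  Keeps every
    detected extremum on its event to sub-sample accuracy by
    construction.
    """
    se2 = sigma * sigma + sk2
    k = amp if sk2 == 0.0 else amp * sigma / math.sqrt(se2)
    if k == 0.0:
        return t
    slope = _field_slope(t, others, sk2)
    u = 0.0
    for _ in range(8):
        u_new = slope * se2 / (k * math.exp(-0.5 * u * u / se2))
        u_new = float(np.clip(u_new, -1.5 * sigma, 1.5 * sigma))
        u = 0.5 * u + 0.5 * u_new
    return t - u


def _y_atoms(offsets: dict[str, float], amps: dict, widths: dict
             ) -> list[tuple[str, float, float, float]]:
    """(name, amp, centre, sigma) of the y-axis Gaussian atoms, with
    centres compensated for neighbour pull.

    mvc/ao/dpv extrema are pinned on the raw field; the SPV lobe is
    pinned on the field smoothed at ``_SPV_SMOOTH_REF_S`` (it is a
    *wide* wave, located after smoothing).  The downstroke and recoil
    atoms are morphology, not events, and stay at fixed offsets.
    """
    ms = 1e-3
    base: dict[str, tuple[float, float, float]] = {}
    for ev in ("mvc", "ao", "spv", "dpv"):
        if ev in offsets:
            base[ev] = (amps[ev], offsets[ev], widths[ev] * ms)
    if "ao" in offsets:
        base["post_ao"] = (amps["post_ao"],
                           offsets["ao"] + _POST_AO_OFFSET_S,
                           widths["post_ao"] * ms)
    if "dpv" in offsets:
        base["recoil"] = (_recoil_amp(offsets, amps, widths),
                          offsets["dpv"] + _RECOIL_OFFSET_S,
                          widths["recoil"] * ms)
    solved = dict(base)
    for _sweep in range(3):
        for name in base:
            if name in ("post_ao", "recoil"):
                continue
            a, _, s = base[name]
            others = [v for k, v in solved.items() if k != name]
            sk2 = _SPV_SMOOTH_REF_S ** 2 if name == "spv" else 0.0
            solved[name] = (a, _solve_center(base[name][1], a, s, others, sk2),
                            s)
    return [(name, a, c, s) for name, (a, c, s) in solved.items()]


def _eval_gcg_axes(trel: np.ndarray, offsets: dict[str, float],
                   amps: dict, widths: dict) -> dict[str, np.ndarray]:
    """Evaluate the clean 3-axis GCG beat template.

    trel: times in seconds relative to the R wave.  offsets: event ->
    time after R in seconds; recognised keys are mvc, ao, spv, ac, mvo,
    dpv, max_disp (any subset).
    """
    ms = 1e-3
    y = np.zeros_like(trel)
    x = np.zeros_like(trel)

    for _name, amp, center, sigma in _y_atoms(offsets, amps, widths):
        y += amp * _gauss(trel, center, sigma)

    if "max_disp" in offsets:
        # Derivative of a compact-support cos^2 displacement bump of
        # height H (deg): integral maximum lands exactly at the event.
        c = offsets["max_disp"]
        w = widths["disp_bump_half"] * ms
        h = amps["disp_bump_deg"]
        u = trel - c
        inside = np.abs(u) <= w
        y[inside] += -h * (np.pi / (2.0 * w)) * np.sin(np.pi * u[inside] / w)

    if "ac" in offsets and "mvo" in offsets:
        # sin^2 arch inset from the notches: zero value and slope at the
        # notch positions, so both minima stay exactly on AC/MVO even
        # after band-pass smearing of the arch edges.
        t_ac, t_mvo = offsets["ac"], offsets["mvo"]
        a0 = t_ac + _ARCH_INSET_S
        a1 = t_mvo - _ARCH_INSET_S
        span = a1 - a0
        if span > 0:
            inside = (trel >= a0) & (trel <= a1)
            amp = amps["arch"] * _ARCH_REF_SPAN_S / span
            x[inside] += amp * np.sin(
                np.pi * (trel[inside] - a0) / span) ** 2
        x += amps["notch"] * _gauss(trel, t_ac, widths["notch"] * ms)
        x += amps["notch"] * _gauss(trel, t_mvo, widths["notch"] * ms)

    for off, key in zip(_X_SYS_OFFSETS_S, ("x_sys_1", "x_sys_2", "x_sys_3")):
        x += amps[key] * _gauss(trel, off, widths["x_sys"] * ms)

    z = amps["z_from_y"] * y + amps["z_from_x"] * x
    return {"gyro_x": x, "gyro_y": y, "gyro_z": z}


def _eval_ecg(trel: np.ndarray, q_off: float, t_off: float,
              amps: dict, widths: dict) -> np.ndarray:
    ms = 1e-3
    ecg = amps["ecg_r"] * _gauss(trel, 0.0, widths["ecg_r"] * ms)
    ecg += amps["ecg_q"] * _gauss(trel, q_off, widths["ecg_q"] * ms)
    ecg += amps["ecg_s"] * _gauss(trel, 0.035, widths["ecg_s"] * ms)
    ecg += amps["ecg_t"] * _gauss(trel, t_off, widths["ecg_t"] * ms)
    return ecg


def _eval_acc(trel: np.ndarray, offsets: dict[str, float],
              amps: dict, widths: dict) -> dict[str, np.ndarray]:
    ms = 1e-3
    sig = widths["acc"] * ms
    z = np.zeros_like(trel)
    if "ao" in offsets:
        u = (trel - offsets["ao"]) / sig
        z += -amps["acc_ao"] * u * np.exp(-0.5 * u * u)
    if "ac" in offsets:
        u = (trel - offsets["ac"]) / sig
        z += -amps["acc_ac"] * u * np.exp(-0.5 * u * u)
    return {"acc_x": 0.4 * z, "acc_y": 0.3 * z, "acc_z": z}


def _check_order(offsets: dict[str, float]) -> None:
    present = [(k, offsets[k]) for k in _EVENT_ORDER if k in offsets]
    allow_eq = {("ao", "spv"), ("mvo", "dpv")}
    for (ka, va), (kb, vb) in zip(present[:-1], present[1:]):
        if va > vb or (va == vb and (ka, kb) not in allow_eq):
            raise ParameterError(
                f"event offsets out of order: {ka}={va:.4f} !< {kb}={vb:.4f}")


def beat_template(event_offsets: dict[str, float], fs: float,
                  amplitudes: Optional[dict] = None,
                  widths_ms: Optional[dict] = None,
                  ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Clean single-beat 3-axis GCG template.

    Parameters
    ----------
    event_offsets : dict
        Event -> time after the R wave in *seconds*; any subset of
        ``mvc, ao, spv, ac, mvo, dpv, max_disp``.  Present events must
        respect the order mvc < ao <= spv < ac < mvo <= dpv.
    fs : float
        Sampling rate in Hz.

    Returns
    -------
    (t, axes) : time vector (s, R wave at t=0) over [-0.3, 0.8] s and a
        dict with ``gyro_x``, ``gyro_y``, ``gyro_z`` arrays.
    """
    _check_order(event_offsets)
    amps = {**PULSE_AMPLITUDES, **(amplitudes or {})}
    widths = {**PULSE_WIDTHS_MS, **(widths_ms or {})}
    lo, hi = _TEMPLATE_SUPPORT_S
    t = np.arange(round(lo * fs), round(hi * fs) + 1) / fs
    return t, _eval_gcg_axes(t, event_offsets, amps, widths)


@dataclass
class SubjectParams:
    """One simulated subject.

    ``event_delays`` holds the subject's *mean* interval increments in ms
    (keys of :data:`DELAY_MEANS_MS`); each beat adds Gaussian jitter of
    SD ``delay_jitter_ms`` to every increment (floored at physiological
    limits).  ``noise_sd`` (degrees/s), ``ecg_noise_sd`` (mV) and
    ``acc_noise_sd`` (g) set additive white noise per channel family;
    respiration modulates motion-channel amplitudes multiplicatively by
    ``1 + resp_depth*sin(2*pi*resp_rate/60*t)``.
    """

    mean_hr: float = HR_POPULATION[0]
    hr_sd_within: float = 2.0
    event_delays: dict[str, float] = field(
        default_factory=lambda: dict(DELAY_MEANS_MS))
    delay_jitter_ms: float = 3.0
    pulse_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(PULSE_AMPLITUDES))
    pulse_widths_ms: dict[str, float] = field(
        default_factory=lambda: dict(PULSE_WIDTHS_MS))
    noise_sd: float = 0.0
    ecg_noise_sd: float = 0.0
    acc_noise_sd: float = 0.0
    resp_rate: float = 15.0
    resp_depth: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.ecg_noise_sd < 0 or self.acc_noise_sd < 0:
            raise ParameterError("noise SDs must be >= 0")
        if not 0 <= self.resp_depth < 1:
            raise ParameterError("resp_depth must be in [0, 1)")
        missing = set(DELAY_MEANS_MS) - set(self.event_delays)
        if missing:
            raise ParameterError(f"event_delays missing keys: {sorted(missing)}")


def subject_noise_for_snr(snr_db: Optional[float],
                          amps: Optional[dict] = None) -> dict[str, float]:
    """Noise SDs per channel family for a given amplitude SNR.

    SNR is defined as the amplitude ratio of the dominant pulse (g_J for
    gyro, R for ECG, the AO atom for the accelerometer) to the white
    noise SD: noise_sd = amp / 10**(snr_db/20).  ``snr_db=None`` means
    noise-free.
    """
    if snr_db is None:
        return {"noise_sd": 0.0, "ecg_noise_sd": 0.0, "acc_noise_sd": 0.0}
    a = {**PULSE_AMPLITUDES, **(amps or {})}
    k = 10.0 ** (-snr_db / 20.0)
    return {"noise_sd": a["ao"] * k,
            "ecg_noise_sd": a["ecg_r"] * k,
            "acc_noise_sd": a["acc_ao"] * k}


def _clip_delay(name: str, value: float) -> float:
    lo, hi = _DELAY_LIMITS_MS[name]
    return float(min(max(value, lo), hi))


def _beat_offsets_s(delays_ms: dict[str, float]) -> dict[str, float]:
    """Interval increments (ms) -> event offsets after R (s)."""
    ms = 1e-3
    r_mvc = delays_ms["r_mvc"]
    r_ao = r_mvc + delays_ms["ivct"]
    r_ac = r_ao + delays_ms["lvet"]
    r_mvo = r_ac + delays_ms["ivrt"]
    return {
        "q": -delays_ms["q_r"] * ms,
        "mvc": r_mvc * ms,
        "ao": r_ao * ms,
        "spv": (r_ao + delays_ms["ao_spv"]) * ms,
        "ac": r_ac * ms,
        "mvo": r_mvo * ms,
        "dpv": (r_mvo + delays_ms["mvo_dpv"]) * ms,
        "max_disp": (r_ac - delays_ms["ac_maxdisp"]) * ms,
    }


def simulate_subject(p: SubjectParams, duration: float = 60.0,
                     fs: float = 800.0) -> tuple[Recording, GroundTruth]:
    """Simulate one subject's recording with exact per-beat ground truth.

    Beat anchors follow per-beat RR = 60/N(mean_hr, hr_sd_within)
    truncated above 300 ms.  The returned GroundTruth holds the event
    times of the clean (pre-noise) signal; deterministic given the seed.
    """
    if duration < 5:
        raise ParameterError("duration must be >= 5 s")
    if fs < 200:
        raise ParameterError("fs must be >= 200 Hz")
    rng = np.random.default_rng(p.seed)
    n = int(round(duration * fs))

    # Beat anchor times.
    t_r_list = []
    t = 0.35
    while t <= duration - 0.65 + 1e-9:
        t_r_list.append(t)
        hr_b = p.mean_hr + (rng.normal(0.0, p.hr_sd_within)
                            if p.hr_sd_within > 0 else 0.0)
        rr = 60.0 / max(hr_b, 20.0)
        t += max(rr, 0.301)
    if not t_r_list:
        raise ParameterError("duration too short for any beat")

    # Per-beat jittered increments -> event offsets.
    truth: dict[str, list[float]] = {k: [] for k in (
        "t_q", "t_r", "t_mvc", "t_ao", "t_ac", "t_mvo",
        "t_spv", "t_dpv", "t_max_disp")}
    beat_offsets = []
    for t_r in t_r_list:
        d = {}
        for name, mean in p.event_delays.items():
            j = rng.normal(0.0, p.delay_jitter_ms) if p.delay_jitter_ms > 0 else 0.0
            d[name] = _clip_delay(name, mean + j)
        off = _beat_offsets_s(d)
        beat_offsets.append(off)
        truth["t_r"].append(t_r)
        truth["t_q"].append(t_r + off["q"])
        for ev in ("mvc", "ao", "ac", "mvo", "spv", "dpv"):
            truth[f"t_{ev}"].append(t_r + off[ev])
        truth["t_max_disp"].append(t_r + off["max_disp"])

    # Clean channels.
    chans = {name: np.zeros(n) for name in
             ("ecg", "gyro_x", "gyro_y", "gyro_z", "acc_x", "acc_y", "acc_z")}
    lo, hi = _TEMPLATE_SUPPORT_S
    for t_r, off in zip(t_r_list, beat_offsets):
        i0 = max(0, int(math.floor((t_r + lo) * fs)))
        i1 = min(n, int(math.ceil((t_r + hi) * fs)) + 1)
        trel = np.arange(i0, i1) / fs - t_r
        gcg = _eval_gcg_axes(trel, off, p.pulse_amplitudes, p.pulse_widths_ms)
        ecg = _eval_ecg(trel, off["q"], off["ac"] - 0.045,
                        p.pulse_amplitudes, p.pulse_widths_ms)
        acc = _eval_acc(trel, off, p.pulse_amplitudes, p.pulse_widths_ms)
        chans["ecg"][i0:i1] += ecg
        for name in ("gyro_x", "gyro_y", "gyro_z"):
            chans[name][i0:i1] += gcg[name]
        for name in ("acc_x", "acc_y", "acc_z"):
            chans[name][i0:i1] += acc[name]

    # Respiration amplitude modulation on the motion channels.
    if p.resp_depth > 0:
        tt = np.arange(n) / fs
        mod = 1.0 + p.resp_depth * np.sin(2 * np.pi * p.resp_rate / 60.0 * tt)
        for name in ("gyro_x", "gyro_y", "gyro_z", "acc_x", "acc_y", "acc_z"):
            chans[name] *= mod

    # Additive white noise (truth is pre-noise).
    if p.ecg_noise_sd > 0:
        chans["ecg"] += rng.normal(0.0, p.ecg_noise_sd, n)
    if p.noise_sd > 0:
        for name in ("gyro_x", "gyro_y", "gyro_z"):
            chans[name] += rng.normal(0.0, p.noise_sd, n)
    if p.acc_noise_sd > 0:
        for name in ("acc_x", "acc_y", "acc_z"):
            chans[name] += rng.normal(0.0, p.acc_noise_sd, n)

    tr = np.asarray(truth["t_r"])
    mean_hr = (60.0 * (len(tr) - 1) / (tr[-1] - tr[0])
               if len(tr) > 1 else p.mean_hr)
    gt = GroundTruth(**{k: np.asarray(v) for k, v in truth.items()},
                     mean_hr=float(mean_hr))
    rec = Recording(fs=fs, **chans)
    return rec, gt


@dataclass
class CohortParams:
    """A cohort of independently simulated subjects.

    Per-subject heart-rate and interval-increment means are drawn from
    ``population`` (name -> (mean, sd), with key ``hr`` plus the keys of
    :data:`DELAY_MEANS_MS`); child seeds derive deterministically from
    ``seed``.  ``snr_db`` sets channel noise via
    :func:`subject_noise_for_snr` (None = noise-free).
    """

    n_subjects: int = 9
    duration: float = 60.0
    fs: float = 800.0
    population: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "hr": HR_POPULATION,
            **{k: (DELAY_MEANS_MS[k], DELAY_POP_SD_MS[k])
               for k in DELAY_MEANS_MS}})
    snr_db: Optional[float] = 10.0
    hr_sd_within: float = 2.0
    delay_jitter_ms: float = 3.0
    resp_rate: float = 15.0
    resp_depth: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")


def draw_subject_params(c: CohortParams,
                        rng: np.random.Generator) -> SubjectParams:
    """Draw one subject's parameters from the cohort population."""
    mu, sd = c.population["hr"]
    hr = mu + (rng.normal(0.0, sd) if sd > 0 else 0.0)
    hr = float(min(max(hr, _HR_LIMITS[0]), _HR_LIMITS[1]))
    delays = {}
    for name in DELAY_MEANS_MS:
        mu, sd = c.population[name]
        v = mu + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        delays[name] = _clip_delay(name, v)
    noise = subject_noise_for_snr(c.snr_db)
    return SubjectParams(mean_hr=hr, hr_sd_within=c.hr_sd_within,
                         event_delays=delays,
                         delay_jitter_ms=c.delay_jitter_ms,
                         resp_rate=c.resp_rate, resp_depth=c.resp_depth,
                         seed=int(rng.integers(0, 2**31 - 1)), **noise)


def simulate_cohort(c: CohortParams) -> list[tuple[Recording, GroundTruth]]:
    """Simulate ``c.n_subjects`` independent subjects."""
    rng = np.random.default_rng(c.seed)
    out = []
    for _ in range(c.n_subjects):
        p = draw_subject_params(c, rng)
        out.append(simulate_subject(p, duration=c.duration, fs=c.fs))
    return out
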