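# Methods

`gyrocg` turns chest angular-velocity recordings (gyrocardiography,
GCG) plus a reference ECG into per-beat cardiac fiducial points and
systolic/diastolic time intervals, and quantifies method agreement.
Because no public GCG data sets with beat-level ground truth exist, the
package ships a phenomenological simulator whose per-beat event times
are known exactly; every processing stage is validated against it.

## Signal model and fiducials

The chest-mounted gyroscope measures angular velocity about three axes
(x left→right, y head→foot, z back→front) in degrees/s, with cardiac
amplitudes of a few deg/s. Six fiducial points carry the timing
information:

* **g_I** — fast downward y-axis notch at mitral valve closure (MVC);
* **g_J** — dominant y-axis peak at aortic valve opening (AO), shortly
  after the ECG R wave;
* **SPV** — broad positive y-axis lobe, the systolic peak-velocity
  wave (temporal analogue of the tissue-Doppler Sa wave);
* **g_K / g_L** — the two notches flanking the "wedge" (∧-shaped)
  x-axis wave around the second heart sound, at aortic closure (AC)
  and mitral opening (MVO);
* **DPV** — minor V-shaped y-axis dip soon after g_L, the diastolic
  peak-velocity wave (analogue of Ea);
* **max. angular displacement** — the maximum of the per-beat time
  integral of the y-axis, an analogue of peak myocardial strain.

With the ECG Q and R waves as time references the intervals follow:
PEP = Q→g_J, LVET = g_J→g_K, QS2 = Q→g_K (= PEP + LVET by
construction), IVCT = g_I→g_J, IVRT = g_K→g_L, plus R→event times,
Q→SPV, Q→DPV and Q→max-displacement. One textual source describes the
QS2 endpoint as "g_K (AVO)"; that reading contradicts both the
g_K ↔ aortic-closure hypothesis and the physiological definition of
QS2 (Q to the second heart sound), so g_K is interpreted as aortic
closure and the "(AVO)" label treated as a typo; `qs2_end="g_l"`
selects the alternative endpoint.

## Simulator

Each beat deposits parametric atoms on the axes at the true event
times. The beat anchors follow RR = 60/N(mean HR, within-subject SD),
truncated above 300 ms. Defaults (degrees/s; widths are Gaussian σ in
ms): MVC −3.3/σ7, AO +4.8/σ7, a post-ejection downstroke −0.875/σ12 at
AO+16 ms, SPV +1.8/σ18, DPV −1.2/σ14. The ECG is a sum of Q/R/S/T
Gaussian atoms (R dominant, 1 mV); the accelerometer channels carry
derivative-of-Gaussian bursts at AO/AC (never annotated). Respiration
modulates the motion channels multiplicatively
(1 + 0.2·sin 2π·0.25 Hz·t); white Gaussian noise is added last, so the
ground truth describes the clean signal.

Design choices that make exact truth possible:

* **Solved atom centres.** Overlapping atom tails pull an extremum off
  its atom's centre; each centre is therefore back-shifted by a Newton
  solve on the closed-form Gaussian field so the detected extremum
  lands exactly on the event (to < 1 sample at 800 Hz). The SPV lobe
  is solved on the field *smoothed at 25 ms σ* — SPV is by definition
  a wide-wave maximum, located after smoothing.
* **Area-free systolic complex.** MVC + AO + downstroke integrate to
  zero, as band-limited valve transients do; heavy smoothing therefore
  erases them and leaves the SPV lobe with a clean maximum.
* **Pinned displacement maximum.** A compact-support cos² displacement
  bump (height 0.07°, half-width 70 ms) peaks exactly at the
  configured Q→max-displacement delay; a broad recoil lobe after DPV
  zeroes each beat's net y integral so the integrated signal has no
  cross-beat staircase.
* **Exact wedge notches.** The x-axis wedge is a sin² arch inset 5 ms
  from Gaussian notches centred exactly on AC and MVO (zero arch value
  and slope at the notches). The arch amplitude scales with 1/span
  (impulse conservation), keeping it detectable when a short IVRT
  narrows it.

Subject-to-subject variation draws *interval increments* — R→MVC
(20 ± 6 ms), IVCT (29 ± 12), LVET (310 ± 26), IVRT (68 ± 14), AO→SPV
(52 ± 17.3), MVO→DPV (7 ± 3), AC→max-displacement (21 ± 13), HR
(59 ± 12 bpm), with Q→R fixed at 33 ms — so the event order holds for
every subject by construction, and the derived quantities carry the
healthy-adult reference statistics (PEP 82, QS2 392, Q→max-disp
371 ms). Increments are clipped at morphological-resolvability floors
(IVCT ≥ 20, IVRT ≥ 45, AO→SPV ≥ 25 ms); the IVCT floor clips ~23% of
its normal mass and shifts its mean by about +2 ms, the others well
under 1 ms. Within a subject only RR varies by default; each increment
additionally gets 3 ms SD beat-to-beat jitter. A single integer seed
drives everything; child seeds derive deterministically.

The 10 dB SNR condition means the white-noise SD is the dominant pulse
amplitude (g_J for gyro, R for ECG) divided by 10^(10/20).

**What the simulator does not emulate:** baseline wander and motion
artefacts, electrode noise spectra, arrhythmia or ectopy, morphology
changes with posture or disease, the unknown heart-to-chest transfer
function, and inter-axis cross-talk beyond a fixed linear mixture on
z. Passing tests therefore demonstrate correct *algorithmic* recovery
of known timing structure, not clinical performance on real chests.

## Preprocessing

Gyroscope channels: 4th-order Butterworth band-pass 1–20 Hz;
accelerometer: 4–45 Hz; ECG: FFT band-pass 0.5–45 Hz with
raised-cosine edges (relative transition width 0.1). Filtering is
zero-phase (forward–backward; "order" is per pass, so magnitudes
square) because ms-level interval estimation cannot tolerate IIR group
delay; causal single-pass mode remains available. Butterworth inputs
are reflect-padded by 1 s and trimmed; the FFT filter masks the DFT of
the whole record directly, which suppresses in-mask bins exactly.

## Detection and annotation

**ECG.** R peaks: 5–20 Hz QRS band-pass → squared derivative → 120 ms
moving average → adaptive threshold → refinement to the ECG maximum,
refractory 250 ms. The adaptive threshold used everywhere is
`rolling median + 0.5·(rolling 95th percentile − median)` over a local
window, floored at 70% of the whole-record value so it cannot decay to
the noise floor in beat-free stretches. Q is the minimum of a lightly
smoothed (σ 5 ms) window [R−50, R) ms with an R−33 ms fallback for
monotone windows; T the maximum of a σ 20 ms-smoothed window
[R+150, R+450] ms. Ties in any extremum search resolve to the
earliest sample, package-wide.

**GCG beats (ECG-free).** A 12 Hz 2nd-order zero-phase high-pass keeps
the ~18–23 Hz valve transients and rejects the ~4–9 Hz SPV and
displacement-bump lobes; the Hilbert envelope (100 ms moving average)
is thresholded as above with a 300 ms refractory, each peak refined to
the y-axis maximum within ±60 ms (the g_J candidate), and candidates
must reach 45% of the median anchor amplitude — a vetting step that
rejects envelope crossings that refine onto minor diastolic lobes.

**Fiducials.** Search windows derive from the reference means ± ≈3
population SD, all configurable: g_J = argmax of y in [R−20, R+95] ms
(the upper bound follows the ±3 SD rule for R-AVO 49 ± 10; a wider
window overlaps the SPV lobe); g_I = the window minimum of
[g_J−80, g_J) ms, required to be a dip of prominence ≥ 25% of the
window range (a merged MVC/AO morphology yields *absent*, not a noise
wiggle); SPV = the most prominent interior local maximum of the
σ 25 ms-smoothed y in (g_J, g_J+120] ms — prominence, not raw argmax,
because the smoothed flank of g_J can exceed the lobe in value while
forming no peak; the wedge peak = maximum of σ 10 ms-smoothed x in
[T+20, T+150] ms when a T peak exists (the wave follows the T wave)
or R+360±120 ms otherwise; g_K/g_L = window minima of [wedge−80,
wedge) and (wedge, wedge+120] ms; DPV = minimum of (g_L, g_L+120] ms.
Every extremum must be strictly interior to its (clipped) window,
otherwise the fiducial is reported absent. Windowed global extrema
replace nearest-local-extremum scanning for noise robustness; on clean
morphology the two coincide.

**Angular displacement** is the cumulative trapezoidal integral of the
y-axis; each beat's segment ([R−200, R+600] ms) is linearly detrended
before taking the argmax over (Q, segment end], since integrating a
band-passed noisy signal drifts.

All annotations are invariant under positive rescaling of the gyro
channels (every threshold is relative).

## Intervals and summaries

Intervals are sample differences converted to ms; any interval with a
missing endpoint is absent. The identities IVCT+LVET+IVRT =
R-MVO − R-MVC and QS2 = PEP + LVET hold exactly by construction.
Cohort summaries are two-stage — mean and sample (n−1) SD of
per-subject means — matching how subject-level statistics are reported
for small cohorts. Heart rate is 60/RR per adjacent anchor pair,
assigned to the later beat.

## Agreement statistics

For paired methods: Pearson r² (undefined on zero variance), RMSE,
and Bland–Altman on d = x − y: bias = mean(d), 95% limits of agreement
= bias ∓/± 1.96·SD(d), reproducibility coefficient RPC = 1.96·SD(d),
CV% = 100·SD(d)/mean of all observations from both methods. Sample
SDs throughout.

## Validation and known limitations

On noise-free simulations every fiducial (including the displacement
maximum) is recovered within one sample at 800 Hz; at 10 dB SNR the
median absolute error per fiducial stays below 10 ms. On the study
conditions (9 subjects × 60 s, 800 Hz, 10 dB SNR) the pipeline
recovers the configured cohort means of HR, IVCT, IVRT, LVET, PEP,
QS2 and Q→max-displacement within three standard errors of the
generator distribution; `scripts/acceptance.py` recomputes these from
scratch.

Residual systematic biases of a few ms remain (g_I and g_K pulled
slightly early, g_L late, by band-pass smearing of asymmetric
neighbourhoods; clip-floor shifts in the draws); they are small
relative to the between-subject spread but would matter for
single-subject absolute accuracy. DPV is detected in roughly 80% of
noisy beats — absences are reported, never imputed. The simulator's
problem sizes (60 s records, nine subjects) keep a full cohort run in
a few seconds while leaving ≥ 50 beats per subject for stable means.
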