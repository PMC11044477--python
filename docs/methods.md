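# Methods

This note documents the acoustic model behind the synthetic generator,
the design of each processing stage, the parameters that matter, and
the known limitations. All quantitative statements below are computed
by the test suite or by `scripts/acceptance.py`; nothing here reports a
number the code does not itself produce.

## Signal model and synthetic generator

A chest recording is modelled as

```
x(t) = breath(t) + crackles(t) + wheezes(t) + noise(t)
```

* **Breath sound.** Independent Gaussian noise per analysis band
  (100–200, 200–400, 400–800, 800–1600 Hz; order-8 Butterworth
  filterbank so cross-band leakage is negligible and the rendered
  per-band expiration/inspiration power ratio equals the squared gain
  ratio by construction). Each band is scaled by a per-phase amplitude
  gain and amplitude-modulated by a half-sine flow envelope over the
  phase. Defaults put the spectral peak in 100–200 Hz with roll-off
  above (≈ −6 dB/octave above 300 Hz, the shape of normal vesicular
  breath sound) and make expiration several dB quieter than
  inspiration, giving true E/I ratios of 0.25/0.17/0.24/0.36 across the
  four bands — the regime of tidal chest auscultation. Inspiration and
  expiration are contiguous within a cycle; cycles are separated by a
  breathing pause (default 0.5 s). Default phase durations are 1.2 s
  (inspiration) and 1.8 s (expiration) with 10% jitter.
* **Crackles.** Exponentially damped sinusoids — fine: 650 Hz centre,
  ~5 ms; coarse: 350 Hz, ~10 ms (literature-typical values). Event
  times are Poisson within each phase with a 30 ms minimum separation
  and a *flow-weighted* density (the half-sine envelope): crackles are
  produced by airflow through opening airways, and a uniform density
  would place events at the zero-flow phase edges where their scaled
  amplitude is physically inaudible. Each event is scaled to a target
  SNR (default 12–18 dB) above the local breath-sound envelope.
* **Wheezes.** Sinusoids with slow (±2%) frequency drift and a
  half-sine amplitude envelope, placed inside a host phase.
* **Noise.** White ambient noise at a target SNR relative to the
  *inspiratory* breath RMS — inspiration is the acoustically defining
  phase, and this reference keeps the noise level independent of the
  expiratory gains, which are the quantity under study. Optional
  friction artifacts (band-limited 20–50 ms bursts mimicking
  stethoscope rub) are available but default to zero: the validation
  suite emulates a simulated dataset in which phase timings and crackle
  peaks are the known ground truth, and friction is a separate,
  deliberately unmodelled confounder (the package flags rather than
  removes it).

The 20-recording validation suite varies cycle count (6–8), phase
durations, ambient SNR (uniform 5–20 dB), crackle rates (0–6 per phase,
every fourth recording crackle-free to probe false positives, one third
coarse) and adds an expiratory wheeze to every fifth recording. Suite
generation is a pure function of `(n_recordings, seed)`.

What the generator does **not** emulate: heart and muscle sounds mixed
below 200 Hz, the stethoscope's automatic gain dynamics, airway-tree
acoustics, forced manoeuvres, and real crackle waveform diversity.
Passing tests therefore demonstrate correct mechanics and calibrated
statistics under this model, not clinical-grade performance on patient
audio.

## Denoising

Zero-phase 4th-order Butterworth band-pass (100–1800 Hz) followed by
power-domain spectral subtraction: the noise power spectrum is the mean
over the quietest 10% of 50 ms frames (the breathing pauses), the
subtraction uses over-subtraction factor 1.0 and a spectral floor of
0.05. Subtraction is gated: if the quietest-decile frame power exceeds
half the median frame power, the recording has no noise-only frames to
learn from (e.g. a continuous tone) and the subtraction is skipped —
otherwise a stationary signal would be subtracted away as "noise".

## Stationary/non-stationary separation

Iterative hard thresholding in the wavelet-packet domain (Daubechies-8,
depth 5, ~125 Hz terminal bands at 8 kHz). Two details matter:

* The per-node robust scale (MAD/0.6745) is a **rolling** statistic
  (0.15 s window): breath sound is flow-modulated, and a global
  per-node scale classifies entire loud phases as "transient".
* Successive passes cycle **circular time shifts** (0, 8, 16, 24
  samples): the decimated packet grid is shift-variant, and a transient
  straddling a coefficient boundary in one alignment is caught in
  another. Iteration stops once every shift has been visited and a pass
  adds less than 1% of the input energy (`max_iter` 10).

Coefficients above `k_sigma = 3.5` local scales move to the
non-stationary estimate; the stationary part is defined as the
time-domain residual, so the additive reconstruction is exact. The
threshold trades completeness for purity: at high event SNR the split
captures a median of roughly three quarters of each crackle's energy
(the sub-threshold coefficient tail stays in the breath part), which is
ample for peak timing; lowering the threshold recovers more energy but
floods the transient channel with breath leakage and destroys detection
precision. On crackle-free recordings the non-stationary energy stays
below 5% of the total.

## Respiratory-cycle extraction

Band-limited (150–800 Hz) log-power envelope of the stationary
component, 50 ms frames every 25 ms, 5-frame moving-average smoothing.
Active regions are found by dual-threshold hysteresis: the seed
threshold is the Otsu split of frame powers, capped at floor + 8 dB so
that quiet expirations still seed when the Otsu split lands *between*
the two phase levels (which it does at high SNR); regions extend down
to floor + 2 dB. When the ambient floor is low, an inspiration and its
expiration merge into one region, so regions are split at internal
envelope minima with ≥ 4 dB prominence — the point where the flow
envelope passes through zero between phases. Alternating segments are
labelled by the power-asymmetry prior (chest-wall inspiratory sound is
louder); the parity is a single global bit, and a recording that
violates the prior (dominant bronchial breathing) comes out swapped —
the documented, test-pinned behaviour that the manual-correction path
(`apply_correction`, wholesale replacement) exists for. Cycles whose
phases fall outside 0.2–6 s are dropped; a trailing unpaired segment is
an incomplete cycle and is discarded. Fewer than two detected cycles
raises a degenerate-recording error prompting manual annotation.

Boundary scoring matches predicted to true boundaries greedily in
temporal order, one-to-one, within a tolerance (default ±200 ms);
F = 2PR/(P+R).

## Crackle detection

On the non-stationary component, band-passed to 300–1600 Hz (spanning
coarse and fine crackle spectra while rejecting the loud low-frequency
breath floor). The rectified envelope (2 ms moving RMS) is compared to
`k` times the **local RMS of the stationary component** in the same
band (0.1 s window): a crackle must stand out of the breath sound that
would mask it, and this reference stays meaningful where the sparse
transient channel is silent (a rolling MAD of the transient envelope
itself collapses to zero and passes everything). Peaks closer than
10 ms merge; candidates whose envelope stays above half peak for more
than 25 ms are rejected as friction/motion transients; events outside
annotated phases are discarded. Detection is hysteretic at the event
level: `k = 2.75` admits candidates, but they only count once at least
3 peaks clear the stricter 3.75 confirmation threshold — crackles occur
in showers, and an isolated borderline excursion in an otherwise clean
recording is noise. On crackle-free synthetic recordings this yields
at most ~1 spurious event; detected peaks sit within ~2 ms of the
injected onset.

## Wheeze detection

Spectrogram of the stationary component (1024-point FFT, Hann, 50%
overlap at 8 kHz), restricted to 100–1600 Hz. Per-bin noise power is
chi-squared distributed, so each bin is judged by its excess over that
bin's **temporal median**, on two scales at once: the frame-power-
normalized spectrum (removing flow-envelope modulation, so loud
inspirations are not flagged wholesale) and the raw spectrum (a quiet
pause frame normalizes to a flat shape far above the breath-shaped
floor but has no absolute excess). Bins whose smaller excess exceeds
7 dB seed ridges, linked across frames within ±1 bin; ridges
lasting ≥ 0.25 s (the classical continuous-adventitious-sound duration;
shorter blips are indistinguishable from noise ridges on this grid)
with mean excess ≥ 10 dB become segments. A second pass masks the
time-frequency extent of confirmed ridges and re-estimates the floors,
since a sustained tone contaminates both the frame power and the
medians. Per segment: power-weighted mean ridge frequency; spectral
quartiles of the segment's normalized spectrum; occupation rate = 100 ×
segment duration / total duration of the segment's phase type
(configurable in principle; the phase-type convention is the default
because a per-cycle or whole-recording denominator makes rates from
recordings with different pause structure incomparable).

## E/I power ratios

Per band, the stationary component is band-passed with an order-8
zero-phase Butterworth (the analysis bands abut; shallow skirts leak
the louder neighbour into the ratio) and the expiratory over
inspiratory mean squared amplitude is pooled across cycles. The band's
residual noise power, estimated from the breathing pauses left
uncovered by the annotation (eroded by 0.1 s margins; needs ≥ 0.5 s of
pause), is subtracted from both phase powers first: additive ambient
noise biases the ratio toward 1 and hits the quiet high-frequency
expiratory bands hardest. The corrected estimator recovers the
generator's gain² ground truth within 10% at default conditions, and
on noise-free renderings scaling the expiratory amplitude by `g`
multiplies every ratio by `g²` to well within 2% — with ambient noise
that comparison is not a pure scaling test, because the two renderings
genuinely differ in their noise-to-signal proportions and the
spectral-subtraction stage is correctly nonlinear in that regime.

## Association models

Lobar models: transformed outcome on one predictor with crossed random
intercepts for subject and zone, fitted by REML (statsmodels MixedLM,
variance components on a single group); Wald test and 95% CI on the
slope. The crossed structure is the default reading of "subject and
zone as random effects" (zone labels are shared across subjects); a
nested variant (`random="nested"`) is one switch away. Spirometry
models use a subject intercept only, on recording-averaged features.
Transforms: natural log for E/I ratios (zeros floored at 1e-3 and
flagged — near-zero ratios occur in practice), square root for crackle
counts, log for airway resistance and mid/late expiratory flows.
Direction labels (positive/negative/ns) are assigned by the slope sign
only when p < α and the fit is not singular. Calibration is verified by
simulation from the models' own generative structure: the null
rejection rate over 500 replicates (25 subjects × 5 zones) lies in
[3%, 7%] at α = 0.05, and the 95% CI covers a true slope of 0.5 in
≥ 90% of 200 replicates. Singular or non-converged fits are reported
as `ns` with a diagnostic flag rather than raised.

ICC is the two-way absolute-agreement average-measures coefficient
computed from the ANOVA mean squares,
`(MS_rows − MS_err) / (MS_rows + (MS_cols − MS_err)/n)`; tests pin it
to an independent brute-force decomposition (1e-10) and to pingouin's
ICC(A,k). Bland–Altman reports mean difference ± 1.96 SD. The
Bonferroni-style family adjustment divides 0.05 by the number of
endpoints per family (6 CT score columns, 3 functional-imaging
columns, 5 spirometry columns).

## Problem sizes and numerical choices

The validation suite uses 20 recordings of ~25–35 s at 8 kHz; the
calibration checks use 500 null and 200 effect replicates of the
25-subject × 5-zone design. The working sample rate is fixed at 8 kHz
(comfortably above twice the 1600 Hz top band); times are seconds from
recording start, intervals half-open, sample indices 0-based; peak
normalization is used throughout because only ratios are
interpretable. Wavelet transforms use symmetric padding, trimmed after
reconstruction. Seeds fix every sample path; suite generation and the
CLI are deterministic given (inputs, config, seed).

## Limitations

Detector thresholds were chosen against the generator's ground truth;
on real patient audio — with heart sounds, friction that mimics
crackles, and gain-riding stethoscopes — the same settings will be less
accurate, and the cycle-extraction parity in particular is expected to
need the manual-correction path in a fraction of recordings. Crackle
sub-typing (fine vs coarse classification of *detected* events),
absolute intensity measures and squawk/rhonchus classes are out of
scope. The association layer assumes Gaussian random effects and
residuals on the transformed scales; it reports, but does not model,
singular fits.
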