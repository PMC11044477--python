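"""Synthetic auscultation signals with exhaustive ground truth.

Real chest recordings with known phase timings, crackle positions and
band-power ratios do not exist, so detector validation follows the
simulated-dataset route: render audio whose every property is known by
construction.

The acoustic model:

* **Breath sound** — independent Gaussian noise per analysis band
  (100–200, 200–400, 400–800, 800–1600 Hz), each band scaled by a
  per-phase amplitude gain and amplitude-modulated by a half-sine flow
  envelope over the phase. Inspiration and expiration are contiguous
  within a cycle; cycles are separated by a breathing pause. Default
  gains put the spectral peak in 100–200 Hz with roll-off above
  (normal vesicular breath sound) and make expiration several dB quieter
  than inspiration, so the true E/I power ratio of band *b* is exactly
  ``(exp_gain[b] / insp_gain[b])**2``.
* **Crackles** — exponentially damped sinusoids (fine: ~650 Hz centre,
  ~5 ms; coarse: ~350 Hz, ~10 ms) at Poisson times within phases, with a
  30 ms minimum separation, each scaled to a target SNR above the local
  breath-sound envelope.
* **Wheezes** — amplitude-enveloped sinusoids with slow frequency drift,
  placed inside a phase.
* **Noise** — white ambient noise at a target SNR relative to the RMS of
  the breath sound over active phases, plus optional friction artifacts
  (short low-frequency noise bursts that mimic stethoscope rub).

Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import sosfiltfilt

from .io_audio import Cycle, CycleAnnotation, Recording
from .preprocess import bandpass_sos

__all__ = [
    "ANALYSIS_BANDS",
    "SimulationSpec",
    "CrackleTruth",
    "WheezeTruth",
    "GroundTruth",
    "simulate_recording",
    "make_validation_suite",
    "simulate_lobar_dataset",
]

#: The four analysis bands (Hz) used for E/I power ratios.
ANALYSIS_BANDS: tuple[tuple[float, float], ...] = (
    (100.0, 200.0),
    (200.0, 400.0),
    (400.0, 800.0),
    (800.0, 1600.0),
)

# Default per-band inspiratory amplitude gains: vesicular spectral shape,
# peak in 100-200 Hz, ~ -6 dB/octave above 300 Hz.
_DEFAULT_INSP_GAIN = (1.0, 0.85, 0.42, 0.21)
# Expiration-to-inspiration amplitude ratios giving band power ratios in
# the range reported for tidal chest recordings (E/I well below 1).
_DEFAULT_EI_AMPLITUDE = (0.50, 0.41, 0.49, 0.60)


@dataclass
class SimulationSpec:
    """Parameters of one synthetic recording.

    Durations are seconds; gains are per-band amplitude factors over
    :data:`ANALYSIS_BANDS`; crackle rates are expected events per phase;
    SNRs are dB.
    """

    n_cycles: int = 7
    insp_duration: float = 1.2
    exp_duration: float = 1.8
    pause_duration: float = 0.5
    duration_jitter: float = 0.10  # fractional SD applied to each phase/pause
    insp_gain: tuple[float, float, float, float] = _DEFAULT_INSP_GAIN
    exp_gain: tuple[float, float, float, float] = tuple(
        i * r for i, r in zip(_DEFAULT_INSP_GAIN, _DEFAULT_EI_AMPLITUDE)
    )
    crackles_per_insp: float = 0.0
    crackles_per_exp: float = 0.0
    crackle_kind: str = "fine"  # "fine" | "coarse"
    crackle_snr_db: tuple[float, float] = (12.0, 18.0)
    wheezes: tuple[tuple[str, float, float, float], ...] = ()
    # each: (phase, f0 Hz, duration s, amplitude relative to phase envelope peak)
    ambient_snr_db: float = 15.0
    friction_rate: float = 0.0  # expected artifacts per recording
    lead_silence: float = 0.4
    sample_rate: int = 8000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        for d in (self.insp_duration, self.exp_duration):
            if not (0.2 <= d <= 6.0):
                raise ValueError(f"phase duration {d} s outside [0.2, 6] s")
        if any(g <= 0 for g in self.insp_gain) or any(g <= 0 for g in self.exp_gain):
            raise ValueError("band gains must be positive")
        if len(self.insp_gain) != 4 or len(self.exp_gain) != 4:
            raise ValueError("gains must be 4-vectors over the analysis bands")
        if self.crackle_kind not in ("fine", "coarse"):
            raise ValueError(f"unknown crackle kind {self.crackle_kind!r}")
        for w in self.wheezes:
            if w[0] not in ("inspiration", "expiration"):
                raise ValueError(f"unknown wheeze phase {w[0]!r}")

    @property
    def true_ei_ratios(self) -> tuple[float, float, float, float]:
        """Ground-truth band power ratios, ``(exp_gain/insp_gain)**2``."""
        return tuple((e / i) ** 2 for e, i in zip(self.exp_gain, self.insp_gain))


@dataclass(frozen=True)
class CrackleTruth:
    time: float  # onset, seconds
    phase: str
    kind: str
    snr_db: float
    amplitude: float = 0.0  # peak amplitude before final normalization


@dataclass(frozen=True)
class WheezeTruth:
    start: float
    end: float
    phase: str
    f0: float


@dataclass(frozen=True)
class GroundTruth:
    """Everything true-by-construction about a synthetic recording."""

    annotation: CycleAnnotation
    crackles: tuple[CrackleTruth, ...]
    wheezes: tuple[WheezeTruth, ...]
    true_ei_ratios: tuple[float, float, float, float]
    ambient_snr_db: float

    def crackle_times(self, phase: str | None = None) -> np.ndarray:
        return np.asarray(
            [c.time for c in self.crackles if phase is None or c.phase == phase]
        )


_CRACKLE_SHAPES = {"fine": (650.0, 0.005), "coarse": (350.0, 0.010)}


def _crackle_waveform(kind: str, fs: float) -> np.ndarray:
    """Unit-peak damped sinusoid; onset at sample 0."""
    f0, dur = _CRACKLE_SHAPES[kind]
    n = int(round(2.5 * dur * fs))
    t = np.arange(n) / fs
    w = np.exp(-t / (dur / 2.0)) * np.sin(2 * np.pi * f0 * t)
    return w / np.max(np.abs(w))


def _poisson_times(rng: np.random.Generator, lo: float, hi: float, rate: float,
                   min_sep: float = 0.030, flow_weighted: bool = False) -> list[float]:
    """Poisson-count event times in [lo, hi], thinned to a minimum gap.

    With ``flow_weighted`` the time density follows the half-sine flow
    envelope of the phase (crackles are excited by airflow through
    opening airways, so they cluster where flow is high, not at the
    near-zero-flow phase edges)."""
    span = hi - lo
    if span <= 0 or rate <= 0:
        return []
    n = rng.poisson(rate)
    if flow_weighted:
        # inverse-CDF sampling of density sin(pi u) on [0, 1]
        u = np.arccos(1.0 - 2.0 * rng.uniform(size=n)) / np.pi
        times = np.sort(lo + span * u)
    else:
        times = np.sort(rng.uniform(lo, hi, size=n))
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= min_sep:
            kept.append(float(t))
    return kept


def simulate_recording(spec: SimulationSpec) -> tuple[Recording, GroundTruth]:
    """Render one synthetic auscultation recording with its ground truth."""
    fs = spec.sample_rate
    rng = np.random.default_rng(spec.seed)

    # --- timing grid -----------------------------------------------------
    def jitter(mean: float, lo: float = 0.2, hi: float = 6.0) -> float:
        return float(np.clip(rng.normal(mean, spec.duration_jitter * mean), lo, hi))

    t = spec.lead_silence
    cycles: list[Cycle] = []
    for _ in range(spec.n_cycles):
        di = jitter(spec.insp_duration)
        de = jitter(spec.exp_duration)
        cycles.append(Cycle(t, t + di, t + di + de))
        t = t + di + de + jitter(spec.pause_duration, lo=0.1, hi=3.0)
    total = t + spec.lead_silence
    n = int(round(total * fs))
    tt = np.arange(n) / fs

    # --- per-band breath noise shaped by per-phase half-sine envelopes ---
    envelope = np.zeros((4, n))
    for c in cycles:
        for (lo_t, hi_t, gains) in (
            (c.insp_start, c.insp_end, spec.insp_gain),
            (c.insp_end, c.exp_end, spec.exp_gain),
        ):
            i0, i1 = int(round(lo_t * fs)), int(round(hi_t * fs))
            half_sine = np.sin(np.pi * (tt[i0:i1] - lo_t) / (hi_t - lo_t))
            for b, g in enumerate(gains):
                envelope[b, i0:i1] = g * half_sine

    breath = np.zeros(n)
    # steep (order-8) filterbank: keeps cross-band leakage small so the
    # rendered audio really has the per-band E/I the gains promise
    for b, (lo_hz, hi_hz) in enumerate(ANALYSIS_BANDS):
        sos = bandpass_sos(lo_hz, hi_hz, fs, order=8)
        band_noise = sosfiltfilt(sos, rng.standard_normal(n))
        band_noise /= np.std(band_noise)
        breath += envelope[b] * band_noise

    # ambient noise is referenced to the inspiratory RMS: inspiration is
    # the acoustically defining phase, and this keeps the noise level
    # independent of the expiratory gains (the quantity under study)
    insp_mask = np.zeros(n, dtype=bool)
    for c in cycles:
        insp_mask[int(round(c.insp_start * fs)) : int(round(c.insp_end * fs))] = True
    breath_rms = float(np.sqrt(np.mean(breath[insp_mask] ** 2))) if insp_mask.any() else 0.0
    local_env = np.sqrt(np.sum(envelope**2, axis=0))  # expected local RMS of breath

    x = breath.copy()

    # --- crackles --------------------------------------------------------
    crackles: list[CrackleTruth] = []
    margin = 0.05
    for c in cycles:
        for phase, rate, lo_t, hi_t in (
            ("inspiration", spec.crackles_per_insp, c.insp_start, c.insp_end),
            ("expiration", spec.crackles_per_exp, c.insp_end, c.exp_end),
        ):
            for ct in _poisson_times(rng, lo_t + margin, hi_t - margin, rate,
                                     flow_weighted=True):
                snr = float(rng.uniform(*spec.crackle_snr_db))
                wav = _crackle_waveform(spec.crackle_kind, fs)
                i0 = int(round(ct * fs))
                ref = max(local_env[i0] , 0.05 * max(spec.insp_gain))
                amp = ref * 10 ** (snr / 20.0)
                i1 = min(n, i0 + wav.size)
                x[i0:i1] += amp * wav[: i1 - i0]
                crackles.append(CrackleTruth(ct, phase, spec.crackle_kind, snr, amp))

    # --- wheezes ---------------------------------------------------------
    wheezes: list[WheezeTruth] = []
    for phase, f0, dur, rel_amp in spec.wheezes:
        host = [
            c for c in cycles
            if (c.insp_duration if phase == "inspiration" else c.exp_duration) > dur + 0.1
        ]
        if not host:
            continue
        c = host[rng.integers(len(host))]
        lo_t, hi_t = (
            (c.insp_start, c.insp_end) if phase == "inspiration" else (c.insp_end, c.exp_end)
        )
        start = float(rng.uniform(lo_t + 0.05, hi_t - dur - 0.05))
        i0, i1 = int(round(start * fs)), int(round((start + dur) * fs))
        seg_t = tt[i0:i1] - start
        freq = f0 * (1.0 + 0.02 * np.sin(2 * np.pi * 0.6 * seg_t + rng.uniform(0, 2 * np.pi)))
        phase_acc = 2 * np.pi * np.cumsum(freq) / fs
        env = np.sin(np.pi * seg_t / dur)  # fade in/out
        peak_gain = max(spec.exp_gain if phase == "expiration" else spec.insp_gain)
        x[i0:i1] += rel_amp * peak_gain * env * np.sin(phase_acc)
        wheezes.append(WheezeTruth(start, start + dur, phase, f0))

    # --- ambient noise and friction artifacts ----------------------------
    if spec.ambient_snr_db is not None and breath_rms > 0:
        sigma = breath_rms * 10 ** (-spec.ambient_snr_db / 20.0)
        x += sigma * rng.standard_normal(n)
    if spec.friction_rate > 0:
        for ft in _poisson_times(rng, spec.lead_silence, total - spec.lead_silence,
                                 spec.friction_rate, min_sep=0.2):
            dur_f = rng.uniform(0.02, 0.05)
            nf = int(dur_f * fs)
            burst = rng.standard_normal(nf)
            sos = bandpass_sos(100, 400, fs, order=2)
            burst = sosfiltfilt(sos, burst)
            burst *= np.hanning(nf) / np.max(np.abs(burst) + 1e-12)
            i0 = int(ft * fs)
            i1 = min(n, i0 + nf)
            x[i0:i1] += 1.5 * breath_rms * burst[: i1 - i0]

    peak = np.max(np.abs(x))
    if peak > 0:
        scale = 0.9 / peak
        x = scale * x
        crackles = [replace(c, amplitude=c.amplitude * scale) for c in crackles]

    rec = Recording(samples=x, sample_rate=fs)
    truth = GroundTruth(
        annotation=CycleAnnotation(tuple(cycles), source="corrected"),
        crackles=tuple(crackles),
        wheezes=tuple(wheezes),
        true_ei_ratios=spec.true_ei_ratios,
        ambient_snr_db=spec.ambient_snr_db,
    )
    return rec, truth


def make_validation_suite(
    n_recordings: int = 20, seed: int = 12345
) -> list[tuple[Recording, GroundTruth]]:
    """Deterministic validation suite spanning the detector test space.

    Recordings vary in cycle count (6–8) and duration jitter, ambient SNR
    (5–20 dB) and crackle rates (0–6 per phase, with every fourth
    recording crackle-free to probe false positives); every fifth
    recording carries an expiratory wheeze.
    """
    if n_recordings < 1:
        raise ValueError("n_recordings must be >= 1")
    suite: list[tuple[Recording, GroundTruth]] = []
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_recordings)]
    rng = np.random.default_rng(ss.generate_state(1)[0] % (2**31))
    for i in range(n_recordings):
        crackle_free = i % 4 == 3
        spec = SimulationSpec(
            n_cycles=int(rng.integers(6, 9)),
            insp_duration=float(rng.uniform(1.0, 1.5)),
            exp_duration=float(rng.uniform(1.4, 2.2)),
            crackles_per_insp=0.0 if crackle_free else float(rng.uniform(0.5, 6.0)),
            crackles_per_exp=0.0 if crackle_free else float(rng.uniform(0.0, 6.0)),
            crackle_kind="coarse" if i % 3 == 2 else "fine",
            ambient_snr_db=float(rng.uniform(5.0, 20.0)),
            wheezes=(("expiration", float(rng.uniform(250, 600)), 0.6, 0.4),)
            if i % 5 == 0
            else (),
            seed=child_seeds[i],
        )
        suite.append(simulate_recording(spec))
    return suite


def simulate_lobar_dataset(
    n_subjects: int = 25,
    zones: tuple[str, ...] = ("RUL", "RML", "RLL", "LUL", "LLL"),
    effect_size: float = 0.0,
    variances: dict | None = None,
    seed: int = 0,
    outcome: str = "log_ei_200_400",
    predictor: str = "cfct_total",
) -> pd.DataFrame:
    """Simulate a lobar feature-by-imaging table with known structure.

    One row per subject x zone. The predictor is a standard-normal draw;
    the outcome is ``effect_size * predictor`` plus a subject random
    intercept, a zone random intercept and residual noise — exactly the
    generative model the lobar mixed-effects analysis assumes. Outcome
    and predictor are on the transformed (analysis) scale.

    ``variances`` keys: ``subject``, ``zone``, ``residual`` (defaults
    0.25, 0.09, 1.0). Zero variances give the noiseless limit where the
    slope is recovered exactly.
    """
    v = {"subject": 0.25, "zone": 0.09, "residual": 1.0}
    if variances:
        unknown = set(variances) - set(v)
        if unknown:
            raise ValueError(f"unknown variance keys {sorted(unknown)}")
        v.update(variances)
    if any(val < 0 for val in v.values()):
        raise ValueError("variances must be non-negative")
    if all(val == 0 for val in v.values()) and effect_size == 0:
        pass  # degenerate but permitted: outcome identically zero
    rng = np.random.default_rng(seed)
    nz = len(zones)
    subj_eff = rng.normal(0, math.sqrt(v["subject"]), n_subjects)
    zone_eff = rng.normal(0, math.sqrt(v["zone"]), nz)
    rows = []
    for i in range(n_subjects):
        for j, z in enumerate(zones):
            x = rng.standard_normal()
            y = effect_size * x + subj_eff[i] + zone_eff[j]
            if v["residual"] > 0:
                y += rng.normal(0, math.sqrt(v["residual"]))
            rows.append(
                {
                    "subject_id": f"S{i:03d}",
                    "assessment_id": "A1",
                    "zone": z,
                    predictor: x,
                    outcome: y,
                }
            )
    return pd.DataFrame(rows)
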