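"""Denoising and stationary/non-stationary separation.

Two stages prepare a recording for feature extraction:

1. :func:`denoise` — a zero-phase Butterworth band-pass (default
   100–1800 Hz) removes mains hum, rumble and out-of-band hiss, followed
   by power-domain spectral subtraction with the noise spectrum estimated
   from the quietest frames (breathing pauses).

2. :func:`separate_stationary_nonstationary` — iterative hard
   thresholding in the wavelet-packet domain splits the denoised signal
   into a *stationary* part (breath sound, including any wheezes, which
   are continuous by definition) and a *non-stationary* part carrying
   discontinuous adventitious sounds (crackles, friction, motion
   artifacts). Per terminal node, coefficients larger than ``k_sigma``
   robust standard deviations (MAD-based) are assigned to the
   non-stationary part; the residual is re-decomposed until the
   transient-energy gain per iteration falls below ``tol``.

The split is exactly additive: ``stationary + nonstationary`` equals the
denoised input sample for sample, because the stationary part is defined
as the time-domain residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.signal import ShortTimeFFT, butter, sosfiltfilt
from scipy.signal.windows import hann

from .io_audio import MIN_DURATION_S, Recording

__all__ = ["PreprocessConfig", "ComponentPair", "denoise", "separate_stationary_nonstationary"]


@dataclass
class PreprocessConfig:
    """Tunable parameters of the denoising and separation stages."""

    band_low_hz: float = 100.0
    band_high_hz: float = 1800.0
    filter_order: int = 4
    #: spectral subtraction: frame length (s), quietest-frame fraction,
    #: over-subtraction factor and spectral floor
    ss_frame_s: float = 0.050
    ss_quiet_fraction: float = 0.10
    ss_alpha: float = 1.0
    ss_beta: float = 0.05
    #: subtraction runs only if the quietest frames are genuinely quiet
    #: (quiet/median frame power below this); an always-on signal has no
    #: noise-only frames and would be subtracted away as "noise"
    ss_quiet_gate: float = 0.5
    #: wavelet-packet separation
    wavelet: str = "db8"
    depth: int = 5
    k_sigma: float = 3.5
    #: rolling window (s) for the per-node robust scale; breath sound is
    #: flow-modulated, so the threshold must track the local envelope
    sigma_window_s: float = 0.15
    #: circular sample shifts cycled over the thresholding passes; the
    #: decimated packet grid is shift-variant, so transients straddling a
    #: coefficient boundary in one pass are caught in a shifted one
    shifts: tuple[int, ...] = (0, 8, 16, 24)
    max_iter: int = 10
    tol: float = 0.01


@dataclass(frozen=True)
class ComponentPair:
    """Stationary (breath) / non-stationary (transient) decomposition."""

    stationary: np.ndarray
    nonstationary: np.ndarray
    sample_rate: int
    iterations_used: int

    def __post_init__(self) -> None:
        if self.stationary.shape != self.nonstationary.shape:
            raise ValueError("component lengths differ")

    @property
    def total(self) -> np.ndarray:
        return self.stationary + self.nonstationary


def bandpass_sos(low_hz: float, high_hz: float, sample_rate: float, order: int = 4):
    """Second-order sections of a Butterworth band-pass."""
    nyq = sample_rate / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(f"band ({low_hz}, {high_hz}) Hz invalid at fs={sample_rate}")
    return butter(order, [low_hz / nyq, high_hz / nyq], btype="bandpass", output="sos")


def _spectral_subtract(x: np.ndarray, fs: float, cfg: PreprocessConfig) -> np.ndarray:
    nperseg = max(64, int(round(cfg.ss_frame_s * fs)))
    hop = nperseg // 2
    win = hann(nperseg, sym=False)
    stft = ShortTimeFFT(win, hop=hop, fs=fs)
    spec = stft.stft(x)
    power = np.abs(spec) ** 2
    frame_pow = power.sum(axis=0)
    n_quiet = max(1, int(np.ceil(cfg.ss_quiet_fraction * frame_pow.size)))
    quiet = np.argsort(frame_pow)[:n_quiet]
    median_pow = float(np.median(frame_pow))
    if median_pow <= 0 or frame_pow[quiet].mean() > cfg.ss_quiet_gate * median_pow:
        return x  # no noise-only frames to learn from
    noise_psd = power[:, quiet].mean(axis=1, keepdims=True)
    clean_pow = np.maximum(power - cfg.ss_alpha * noise_psd, cfg.ss_beta * power)
    gain = np.sqrt(clean_pow / np.maximum(power, 1e-300))
    y = stft.istft(spec * gain, k1=x.size)
    return np.real(y[: x.size])


def denoise(rec: Recording, config: PreprocessConfig | None = None) -> Recording:
    """Band-pass filter (zero-phase) and spectrally denoise a recording.

    Returns a recording of identical length and rate. An all-zero input
    passes through as all zeros.
    """
    cfg = config or PreprocessConfig()
    rec.require_min_duration(MIN_DURATION_S)
    x = rec.samples
    if not np.any(x):
        return rec.with_samples(np.zeros_like(x))
    sos = bandpass_sos(cfg.band_low_hz, cfg.band_high_hz, rec.sample_rate, cfg.filter_order)
    y = sosfiltfilt(sos, x)
    y = _spectral_subtract(y, rec.sample_rate, cfg)
    return rec.with_samples(y)


def _rolling_robust_sigma(c: np.ndarray, window: int) -> np.ndarray:
    """Rolling MAD-based scale of wavelet coefficients (median |c| per
    half-overlapping block, interpolated), tracking the flow envelope."""
    n = c.size
    a = np.abs(c)
    if n <= window:
        return np.full(n, np.median(a) / 0.6745)
    centres, scales = [], []
    step = max(1, window // 2)
    for s in range(0, n - window + 1, step):
        seg = a[s : s + window]
        centres.append(s + window / 2)
        scales.append(np.median(seg) / 0.6745)
    return np.interp(np.arange(n), centres, scales)


def _wp_transient_pass(x: np.ndarray, fs: float, cfg: PreprocessConfig) -> np.ndarray:
    """One wavelet-packet thresholding pass: reconstruct the part of ``x``
    carried by coefficients beyond k_sigma rolling robust SDs of their
    node. The scale is local in time because the breath sound is
    flow-modulated — a global scale would flag entire loud phases."""
    wp = pywt.WaveletPacket(x, cfg.wavelet, mode="symmetric", maxlevel=cfg.depth)
    out = pywt.WaveletPacket(
        np.zeros_like(x), cfg.wavelet, mode="symmetric", maxlevel=cfg.depth
    )
    coeff_rate = fs / 2**cfg.depth
    window = max(8, int(round(cfg.sigma_window_s * coeff_rate)))
    any_kept = False
    for node in wp.get_level(cfg.depth, order="natural"):
        c = node.data
        sigma = _rolling_robust_sigma(c, window)
        if not np.any(sigma > 0):
            continue
        mask = np.abs(c) > cfg.k_sigma * sigma
        if mask.any():
            out[node.path] = np.where(mask, c, 0.0)
            any_kept = True
    if not any_kept:
        return np.zeros_like(x)
    y = out.reconstruct(update=False)
    return np.asarray(y)[: x.size]


def separate_stationary_nonstationary(
    rec: Recording, config: PreprocessConfig | None = None
) -> ComponentPair:
    """Split a (denoised) recording into breath sound and transients.

    Iterates hard thresholding in the wavelet-packet domain: each pass
    moves outlier coefficients to the non-stationary estimate and
    re-decomposes the residual — under a cycled circular time shift, so
    transients that straddle a coefficient boundary of the decimated
    packet grid in one pass are caught in another. Stops once every
    shift has been visited and a pass adds less than ``tol`` of the
    input energy, or after ``max_iter`` passes.
    """
    cfg = config or PreprocessConfig()
    x = np.asarray(rec.samples, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples")
    nonstationary = np.zeros_like(x)
    residual = x.copy()
    total_energy = float(np.sum(x**2))
    shifts = cfg.shifts or (0,)
    iterations = 0
    for i in range(cfg.max_iter):
        iterations += 1
        s = shifts[i % len(shifts)]
        t = np.roll(_wp_transient_pass(np.roll(residual, -s), rec.sample_rate, cfg), s)
        gain = float(np.sum(t**2))
        nonstationary += t
        residual -= t
        if gain == 0.0 and not np.any(nonstationary):
            break  # nothing transient at all (e.g. silence)
        if i >= len(shifts) - 1 and gain < cfg.tol * total_energy:
            break
    stationary = x - nonstationary  # exact additive reconstruction
    return ComponentPair(
        stationary=stationary,
        nonstationary=nonstationary,
        sample_rate=rec.sample_rate,
        iterations_used=iterations,
    )
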