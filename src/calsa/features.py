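"""Per-recording acoustic endpoints.

Three families of features are computed once the signal is separated and
the respiratory cycles are annotated:

* **E/I power ratios** — expiratory over inspiratory mean-square
  amplitude of the stationary component, band-passed to each of the four
  analysis bands (100–200, 200–400, 400–800, 800–1600 Hz), pooled over
  all annotated cycles. Ratios are scale-invariant by construction,
  which is what makes them comparable across recordings made by a
  stethoscope with automatic gain.
* **Crackle counts** — rectified-envelope peak picking on the
  non-stationary component against a rolling robust noise floor; counts
  are reported as mean events per cycle, for inspiration, expiration and
  the full cycle.
* **Wheeze segments** — spectrogram ridge tracking on the stationary
  component; tonal ridges lasting at least ``min_wheeze_s`` become
  segments characterized by power-weighted mean frequency, spectral
  quartiles of the normalized segment spectrum, and the occupation rate
  (percent of the total duration of the segment's phase type).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation
from scipy.signal import ShortTimeFFT, find_peaks, sosfiltfilt
from scipy.signal.windows import hann

from .io_audio import ChestLocation, CycleAnnotation
from .preprocess import ComponentPair, bandpass_sos
from .synthetic import ANALYSIS_BANDS

__all__ = [
    "FeatureConfig",
    "EIRatios",
    "CrackleEvent",
    "CrackleCounts",
    "WheezeSegment",
    "FeatureRow",
    "UndefinedRatioError",
    "ei_ratios",
    "detect_crackles",
    "crackle_counts",
    "detect_wheezes",
    "analyze_recording",
    "score_crackle_detection",
]


class UndefinedRatioError(ValueError):
    """Inspiratory band power is zero; the E/I ratio is undefined."""


@dataclass
class FeatureConfig:
    """Tunables of the feature extractors."""

    bands: tuple[tuple[float, float], ...] = ANALYSIS_BANDS
    # crackle detector
    crackle_k: float = 2.75  # base threshold = k x local breath-sound floor
    crackle_k_high: float = 3.75  # seed threshold confirming crackle presence
    crackle_min_seeds: int = 3  # seeds needed before base-threshold events count
    crackle_band: tuple[float, float] = (300.0, 1600.0)
    crackle_floor_window_s: float = 0.1
    crackle_min_separation_s: float = 0.010
    crackle_max_duration_s: float = 0.025
    crackle_env_smooth_s: float = 0.002
    # wheeze detector
    wheeze_nfft: int = 1024
    wheeze_overlap: float = 0.5
    wheeze_band: tuple[float, float] = (100.0, 1600.0)
    wheeze_seed_db: float = 7.0  # per-frame excess seeding/continuing a ridge
    wheeze_excess_db: float = 10.0  # mean ridge excess over the per-bin floor
    #: classical continuous-adventitious-sound criterion (> 250 ms); short
    #: tonal blips at the 100 ms scale are indistinguishable from noise
    #: ridges on the default spectrogram grid
    wheeze_min_duration_s: float = 0.25
    wheeze_max_bin_jump: int = 1


@dataclass(frozen=True)
class EIRatios:
    """Expiration-to-inspiration band power ratios (natural scale)."""

    r_100_200: float
    r_200_400: float
    r_400_800: float
    r_800_1600: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.r_100_200, self.r_200_400, self.r_400_800, self.r_800_1600)


@dataclass(frozen=True)
class CrackleEvent:
    """One detected discontinuous adventitious transient."""

    time: float
    phase: str  # "inspiration" | "expiration"
    peak_amplitude: float
    duration: float


@dataclass(frozen=True)
class CrackleCounts:
    """Mean crackle events per respiratory cycle."""

    full_cycle: float
    inspiration: float
    expiration: float


@dataclass(frozen=True)
class WheezeSegment:
    """One continuous tonal segment."""

    start: float
    end: float
    phase: str
    mean_frequency: float
    f25: float
    f50: float
    f75: float
    occupation_rate: float  # % of the total duration of this phase type

    def __post_init__(self) -> None:
        if not (self.f25 <= self.f50 <= self.f75):
            raise ValueError("spectral quartiles must be ordered")
        if not (0.0 < self.occupation_rate <= 100.0):
            raise ValueError("occupation rate must be in (0, 100]")


@dataclass(frozen=True)
class FeatureRow:
    """All endpoints of one recording."""

    subject_id: str
    assessment_id: str
    location: ChestLocation | None
    n_cycles: int
    ei: EIRatios | None
    crackles: CrackleCounts
    wheeze_segments: tuple[WheezeSegment, ...]
    quality_flags: frozenset[str] = frozenset()

    def to_dict(self) -> dict:
        d = {
            "subject_id": self.subject_id,
            "assessment_id": self.assessment_id,
            "location": self.location.value if self.location else "",
            "n_cycles": self.n_cycles,
            "ei_100_200": self.ei.r_100_200 if self.ei else np.nan,
            "ei_200_400": self.ei.r_200_400 if self.ei else np.nan,
            "ei_400_800": self.ei.r_400_800 if self.ei else np.nan,
            "ei_800_1600": self.ei.r_800_1600 if self.ei else np.nan,
            "crackles_full": self.crackles.full_cycle,
            "crackles_insp": self.crackles.inspiration,
            "crackles_exp": self.crackles.expiration,
            "n_wheezes": len(self.wheeze_segments),
            "wheeze_occupation_total": float(
                sum(w.occupation_rate for w in self.wheeze_segments)
            ),
            "quality_flags": ";".join(sorted(self.quality_flags)),
        }
        return d


def ei_ratios(
    comp: ComponentPair,
    ann: CycleAnnotation,
    bands: tuple[tuple[float, float], ...] = ANALYSIS_BANDS,
    noise_correction: bool = True,
) -> EIRatios:
    """Band-limited expiration/inspiration power ratios.

    For each band the stationary component is band-passed (zero-phase)
    and the ratio of mean squared amplitude over all expiratory samples
    to that over all inspiratory samples — pooled across cycles — is
    returned. With ``noise_correction`` (default), the band's residual
    noise power, estimated from the breathing pauses left uncovered by
    the annotation, is subtracted from both phase powers first: additive
    ambient noise otherwise biases the ratio toward 1, hitting the quiet
    high-frequency expirations hardest. Raises
    :class:`UndefinedRatioError` when an inspiratory band power is zero;
    a truly silent expiration gives the allowed lower edge 0.
    """
    ann.require_min_cycles(2)
    fs = comp.sample_rate
    n = comp.stationary.size
    insp = ann.phase_sample_mask(n, fs, "inspiration")
    exp = ann.phase_sample_mask(n, fs, "expiration")
    if not insp.any() or not exp.any():
        raise UndefinedRatioError("annotation covers no samples in one phase")
    pause = ~binary_dilation(insp | exp, np.ones(int(0.1 * fs), dtype=bool))
    use_pause = noise_correction and pause.sum() >= 0.5 * fs
    ratios = []
    for lo, hi in bands:
        if not (0 < lo < hi < fs / 2):
            raise ValueError(f"band ({lo}, {hi}) Hz outside (0, fs/2)")
        # order-8 band edges: adjacent analysis bands abut, so shallow
        # skirts would leak the louder neighbour into the ratio
        y = sosfiltfilt(bandpass_sos(lo, hi, fs, order=8), comp.stationary)
        p_i = float(np.mean(y[insp] ** 2))
        p_e = float(np.mean(y[exp] ** 2))
        if p_i == 0.0:
            raise UndefinedRatioError(f"zero inspiratory power in band {lo}-{hi} Hz")
        if use_pause:
            p_n = float(np.mean(y[pause] ** 2))
            # never correct away more than most of the inspiratory power
            p_i = max(p_i - p_n, 0.05 * p_i)
            p_e = max(p_e - p_n, 0.0)
        ratios.append(p_e / p_i)
    return EIRatios(*ratios)


def detect_crackles(
    comp: ComponentPair,
    ann: CycleAnnotation,
    config: FeatureConfig | None = None,
) -> list[CrackleEvent]:
    """Pick crackle peaks from the non-stationary component.

    Both components are restricted to the crackle band (default
    300–1600 Hz, spanning coarse and fine crackle spectra while
    rejecting the loud low-frequency breath floor). The rectified
    envelope of the non-stationary part (short moving RMS) is compared
    against ``crackle_k`` times the rolling noise floor given by the
    *stationary* component's local RMS — a crackle must stand out of the
    breath sound that would mask it, which is a meaningful reference
    even where the transient channel itself is silent. Peaks closer
    than the 10 ms dead time are merged, candidates whose envelope stays
    above half peak for longer than ``crackle_max_duration_s`` are
    rejected as non-crackle (friction/motion) transients, and events
    outside annotated phases are discarded. Detection is hysteretic at
    the event level: accepted events need ``crackle_min_seeds`` peaks
    above the stricter ``crackle_k_high`` confirmation threshold before
    base-threshold peaks are trusted (crackles occur in showers; a lone
    borderline transient in an otherwise clean recording is noise).
    """
    cfg = config or FeatureConfig()
    fs = comp.sample_rate
    if not np.any(comp.nonstationary):
        return []
    sos = bandpass_sos(cfg.crackle_band[0], cfg.crackle_band[1], fs, order=4)
    x = sosfiltfilt(sos, comp.nonstationary)
    breath = sosfiltfilt(sos, comp.stationary)
    k = max(1, int(round(cfg.crackle_env_smooth_s * fs)))
    env = np.sqrt(np.convolve(x**2, np.ones(k) / k, mode="same"))
    w = max(1, int(round(cfg.crackle_floor_window_s * fs)))
    floor = np.sqrt(np.convolve(breath**2, np.ones(w) / w, mode="same"))
    threshold = cfg.crackle_k * np.maximum(floor, 1e-12)
    distance = max(1, int(round(cfg.crackle_min_separation_s * fs)))
    peaks, props = find_peaks(env, height=threshold, distance=distance)
    candidates: list[tuple[CrackleEvent, float]] = []
    max_dur = int(round(cfg.crackle_max_duration_s * fs))
    for p in peaks:
        half = env[p] / 2.0
        a = p
        while a > 0 and env[a - 1] > half and p - a < 2 * max_dur:
            a -= 1
        b = p
        while b < env.size - 1 and env[b + 1] > half and b - p < 2 * max_dur:
            b += 1
        dur = (b - a) / fs
        if dur > cfg.crackle_max_duration_s:
            continue
        t = p / fs
        phase = ann.phase_of(t)
        if phase is None:
            continue
        ratio = float(env[p] / max(floor[p], 1e-12))
        candidates.append(
            (CrackleEvent(time=t, phase=phase, peak_amplitude=float(env[p]), duration=dur), ratio)
        )
    # event-level hysteresis: crackles come in showers, so base-threshold
    # events only count once enough high-confidence seeds establish that
    # the recording contains crackles; isolated borderline excursions of
    # clean breath noise are dropped
    n_seeds = sum(1 for _, r in candidates if r >= cfg.crackle_k_high)
    if n_seeds >= cfg.crackle_min_seeds:
        return [e for e, _ in candidates]
    return [e for e, r in candidates if r >= cfg.crackle_k_high]


def crackle_counts(events: list[CrackleEvent], ann: CycleAnnotation) -> CrackleCounts:
    """Mean events per cycle by phase; full cycle is the exact sum."""
    ann.require_min_cycles(2)
    n = ann.n_cycles
    insp = sum(1 for e in events if e.phase == "inspiration") / n
    exp = sum(1 for e in events if e.phase == "expiration") / n
    return CrackleCounts(full_cycle=insp + exp, inspiration=insp, expiration=exp)


def detect_wheezes(
    comp: ComponentPair,
    ann: CycleAnnotation,
    config: FeatureConfig | None = None,
) -> list[WheezeSegment]:
    """Track tonal ridges in the stationary component's spectrogram.

    A wheeze is a narrow spectral line riding on the broad breath-sound
    spectrum whose per-bin noise power is chi-squared distributed. Each
    spectrogram frame is first normalized by its total band power
    (removing the flow-envelope modulation); each bin is then judged by
    its excess over that bin's *temporal median* across the recording —
    a floor that tracks the breath spectral shape exactly and cannot be
    contaminated by a tone present in under half the frames. Bins
    exceeding ``wheeze_seed_db`` are linked across frames into ridges
    tolerating a ±``wheeze_max_bin_jump``-bin excursion; ridges
    persisting ``wheeze_min_duration_s`` with a mean excess of at least
    ``wheeze_excess_db`` become wheeze segments.
    """
    cfg = config or FeatureConfig()
    fs = comp.sample_rate
    x = comp.stationary
    if not np.any(x):
        return []
    nfft = cfg.wheeze_nfft
    hop = int(nfft * (1 - cfg.wheeze_overlap))
    stft = ShortTimeFFT(hann(nfft, sym=False), hop=hop, fs=fs)
    spec = np.abs(stft.stft(x)) ** 2
    freqs = stft.f
    times = stft.t(x.size)
    band = (freqs >= cfg.wheeze_band[0]) & (freqs <= cfg.wheeze_band[1])
    band_idx = np.where(band)[0]
    sub = spec[band_idx, :]
    # excess over the per-bin temporal median, judged both on the
    # frame-power-normalized spectrum (removes the flow-envelope
    # modulation, so loud inspirations are not flagged wholesale) and on
    # the raw spectrum (a quiet ambient-only frame normalizes to a flat
    # shape far above the breath-shaped floor, but carries no absolute
    # power excess); a bin is tonal only if it stands out in both
    def _excess(tonal_mask: np.ndarray | None) -> np.ndarray:
        masked = np.where(tonal_mask, np.nan, sub) if tonal_mask is not None else sub
        frame_power = np.nansum(masked, axis=0, keepdims=True)
        frame_power = np.maximum(frame_power, 1e-300)
        norm = sub / frame_power
        norm_masked = np.where(tonal_mask, np.nan, norm) if tonal_mask is not None else norm
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
            floor_norm = np.nanmedian(norm_masked, axis=1, keepdims=True)
            floor_raw = np.nanmedian(masked, axis=1, keepdims=True)
        floor_norm = np.maximum(np.nan_to_num(floor_norm), 1e-300)
        floor_raw = np.maximum(np.nan_to_num(floor_raw), 1e-300)
        return np.minimum(
            10.0 * np.log10(np.maximum(norm, 1e-300) / floor_norm),
            10.0 * np.log10(np.maximum(sub, 1e-300) / floor_raw),
        )

    frame_dt = hop / fs
    min_frames = max(2, int(np.ceil(cfg.wheeze_min_duration_s / frame_dt)))

    def _find_ridges(excess_db: np.ndarray) -> list[list[tuple[int, int]]]:
        frame_peaks: list[list[int]] = []
        for j in range(sub.shape[1]):
            pk, _ = find_peaks(excess_db[:, j], height=cfg.wheeze_seed_db)
            frame_peaks.append(list(pk))
        ridges: list[list[tuple[int, int]]] = []  # list of (frame, bin)
        open_ridges: list[list[tuple[int, int]]] = []
        for j, peaks in enumerate(frame_peaks):
            used = set()
            still_open = []
            for ridge in open_ridges:
                last_bin = ridge[-1][1]
                match = None
                for p in peaks:
                    if p in used:
                        continue
                    if abs(p - last_bin) <= cfg.wheeze_max_bin_jump:
                        match = p
                        break
                if match is not None:
                    ridge.append((j, match))
                    used.add(match)
                    still_open.append(ridge)
                else:
                    ridges.append(ridge)
            open_ridges = still_open
            for p in peaks:
                if p not in used:
                    open_ridges.append([(j, p)])
        ridges.extend(open_ridges)
        return [r for r in ridges if len(r) >= min_frames]

    # two passes: a sustained tone contaminates the frame power and the
    # temporal medians, so the time-frequency extent of first-pass
    # ridges (persistent lines only — transient excursions must stay in
    # the floor statistics) is excluded when the floors are re-estimated
    excess_db = _excess(None)
    ridges = _find_ridges(excess_db)
    confirmed = [
        r for r in ridges
        if np.mean([excess_db[b, j] for j, b in r]) >= cfg.wheeze_excess_db
    ]
    if confirmed:
        mask = np.zeros(sub.shape, dtype=bool)
        for ridge in confirmed:
            for j, b in ridge:
                mask[max(0, b - 2) : b + 3, j] = True
        excess_db = _excess(mask)
        ridges = _find_ridges(excess_db)

    segments: list[WheezeSegment] = []
    for ridge in ridges:
        if np.mean([excess_db[b, j] for j, b in ridge]) < cfg.wheeze_excess_db:
            continue
        j0, j1 = ridge[0][0], ridge[-1][0]
        start = float(times[j0])
        end = float(times[j1]) + frame_dt
        mid = 0.5 * (start + end)
        phase = ann.phase_of(mid)
        if phase is None:
            continue
        ridge_f = np.array([freqs[band_idx[b]] for _, b in ridge])
        ridge_p = np.array([sub[b, j] for j, b in ridge])
        mean_f = float(np.sum(ridge_f * ridge_p) / np.sum(ridge_p))
        # quartiles of the normalized power spectrum of the segment's slice
        slice_pow = sub[:, j0 : j1 + 1].sum(axis=1)
        cum = np.cumsum(slice_pow)
        cum = cum / cum[-1]
        fsub = freqs[band_idx]
        f25, f50, f75 = (float(np.interp(q, cum, fsub)) for q in (0.25, 0.50, 0.75))
        total_phase = ann.total_phase_duration(phase)
        if total_phase <= 0:
            continue
        occupation = min(100.0, 100.0 * (end - start) / total_phase)
        segments.append(
            WheezeSegment(
                start=start,
                end=end,
                phase=phase,
                mean_frequency=mean_f,
                f25=f25,
                f50=f50,
                f75=f75,
                occupation_rate=occupation,
            )
        )
    return segments


def score_crackle_detection(
    detected_times: np.ndarray, true_times: np.ndarray, tolerance: float = 0.010
) -> float:
    """Event-level F-score: greedy in-order one-to-one matching of
    detected to true crackle times within ``tolerance`` seconds."""
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    d = np.sort(np.asarray(detected_times, dtype=float))
    t = np.sort(np.asarray(true_times, dtype=float))
    if d.size == 0 and t.size == 0:
        return 1.0
    if d.size == 0 or t.size == 0:
        return 0.0
    matches = 0
    i = j = 0
    while i < d.size and j < t.size:
        diff = d[i] - t[j]
        if abs(diff) <= tolerance:
            matches += 1
            i += 1
            j += 1
        elif diff < 0:
            i += 1
        else:
            j += 1
    precision = matches / d.size
    recall = matches / t.size
    return 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)


def _quality_flags(samples: np.ndarray) -> frozenset[str]:
    flags = set()
    clip_frac = float(np.mean(np.abs(samples) > 0.985))
    if clip_frac > 0.001:
        flags.add("clipping")
    return frozenset(flags)


def analyze_recording(
    rec,
    annotation: CycleAnnotation | None = None,
    pre_config=None,
    seg_config=None,
    feat_config: FeatureConfig | None = None,
) -> FeatureRow:
    """Full per-recording pipeline: denoise, separate, segment (unless a
    manual annotation is given), then compute all endpoints."""
    from .preprocess import denoise, separate_stationary_nonstationary
    from .segmentation import extract_cycles

    flags = set(_quality_flags(rec.samples))
    den = denoise(rec, pre_config)
    comp = separate_stationary_nonstationary(den, pre_config)
    if annotation is None:
        annotation = extract_cycles(comp, seg_config)
    annotation.require_min_cycles(2)
    try:
        ei = ei_ratios(comp, annotation)
    except UndefinedRatioError:
        ei = None
        flags.add("undefined_ei")
    events = detect_crackles(comp, annotation, feat_config)
    counts = crackle_counts(events, annotation)
    wheezes = detect_wheezes(comp, annotation, feat_config)
    return FeatureRow(
        subject_id=rec.subject_id,
        assessment_id=rec.assessment_id,
        location=rec.location,
        n_cycles=annotation.n_cycles,
        ei=ei,
        crackles=counts,
        wheeze_segments=tuple(wheezes),
        quality_flags=frozenset(flags),
    )
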