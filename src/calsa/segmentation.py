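"""Respiratory-cycle extraction from the breath-sound component.

The detector works on a band-limited (default 150–800 Hz) log-power
envelope of the stationary component: frames of 50 ms every 25 ms,
smoothed with a short moving average. Active (sound-producing) segments
are found by dual-threshold hysteresis around an Otsu split of the frame
powers, then labelled inspiration/expiration by alternation. The global
phase parity — which alternation state is inspiration — is set by the
power-asymmetry prior that chest-wall inspiratory sound is markedly
louder than expiratory sound; the parity is a single bit and, when a
recording violates the prior (e.g. dominant bronchial breathing), a
manual annotation overrides the automatic one wholesale, mirroring a
semi-automated clinical workflow.

Within a cycle the inspiration/expiration boundary is refined to the
envelope minimum in the gap between the two active segments; phase ends
are extended down the envelope flanks toward the local noise floor so
that boundary timings track the true flow envelope rather than the
detection threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, sosfiltfilt

from .io_audio import Cycle, CycleAnnotation
from .preprocess import ComponentPair, bandpass_sos

__all__ = [
    "SegmentationConfig",
    "EnvelopeTrack",
    "DegenerateRecordingError",
    "compute_envelope",
    "extract_cycles",
    "apply_correction",
    "score_cycle_detection",
]


class DegenerateRecordingError(RuntimeError):
    """Fewer than two respiratory cycles could be detected; the recording
    needs manual annotation."""


@dataclass
class SegmentationConfig:
    """Parameters of the cycle detector."""

    frame_len_s: float = 0.050
    frame_step_s: float = 0.025
    env_band: tuple[float, float] = (150.0, 800.0)
    smooth_frames: int = 5
    #: hysteresis: seed threshold = Otsu split of frame log-powers,
    #: capped at floor + high_margin_db so quiet expirations still seed;
    #: low threshold = floor + low_margin_db (dB above the noise floor)
    low_margin_db: float = 2.0
    high_margin_db: float = 8.0
    #: an active region is split into phases at internal envelope minima
    #: with at least this prominence (dB); inspiration and expiration
    #: merge into one region whenever the ambient floor sits below the
    #: inter-phase dip
    split_prominence_db: float = 4.0
    min_phase_s: float = 0.2
    max_phase_s: float = 6.0
    min_gap_s: float = 0.0
    match_tolerance_s: float = 0.2


@dataclass(frozen=True)
class EnvelopeTrack:
    """Uniform log-power envelope (dB, relative) on a frame grid."""

    times: np.ndarray
    values: np.ndarray
    frame_step: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("envelope contains non-finite values")


def compute_envelope(comp: ComponentPair, cfg: SegmentationConfig) -> EnvelopeTrack:
    """Band-limited, smoothed log-power envelope of the stationary part."""
    fs = comp.sample_rate
    sos = bandpass_sos(cfg.env_band[0], cfg.env_band[1], fs, order=4)
    x = sosfiltfilt(sos, comp.stationary)
    frame = int(round(cfg.frame_len_s * fs))
    step = int(round(cfg.frame_step_s * fs))
    n_frames = max(1, 1 + (x.size - frame) // step)
    idx = np.arange(frame)[None, :] + step * np.arange(n_frames)[:, None]
    power = np.mean(x[idx] ** 2, axis=1)
    floor = max(np.max(power) * 1e-10, 1e-300)
    db = 10.0 * np.log10(np.maximum(power, floor))
    if cfg.smooth_frames > 1:
        k = np.ones(cfg.smooth_frames) / cfg.smooth_frames
        db = np.convolve(db, k, mode="same")
    times = (np.arange(n_frames) * step + frame / 2) / fs
    return EnvelopeTrack(times=times, values=db, frame_step=cfg.frame_step_s)


def _otsu_threshold(values: np.ndarray, n_bins: int = 128) -> float:
    """Threshold maximizing between-class variance of a 1-D sample."""
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi - lo < 1e-9:
        return hi
    hist, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    mids = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    total = w.sum()
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * mids)
    mean_all = cum_m[-1] / total
    with np.errstate(divide="ignore", invalid="ignore"):
        w0 = cum_w / total
        w1 = 1.0 - w0
        mu0 = cum_m / cum_w
        mu1 = (cum_m[-1] - cum_m) / (total - cum_w)
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -1.0
    return float(mids[int(np.argmax(between))])


def _active_segments(env: EnvelopeTrack, cfg: SegmentationConfig) -> list[tuple[int, int]]:
    """Hysteresis segmentation with valley splitting.

    Active regions are seeded where the envelope exceeds the Otsu split
    of frame powers — capped at ``floor + high_margin_db`` so that quiet
    expirations still seed when the split lands between the two phase
    levels — and extended down to ``floor + low_margin_db``. When the
    ambient floor is low, an inspiration and its expiration merge into a
    single region; each region is therefore split at internal envelope
    minima of at least ``split_prominence_db`` prominence, which is
    where the flow envelope passes through zero between phases.
    """
    v = env.values
    otsu = _otsu_threshold(v)
    floor = float(np.median(v[v < otsu])) if np.any(v < otsu) else float(np.min(v))
    t_high = min(otsu, floor + cfg.high_margin_db)
    t_low = min(floor + cfg.low_margin_db, t_high)
    above_low = v > t_low
    regions: list[tuple[int, int]] = []
    i = 0
    n = v.size
    while i < n:
        if above_low[i]:
            j = i
            while j < n and above_low[j]:
                j += 1
            if np.any(v[i:j] > t_high):
                regions.append((i, j))
            i = j
        else:
            i += 1
    segments: list[tuple[int, int]] = []
    for a, b in regions:
        valleys, _ = find_peaks(-v[a:b], prominence=cfg.split_prominence_db)
        cuts = [a] + [a + k for k in valleys] + [b]
        segments.extend((c0, c1) for c0, c1 in zip(cuts[:-1], cuts[1:]))
    return segments


def _refine_boundary(env: EnvelopeTrack, a_end: int, b_start: int) -> float:
    """Boundary time between two adjacent segments: envelope minimum in
    the inter-segment gap (midpoint when the gap is empty)."""
    if b_start <= a_end:
        return float(env.times[a_end])
    gap = env.values[a_end:b_start]
    k = int(np.argmin(gap))
    return float(env.times[a_end + k])


def extract_cycles(
    comp: ComponentPair, config: SegmentationConfig | None = None
) -> CycleAnnotation:
    """Detect respiratory cycles in the stationary component.

    Raises
    ------
    DegenerateRecordingError
        If fewer than two plausible cycles are found (silence, a single
        breath, or an envelope with no bimodal structure), prompting
        manual annotation.
    """
    cfg = config or SegmentationConfig()
    if comp.stationary.size / comp.sample_rate < 10.0:
        raise ValueError("recording shorter than the 10 s analysis minimum")
    if not np.any(comp.stationary):
        raise DegenerateRecordingError("silent recording: no cycles detectable")
    env = compute_envelope(comp, cfg)
    segments = _active_segments(env, cfg)
    # drop segments too short to be a phase
    min_frames = max(1, int(round(cfg.min_phase_s / cfg.frame_step_s)) - 1)
    segments = [(a, b) for a, b in segments if b - a >= min_frames]
    if len(segments) < 4:
        raise DegenerateRecordingError(
            f"only {len(segments)} active segments found; need >= 4 (two cycles)"
        )

    # phase parity: the alternation class with the higher peak power is
    # inspiration (chest-wall inspiratory sound is louder)
    peaks = np.array([np.max(env.values[a:b]) for a, b in segments])
    even_louder = np.median(peaks[0::2]) >= np.median(peaks[1::2])
    first_insp = 0 if even_louder else 1

    cycles: list[Cycle] = []
    i = first_insp
    step = cfg.frame_step_s
    while i + 1 < len(segments):
        (ia, ib), (ea, eb) = segments[i], segments[i + 1]
        insp_start = float(env.times[ia]) - step
        insp_end = _refine_boundary(env, ib, ea)
        exp_end = float(env.times[eb - 1]) + step
        di, de = insp_end - insp_start, exp_end - insp_end
        if (
            cfg.min_phase_s <= di <= cfg.max_phase_s
            and cfg.min_phase_s <= de <= cfg.max_phase_s
        ):
            if not cycles or insp_start >= cycles[-1].exp_end:
                cycles.append(Cycle(max(0.0, insp_start), insp_end, exp_end))
        i += 2  # trailing unpaired segment (incomplete cycle) is discarded

    if len(cycles) < 2:
        raise DegenerateRecordingError(
            f"{len(cycles)} valid cycle(s) detected; at least 2 required"
        )
    return CycleAnnotation(tuple(cycles), source="automatic")


def apply_correction(auto: CycleAnnotation, manual: CycleAnnotation) -> CycleAnnotation:
    """Replace an automatic annotation wholesale with a manual one."""
    manual.require_min_cycles(2)
    return CycleAnnotation(manual.cycles, source="corrected")


def score_cycle_detection(
    pred: CycleAnnotation, truth: CycleAnnotation, tolerance: float = 0.2
) -> float:
    """Boundary-level F-score of a predicted annotation against truth.

    Each annotation contributes three boundaries per cycle (inspiration
    start, inspiration/expiration transition, expiration end). Predicted
    and true boundaries are matched greedily in temporal order, one-to-
    one, within ``tolerance`` seconds; F = 2PR/(P+R), and 0 when no
    boundary matches.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    p = pred.boundaries()
    t = truth.boundaries()
    if p.size == 0 and t.size == 0:
        return 1.0
    if p.size == 0 or t.size == 0:
        return 0.0
    matches = 0
    i = j = 0
    while i < p.size and j < t.size:
        d = p[i] - t[j]
        if abs(d) <= tolerance:
            matches += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    precision = matches / p.size
    recall = matches / t.size
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
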