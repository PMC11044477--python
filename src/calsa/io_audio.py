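"""Audio and annotation I/O.

Recordings are single-channel auscultation signals captured at one of six
standard chest locations (two anterior, two lateral, two posterior).
Internally everything runs at a fixed working rate of 8 kHz — comfortably
above twice the 1600 Hz upper analysis band — with amplitudes peak-
normalized to [-1, 1]: the stethoscope's automatic gain makes absolute
sound level meaningless, so only ratios are ever interpreted.

Respiratory-cycle annotations are ordered (inspiration_start,
inspiration_end, expiration_end) triples in seconds from recording start;
each phase interval is half-open and the expiration of a cycle starts
exactly where its inspiration ends.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "DEFAULT_SAMPLE_RATE",
    "MIN_DURATION_S",
    "ChestLocation",
    "Recording",
    "Cycle",
    "CycleAnnotation",
    "read_recording",
    "write_recording",
    "read_annotation",
    "write_annotation",
]

#: Working sample rate (Hz). 2 x 1600 Hz top band = 3200 Hz is the floor;
#: 8 kHz keeps FFT sizes cheap while leaving generous transition bands.
DEFAULT_SAMPLE_RATE = 8000

#: Minimum recording duration (s) accepted for feature extraction.
MIN_DURATION_S = 10.0


class ChestLocation(str, Enum):
    """Standard auscultation sites used for regional analysis."""

    ANTERIOR_LEFT = "anterior_left"
    ANTERIOR_RIGHT = "anterior_right"
    LATERAL_LEFT = "lateral_left"
    LATERAL_RIGHT = "lateral_right"
    POSTERIOR_LEFT = "posterior_left"
    POSTERIOR_RIGHT = "posterior_right"


@dataclass(frozen=True)
class Recording:
    """A mono auscultation signal with its provenance.

    Parameters
    ----------
    samples : ndarray of float
        Dimensionless amplitudes, peak-normalized to at most 1 in
        magnitude.
    sample_rate : int
        Sampling rate in Hz; must exceed 3200 Hz so the 800–1600 Hz band
        is below Nyquist.
    subject_id, assessment_id : str
        Opaque identifiers carried through to the feature table.
    location : ChestLocation or None
        Chest site of the recording, if known.
    """

    samples: np.ndarray
    sample_rate: int
    subject_id: str = ""
    assessment_id: str = ""
    location: ChestLocation | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("Recording.samples must be one-dimensional (mono)")
        if samples.size == 0:
            raise ValueError("Recording contains no samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("Recording contains non-finite samples")
        if self.sample_rate <= 3200:
            raise ValueError(
                f"sample_rate must exceed 3200 Hz (got {self.sample_rate}); "
                "the 800-1600 Hz band would alias"
            )
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.sample_rate

    def with_samples(self, samples: np.ndarray) -> "Recording":
        """Copy of this recording with new samples at the same rate."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64))

    def require_min_duration(self, min_s: float = MIN_DURATION_S) -> None:
        if self.duration < min_s:
            raise ValueError(
                f"recording of {self.duration:.2f} s is shorter than the "
                f"{min_s:.0f} s minimum required for analysis"
            )


@dataclass(frozen=True)
class Cycle:
    """One respiratory cycle: inspiration [start, insp_end), expiration
    [insp_end, exp_end), times in seconds from recording start."""

    insp_start: float
    insp_end: float
    exp_end: float

    def __post_init__(self) -> None:
        if not (self.insp_start < self.insp_end < self.exp_end):
            raise ValueError(
                f"cycle times must increase: "
                f"({self.insp_start}, {self.insp_end}, {self.exp_end})"
            )

    @property
    def insp_duration(self) -> float:
        return self.insp_end - self.insp_start

    @property
    def exp_duration(self) -> float:
        return self.exp_end - self.insp_end

    def phase_of(self, t: float) -> str | None:
        """'inspiration', 'expiration' or None for a time in seconds."""
        if self.insp_start <= t < self.insp_end:
            return "inspiration"
        if self.insp_end <= t < self.exp_end:
            return "expiration"
        return None


@dataclass(frozen=True)
class CycleAnnotation:
    """Ordered, non-overlapping respiratory cycles for one recording."""

    cycles: tuple[Cycle, ...]
    source: str = "automatic"  # "automatic" | "corrected"

    def __post_init__(self) -> None:
        cycles = tuple(self.cycles)
        if self.source not in ("automatic", "corrected"):
            raise ValueError(f"unknown annotation source {self.source!r}")
        for i in range(1, len(cycles)):
            if cycles[i].insp_start < cycles[i - 1].exp_end:
                raise ValueError(
                    f"cycle {i} starts at {cycles[i].insp_start:.3f} s, before "
                    f"cycle {i - 1} ends at {cycles[i - 1].exp_end:.3f} s"
                )
        object.__setattr__(self, "cycles", cycles)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def require_min_cycles(self, n: int = 2) -> None:
        if self.n_cycles < n:
            raise ValueError(
                f"annotation has {self.n_cycles} cycle(s); at least {n} are "
                "required for feature extraction"
            )

    def boundaries(self) -> np.ndarray:
        """All phase boundaries (insp_start, insp_end, exp_end per cycle),
        in order."""
        out = []
        for c in self.cycles:
            out.extend((c.insp_start, c.insp_end, c.exp_end))
        return np.asarray(out)

    def phase_of(self, t: float) -> str | None:
        for c in self.cycles:
            p = c.phase_of(t)
            if p is not None:
                return p
        return None

    def total_phase_duration(self, phase: str) -> float:
        """Summed duration (s) of all inspirations or expirations."""
        if phase == "inspiration":
            return float(sum(c.insp_duration for c in self.cycles))
        if phase == "expiration":
            return float(sum(c.exp_duration for c in self.cycles))
        raise ValueError(f"unknown phase {phase!r}")

    def phase_sample_mask(self, n_samples: int, sample_rate: float, phase: str) -> np.ndarray:
        """Boolean mask of samples falling inside the given phase."""
        mask = np.zeros(n_samples, dtype=bool)
        for c in self.cycles:
            if phase == "inspiration":
                lo, hi = c.insp_start, c.insp_end
            else:
                lo, hi = c.insp_end, c.exp_end
            i0 = max(0, int(math.ceil(lo * sample_rate)))
            i1 = min(n_samples, int(math.ceil(hi * sample_rate)))
            mask[i0:i1] = True
        return mask


def read_recording(
    path: str | Path,
    target_rate: int = DEFAULT_SAMPLE_RATE,
    *,
    subject_id: str = "",
    assessment_id: str = "",
    location: ChestLocation | str | None = None,
) -> Recording:
    """Read a WAV file into a mono, resampled, peak-normalized Recording.

    Stereo input is collapsed by channel mean; integer PCM is scaled to
    [-1, 1]; the signal is polyphase-resampled to ``target_rate`` and
    finally rescaled to unit peak.
    """
    path = Path(path)
    rate, data = wavfile.read(path)  # raises on unreadable files
    data = np.asarray(data)
    if data.size == 0:
        raise ValueError(f"{path}: zero-length audio")
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    if rate != target_rate:
        frac = Fraction(target_rate, int(rate)).limit_denominator(1000)
        data = resample_poly(data, frac.numerator, frac.denominator)
    peak = np.max(np.abs(data))
    if peak > 0:
        data = data / peak
    if isinstance(location, str):
        location = ChestLocation(location)
    return Recording(
        samples=data,
        sample_rate=target_rate,
        subject_id=subject_id,
        assessment_id=assessment_id,
        location=location,
    )


def write_recording(path: str | Path, rec: Recording) -> None:
    """Write a Recording as 16-bit PCM RIFF WAV."""
    peak = np.max(np.abs(rec.samples))
    scale = 0.999 / peak if peak > 0 else 1.0
    pcm = np.round(rec.samples * scale * 32767.0).astype(np.int16)
    wavfile.write(Path(path), rec.sample_rate, pcm)


def _annotation_to_dict(ann: CycleAnnotation, recording: str) -> dict:
    return {
        "recording": recording,
        "source": ann.source,
        "cycles": [
            {
                "insp_start": round(c.insp_start, 3),
                "insp_end": round(c.insp_end, 3),
                "exp_end": round(c.exp_end, 3),
            }
            for c in ann.cycles
        ],
    }


def write_annotation(path: str | Path, ann: CycleAnnotation, recording: str = "") -> None:
    """Serialize an annotation as JSON (times at millisecond precision)."""
    Path(path).write_text(json.dumps(_annotation_to_dict(ann, recording), indent=1))


def read_annotation(path: str | Path, *, source: str | None = None) -> CycleAnnotation:
    """Read and validate a cycle-annotation JSON file.

    Externally supplied files default to ``source="corrected"`` (a file on
    disk is, by the workflow's convention, an annotation a human has had
    the chance to edit) unless the document or the caller says otherwise.
    """
    doc = json.loads(Path(path).read_text())
    cycles = []
    for i, c in enumerate(doc.get("cycles", [])):
        try:
            cycles.append(Cycle(float(c["insp_start"]), float(c["insp_end"]), float(c["exp_end"])))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}: invalid cycle at index {i}: {exc}") from exc
    try:
        ann = CycleAnnotation(tuple(cycles), source=source or doc.get("source", "corrected"))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    return ann
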