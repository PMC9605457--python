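"""Beat segmentation: foot detection, interval screening, heart-rate statistics.

A "foot" is the pre-upstroke onset of one pulse beat. Feet are located with
the intersecting-tangent construction (horizontal line through the local
minimum intersected with the tangent at the steepest upslope), which is
robust to baseline drift; a plain minimum-picking fallback is available via
``method="min"``. Foot-to-foot intervals outside a physiological range, or
deviating more than 30% from the median interval, are rejected as artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .errors import InsufficientBeatsError, InvalidParameterError

# physiological beat-period range (s): 40-180 bpm
MIN_INTERVAL_S = 0.33
MAX_INTERVAL_S = 1.5
#: maximal relative deviation from the median interval before rejection
MEDIAN_DEVIATION_FRAC = 0.30


@dataclass
class SimulationTruth:
    """Ground truth carried by simulated recordings (exact segmentation)."""

    foot_indices: np.ndarray          # beat-start samples, plus the final boundary
    rr_s: np.ndarray                  # per-beat period (s), quantised to the grid
    amplitudes: np.ndarray            # (n_beats, 10) jittered harmonic amplitudes
    phases_deg: np.ndarray            # (n_beats, 10) jittered harmonic phases


@dataclass
class PulseRecording:
    """One sampled single-channel pulse waveform."""

    samples: np.ndarray
    fs: float
    channel: str = "BPW"
    subject_id: str = ""
    session: str = "M0"
    truth: Optional[SimulationTruth] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def validate(self) -> None:
        if self.fs <= 0:
            raise InvalidParameterError(f"fs must be positive, got {self.fs}")
        if len(self.samples) < 3 * self.fs:
            raise InvalidParameterError(
                f"recording too short: {self.duration_s:.2f} s < 3 s"
            )
        if not np.all(np.isfinite(self.samples)):
            raise InvalidParameterError("recording contains non-finite samples")
        if self.channel not in ("BPW", "PPG"):
            raise InvalidParameterError(f"unknown channel {self.channel!r}")


@dataclass
class BeatSet:
    """Detected feet and the valid per-beat segments they induce.

    ``foot_indices`` keeps every detected foot; ``beats``/``intervals_s``
    keep only the segments whose interval passed the artifact screen, so
    the two agree in length only when nothing was rejected.
    """

    foot_indices: np.ndarray
    intervals_s: np.ndarray
    beats: list[np.ndarray]

    @property
    def n_beats(self) -> int:
        return len(self.beats)


def _conditioned(x: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 0.5-40 Hz band-pass used for detection only."""
    nyq = fs / 2.0
    high = min(40.0, 0.9 * nyq)
    sos = sps.butter(2, [0.5 / nyq, high / nyq], btype="band", output="sos")
    return sps.sosfiltfilt(sos, x)


def _tangent_foot(x: np.ndarray, grad: np.ndarray, lo: int, peak: int) -> Optional[int]:
    """Intersecting-tangent foot in the window (lo, peak]."""
    window = x[lo : peak + 1]
    if window.size < 3:
        return None
    i_min = lo + int(np.argmin(window))
    if i_min >= peak:
        return None
    i_up = i_min + int(np.argmax(grad[i_min : peak + 1]))
    slope = grad[i_up]
    if slope <= 0:
        return i_min
    foot = i_up - (x[i_up] - x[i_min]) / slope
    return int(round(max(foot, lo)))


def detect_feet(rec: PulseRecording, method: str = "tangent") -> BeatSet:
    """Locate beat onsets and screen the induced intervals.

    Parameters
    ----------
    rec : PulseRecording
    method : {"tangent", "min"}
        Foot definition: intersecting tangent (default) or the plain
        local minimum preceding each systolic peak.

    Raises
    ------
    InsufficientBeatsError
        If fewer than 3 valid beats survive screening.
    """
    rec.validate()
    if method not in ("tangent", "min"):
        raise InvalidParameterError(f"unknown foot method {method!r}")
    x = _conditioned(rec.samples, rec.fs)
    grad = np.gradient(x)

    distance = max(2, int(round(MIN_INTERVAL_S * rec.fs)))
    spread = np.percentile(x, 95) - np.percentile(x, 5)
    if spread <= 0:
        raise InsufficientBeatsError("flat signal: no beats detected")
    peaks, _ = sps.find_peaks(x, distance=distance, prominence=0.25 * spread)
    if len(peaks) < 3:
        raise InsufficientBeatsError(f"only {len(peaks)} systolic peaks found")

    max_lead = int(round(MAX_INTERVAL_S * rec.fs))
    feet: list[int] = []
    for j, peak in enumerate(peaks):
        lo = int(peaks[j - 1]) if j > 0 else max(0, int(peak) - max_lead)
        if method == "min":
            window = x[lo : peak + 1]
            if window.size < 3:
                continue
            foot = lo + int(np.argmin(window))
            if foot >= peak:
                continue
        else:
            foot = _tangent_foot(x, grad, lo, int(peak))
            if foot is None:
                continue
        if not feet or foot > feet[-1]:
            feet.append(foot)

    feet_arr = np.asarray(feet, dtype=int)
    if len(feet_arr) < 4:
        raise InsufficientBeatsError(f"only {len(feet_arr)} feet detected")

    intervals = np.diff(feet_arr) / rec.fs
    in_range = (intervals >= MIN_INTERVAL_S) & (intervals <= MAX_INTERVAL_S)
    if not in_range.any():
        raise InsufficientBeatsError("no intervals in physiological range")
    median = float(np.median(intervals[in_range]))
    valid = in_range & (np.abs(intervals - median) <= MEDIAN_DEVIATION_FRAC * median)
    if valid.sum() < 3:
        raise InsufficientBeatsError(f"only {int(valid.sum())} valid beats")

    beats = [
        rec.samples[feet_arr[i] : feet_arr[i + 1]]
        for i in np.flatnonzero(valid)
    ]
    return BeatSet(
        foot_indices=feet_arr,
        intervals_s=intervals[valid],
        beats=beats,
    )


def beats_from_feet(rec: PulseRecording, foot_indices: np.ndarray) -> BeatSet:
    """Build a BeatSet from externally supplied feet (e.g. simulator truth)."""
    feet = np.asarray(foot_indices, dtype=int)
    if feet.ndim != 1 or len(feet) < 2 or np.any(np.diff(feet) <= 0):
        raise InvalidParameterError("foot_indices must be strictly increasing")
    intervals = np.diff(feet) / rec.fs
    beats = [rec.samples[feet[i] : feet[i + 1]] for i in range(len(feet) - 1)]
    return BeatSet(foot_indices=feet, intervals_s=intervals, beats=beats)


def heart_rate_stats(bs: BeatSet) -> tuple[float, float]:
    """Return (HR in beats/min, HR_CV in %) from foot-to-foot intervals.

    HR = 60 / mean(interval); HR_CV = 100 * sample SD / mean (n-1 denominator).
    """
    iv = np.asarray(bs.intervals_s, dtype=float)
    if len(iv) < 3:
        raise InsufficientBeatsError(f"need >= 3 intervals, got {len(iv)}")
    mean = float(iv.mean())
    hr = 60.0 / mean
    hr_cv = 100.0 * float(iv.std(ddof=1)) / mean
    return hr, hr_cv
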