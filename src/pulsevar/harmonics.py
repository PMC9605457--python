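"""Per-beat harmonic decomposition and the 40 beat-wise variability indices.

Each beat segment is treated as exactly one period of its own fundamental:
harmonic coefficients are DFT bins of the segment (no zero-padding, no fixed
frequency grid), so beats of different lengths stay aligned harmonic by
harmonic. For one recording the per-beat values are aggregated into four
index families over harmonics n = 1..10:

* ``C_n``   — mean amplitude proportion (%),
* ``CV_n``  — coefficient of variation of the per-beat proportions (%),
* ``P_n``   — circular mean phase (degrees, cosine convention, beat foot
  as time reference),
* ``P_n_SD`` — circular standard deviation of the per-beat phases (degrees),

plus HR and HR_CV from the beat periods: 42 values per recording, 40 of
which are the harmonic indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sst

from .errors import InsufficientBeatsError, InvalidBeatError, InvalidParameterError
from .simulate import N_HARMONICS, wrap_degrees

MIN_BEAT_SAMPLES = 40
INDEX_FAMILIES = ("C", "CV", "P", "P_SD")


@dataclass(frozen=True)
class BeatHarmonics:
    """Harmonic content of one beat.

    ``amplitudes[0]`` is the DC level; ``amplitudes[n]`` and
    ``phases_deg[n-1]`` describe harmonic n for n = 1..10.
    """

    amplitudes: np.ndarray  # shape (11,)
    phases_deg: np.ndarray  # shape (10,), wrapped to (-180, 180]
    period_s: float


@dataclass(frozen=True)
class HarmonicProfile:
    """Aggregated indices for one recording."""

    C: np.ndarray
    CV: np.ndarray
    P: np.ndarray
    P_SD: np.ndarray
    HR: float
    HR_CV: float
    n_beats: int

    def value(self, name: str) -> float:
        """Look up an index by its flat name, e.g. ``C2``, ``P3_SD``, ``HR_CV``."""
        if name == "HR":
            return self.HR
        if name == "HR_CV":
            return self.HR_CV
        for family in ("CV", "C"):  # CV before C: "CV2" starts with "C"
            if name.startswith(family) and name[len(family):].isdigit():
                n = int(name[len(family):])
                if 1 <= n <= N_HARMONICS:
                    return float(getattr(self, family)[n - 1])
        if name.startswith("P"):
            body = name[1:]
            if body.endswith("_SD") and body[:-3].isdigit():
                n = int(body[:-3])
                if 1 <= n <= N_HARMONICS:
                    return float(self.P_SD[n - 1])
            if body.isdigit() and 1 <= int(body) <= N_HARMONICS:
                return float(self.P[int(body) - 1])
        raise KeyError(name)

    def as_row(self) -> dict[str, float]:
        """Flat dict: HR, HR_CV, C1..C10, CV1..CV10, P1..P10, P1_SD..P10_SD."""
        row: dict[str, float] = {"HR": self.HR, "HR_CV": self.HR_CV}
        for n in range(1, N_HARMONICS + 1):
            row[f"C{n}"] = float(self.C[n - 1])
        for n in range(1, N_HARMONICS + 1):
            row[f"CV{n}"] = float(self.CV[n - 1])
        for n in range(1, N_HARMONICS + 1):
            row[f"P{n}"] = float(self.P[n - 1])
        for n in range(1, N_HARMONICS + 1):
            row[f"P{n}_SD"] = float(self.P_SD[n - 1])
        return row


def feature_names(include_hr: bool = False) -> list[str]:
    """The 40 harmonic index names (optionally prefixed by HR, HR_CV)."""
    names = ["HR", "HR_CV"] if include_hr else []
    for family in INDEX_FAMILIES:
        for n in range(1, N_HARMONICS + 1):
            names.append(f"P{n}_SD" if family == "P_SD" else f"{family}{n}")
    return names


def beat_harmonics(beat: np.ndarray, fs: float) -> BeatHarmonics:
    """DFT of one beat at exact multiples of its own fundamental.

    a_n = (2/N) sum_t s[t] exp(-i 2 pi n t / N), so a signal
    A cos(2 pi n t / N + phi) yields amplitude A and phase phi.
    """
    if fs <= 0:
        raise InvalidParameterError(f"fs must be positive, got {fs}")
    s = np.asarray(beat, dtype=float)
    n = len(s)
    if n < MIN_BEAT_SAMPLES:
        raise InvalidBeatError(f"beat has {n} < {MIN_BEAT_SAMPLES} samples")
    spectrum = np.fft.rfft(s)
    coeffs = 2.0 * spectrum[1 : N_HARMONICS + 1] / n
    amplitudes = np.empty(N_HARMONICS + 1)
    amplitudes[0] = float(s.mean())
    amplitudes[1:] = np.abs(coeffs)
    phases = wrap_degrees(np.degrees(np.angle(coeffs)))
    return BeatHarmonics(amplitudes=amplitudes, phases_deg=phases, period_s=n / fs)


def amplitude_proportions(bh: BeatHarmonics, norm: str = "sum") -> np.ndarray:
    """Per-beat C_n in %.

    ``norm="sum"`` divides by the sum of harmonic magnitudes 1..10 (the
    proportions then sum to exactly 100); ``norm="fundamental"`` divides by
    the first harmonic instead.
    """
    amps = np.asarray(bh.amplitudes[1:], dtype=float)
    if norm == "sum":
        denom = amps.sum()
    elif norm == "fundamental":
        denom = amps[0]
    else:
        raise InvalidParameterError(f"unknown norm {norm!r}")
    if denom <= 0:
        raise InvalidBeatError("beat has no harmonic content")
    return 100.0 * amps / denom


def _circular_mean_sd_deg(phases_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rad = np.radians(phases_deg)
    mean = sst.circmean(rad, high=np.pi, low=-np.pi, axis=0)
    sd = sst.circstd(rad, high=np.pi, low=-np.pi, axis=0)
    return wrap_degrees(np.degrees(mean)), np.degrees(sd)


def aggregate_profile(
    beats: list[BeatHarmonics],
    cn_norm: str = "sum",
    circular: bool = True,
) -> HarmonicProfile:
    """Aggregate per-beat harmonics into the 40 indices plus HR / HR_CV.

    Phase statistics are circular by default (mean direction, SD from the
    resultant length); ``circular=False`` switches to plain linear
    mean/SD of the wrapped phase values.
    """
    if len(beats) < 3:
        raise InsufficientBeatsError(f"need >= 3 beats, got {len(beats)}")
    c_mat = np.vstack([amplitude_proportions(b, norm=cn_norm) for b in beats])
    p_mat = np.vstack([b.phases_deg for b in beats])
    periods = np.asarray([b.period_s for b in beats])

    c_mean = c_mat.mean(axis=0)
    c_sd = c_mat.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(c_mean > 0, 100.0 * c_sd / c_mean, 0.0)

    if circular:
        p_mean, p_sd = _circular_mean_sd_deg(p_mat)
    else:
        p_mean = wrap_degrees(p_mat.mean(axis=0))
        p_sd = p_mat.std(axis=0, ddof=1)

    mean_period = float(periods.mean())
    hr = 60.0 / mean_period
    hr_cv = 100.0 * float(periods.std(ddof=1)) / mean_period
    return HarmonicProfile(
        C=c_mean, CV=cv, P=p_mean, P_SD=p_sd,
        HR=hr, HR_CV=hr_cv, n_beats=len(beats),
    )
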