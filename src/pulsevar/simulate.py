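"""Synthetic cohorts of paired pulse recordings with known harmonic structure.

The simulator is a statistical emulator of the beat-wise indices, not a
hemodynamic model: each beat is a finite Fourier series (10 harmonics) whose
amplitudes and phases are jittered beat-to-beat, beats are concatenated
phase-continuously at the foot (every beat starts at its own minimum), and
the exact segmentation is carried along as ground truth.

Amplitude jitter is calibrated so that the *extracted* coefficient of
variation of the amplitude proportions matches the configured target: the
proportions are a closed composition (they sum to 100%), which shrinks the
dispersion of the dominant harmonics, so the per-harmonic log-normal jitter
scales are obtained by solving the linearised variance system rather than
being used verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .preprocess import PulseRecording, SimulationTruth

N_HARMONICS = 10

GROUPS = ("N", "C", "V")

#: pulse-like decaying harmonic magnitudes (arbitrary units)
_DEFAULT_AMPLITUDES = (1.0, 0.58, 0.35, 0.21, 0.13, 0.082, 0.052, 0.034, 0.022, 0.015)


def wrap_degrees(x):
    """Wrap angles (degrees) to (-180, 180]."""
    w = np.asarray(x, dtype=float)
    w = (w + 180.0) % 360.0 - 180.0
    return np.where(w == -180.0, 180.0, w) if w.ndim else float(w if w != -180.0 else 180.0)


def _as_harmonic_vector(value, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (N_HARMONICS,)).copy()
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise InvalidParameterError(f"{name} must be finite and >= 0")
    return arr


@dataclass(frozen=True)
class BeatTemplate:
    """Harmonic content of the idealised beat."""

    harmonic_amplitudes: tuple[float, ...] = _DEFAULT_AMPLITUDES
    harmonic_phases_deg: tuple[float, ...] = (180.0,) * N_HARMONICS
    baseline_offset: float = 0.0

    def __post_init__(self):
        amps = np.asarray(self.harmonic_amplitudes, dtype=float)
        phases = np.asarray(self.harmonic_phases_deg, dtype=float)
        if amps.shape != (N_HARMONICS,) or phases.shape != (N_HARMONICS,):
            raise InvalidParameterError(
                f"need exactly {N_HARMONICS} amplitudes and phases"
            )
        if np.any(amps < 0):
            raise InvalidParameterError("harmonic amplitudes must be >= 0")
        if amps[0] == 0:
            raise InvalidParameterError("harmonic 1 must be nonzero")
        object.__setattr__(self, "harmonic_amplitudes", tuple(amps))
        object.__setattr__(
            self, "harmonic_phases_deg", tuple(float(p) for p in wrap_degrees(phases))
        )

    @property
    def amplitudes(self) -> np.ndarray:
        return np.asarray(self.harmonic_amplitudes)

    @property
    def phases_deg(self) -> np.ndarray:
        return np.asarray(self.harmonic_phases_deg)

    def proportions(self) -> np.ndarray:
        """Normalised amplitude proportions (fractions summing to 1)."""
        a = self.amplitudes
        return a / a.sum()


@dataclass(frozen=True)
class JitterModel:
    """Beat-to-beat variability configuration.

    ``rr_cv`` targets HR_CV/100; ``amp_jitter_cv`` targets the extracted
    CV_n of the amplitude proportions (fraction); ``phase_jitter_sd_deg``
    targets the extracted P_n_SD (degrees).
    """

    rr_mean: float = 0.75
    rr_cv: float = 0.0
    amp_jitter_cv: float | Sequence[float] = 0.0
    phase_jitter_sd_deg: float | Sequence[float] = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.rr_mean <= 0:
            raise InvalidParameterError(f"rr_mean must be positive, got {self.rr_mean}")
        for name in ("rr_cv", "noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        _as_harmonic_vector(self.amp_jitter_cv, "amp_jitter_cv")
        _as_harmonic_vector(self.phase_jitter_sd_deg, "phase_jitter_sd_deg")

    @property
    def amp_cv_vector(self) -> np.ndarray:
        return _as_harmonic_vector(self.amp_jitter_cv, "amp_jitter_cv")

    @property
    def phase_sd_vector(self) -> np.ndarray:
        return _as_harmonic_vector(self.phase_jitter_sd_deg, "phase_jitter_sd_deg")


def calibrated_amp_sigmas(proportions: np.ndarray, target_cv: np.ndarray) -> np.ndarray:
    """Per-harmonic log-normal sigmas whose closed composition has CV ~ target.

    With x_n = exp(sigma_n z_n) and proportions p, the linearised variance of
    log C_n is sigma_n^2 (1-p_n)^2 + sum_{k!=n} sigma_k^2 p_k^2. Solving
    A u = target^2 for u = sigma^2 undoes the closure shrinkage.
    """
    p = np.asarray(proportions, dtype=float)
    c = np.asarray(target_cv, dtype=float)
    if np.all(c == 0):
        return np.zeros(N_HARMONICS)
    A = np.tile(p**2, (N_HARMONICS, 1))
    np.fill_diagonal(A, (1.0 - p) ** 2)
    u = np.linalg.solve(A, c**2)
    if np.any(u < 0):
        # closure makes an exact match infeasible (very dominant harmonic);
        # fall back to the uncompensated scales for the offending entries
        u = np.where(u < 0, c**2, u)
    return np.sqrt(u)


def render_beat(template: BeatTemplate, rr: float, fs: float) -> np.ndarray:
    """Render one beat: baseline + sum_n amp_n cos(2 pi n t / rr + phase_n).

    The segment has round(fs * rr) samples covering [0, rr); the period is
    quantised to the sample grid so the segment is exactly one DFT period.
    """
    if rr <= 0 or fs <= 0:
        raise InvalidParameterError(f"rr and fs must be positive, got rr={rr}, fs={fs}")
    n = int(round(fs * rr))
    if n < 40:
        raise InvalidParameterError(f"fs * rr = {fs * rr:.1f} < 40 samples")
    return _render(template.amplitudes, template.phases_deg, template.baseline_offset, n)


def _render(amps: np.ndarray, phases_deg: np.ndarray, baseline: float, n: int) -> np.ndarray:
    k = np.arange(n)
    harmonics = np.arange(1, N_HARMONICS + 1)
    angles = (
        2.0 * np.pi * np.outer(harmonics, k) / n
        + np.radians(phases_deg)[:, None]
    )
    return baseline + (amps[:, None] * np.cos(angles)).sum(axis=0)


def _draw_rr(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Log-normal rr with matched mean/CV, truncated to [0.33, 1.5] s."""
    if cv == 0:
        return float(np.clip(mean, 0.33, 1.5))
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    for _ in range(1000):
        rr = float(rng.lognormal(mu, np.sqrt(sigma2)))
        if 0.33 <= rr <= 1.5:
            return rr
    raise InvalidParameterError(
        f"could not draw rr in [0.33, 1.5] s from mean={mean}, cv={cv}"
    )


def simulate_recording(
    template: BeatTemplate,
    jitter: JitterModel,
    duration_s: float = 60.0,
    fs: float = 500.0,
    channel: str = "BPW",
    subject_id: str = "",
    session: str = "M0",
) -> PulseRecording:
    """Concatenate jittered beats into one recording with exact ground truth."""
    if fs <= 0 or duration_s <= 0:
        raise InvalidParameterError("fs and duration_s must be positive")
    if duration_s <= 3 * jitter.rr_mean:
        raise InvalidParameterError(
            f"duration {duration_s} s too short for rr_mean {jitter.rr_mean} s"
        )
    rng = np.random.default_rng(jitter.seed)
    amp_sigma = calibrated_amp_sigmas(template.proportions(), jitter.amp_cv_vector)
    phase_sd = jitter.phase_sd_vector
    base_amps = template.amplitudes
    base_phases = template.phases_deg

    n_target = int(round(duration_s * fs))
    chunks: list[np.ndarray] = []
    feet = [0]
    rr_list: list[float] = []
    amp_rows: list[np.ndarray] = []
    phase_rows: list[np.ndarray] = []
    total = 0
    while True:
        rr = _draw_rr(rng, jitter.rr_mean, jitter.rr_cv)
        n = int(round(fs * rr))
        if total + n > n_target:
            break
        z = rng.standard_normal(N_HARMONICS)
        amps = base_amps * np.exp(amp_sigma * z - amp_sigma**2 / 2.0)
        phases = wrap_degrees(base_phases + rng.normal(0.0, phase_sd))
        chunks.append(_render(amps, phases, template.baseline_offset, n))
        total += n
        feet.append(total)
        rr_list.append(n / fs)
        amp_rows.append(amps)
        phase_rows.append(phases)

    samples = np.concatenate(chunks)
    if jitter.noise_sd > 0:
        samples = samples + rng.normal(0.0, jitter.noise_sd, size=len(samples))
    truth = SimulationTruth(
        foot_indices=np.asarray(feet, dtype=int),
        rr_s=np.asarray(rr_list),
        amplitudes=np.vstack(amp_rows),
        phases_deg=np.vstack(phase_rows),
    )
    return PulseRecording(
        samples=samples,
        fs=fs,
        channel=channel,
        subject_id=subject_id,
        session=session,
        truth=truth,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout and post-session (M1) perturbations.

    Group V subjects get their phase jitter multiplied by
    ``effect_post_phase_sd`` and harmonics 6-10 amplitudes multiplied by
    ``effect_post_high_harmonics`` at M1; group C gets a heart-rate-level
    shift only; group N is unchanged. Factors of 1 give a null cohort.
    """

    n_per_group: tuple[int, int, int] = (28, 34, 11)  # (N, C, V)
    effect_post_phase_sd: float = 1.0
    effect_post_high_harmonics: float = 1.0
    comorbidity_flag_prob: float = 0.3
    duration_s: float = 60.0
    fs: float = 500.0
    # baseline physiology ranges (uniform per subject)
    rr_mean_range: tuple[float, float] = (0.6, 1.0)     # 60-100 bpm
    rr_cv_range: tuple[float, float] = (0.035, 0.045)   # HR_CV 3.5-4.5%
    amp_jitter_cv: float = 0.05
    phase_jitter_sd_deg: float = 6.0
    noise_sd: float = 0.01
    hr_shift_range_c: tuple[float, float] = (0.94, 1.06)

    def __post_init__(self):
        if len(self.n_per_group) != 3 or any(n < 0 for n in self.n_per_group):
            raise InvalidParameterError("n_per_group must be 3 counts >= 0")
        if self.effect_post_phase_sd < 0 or self.effect_post_high_harmonics < 0:
            raise InvalidParameterError("effect factors must be >= 0")
        if not 0 <= self.comorbidity_flag_prob <= 1:
            raise InvalidParameterError("comorbidity_flag_prob must be in [0, 1]")


@dataclass
class Cohort:
    """Paired recordings plus the label table."""

    recordings: list[PulseRecording]
    labels: pd.DataFrame
    spec: CohortSpec = field(repr=False, default=None)

    def by_subject(self) -> dict[tuple[str, str], PulseRecording]:
        return {(r.subject_id, r.session): r for r in self.recordings}


def simulate_cohort(
    spec: CohortSpec,
    template: Optional[BeatTemplate] = None,
    seed: int = 0,
) -> Cohort:
    """Simulate paired (M0, M1) recordings for groups N, C and V."""
    template = template or BeatTemplate()
    master = np.random.default_rng(seed)
    recordings: list[PulseRecording] = []
    rows = []
    idx = 0
    for group, count in zip(GROUPS, spec.n_per_group):
        for _ in range(count):
            idx += 1
            subject = f"s{idx:03d}"
            rr_mean = float(master.uniform(*spec.rr_mean_range))
            rr_cv = float(master.uniform(*spec.rr_cv_range))
            subgroup = "A" if master.random() < spec.comorbidity_flag_prob else "B"
            base = JitterModel(
                rr_mean=rr_mean,
                rr_cv=rr_cv,
                amp_jitter_cv=spec.amp_jitter_cv,
                phase_jitter_sd_deg=spec.phase_jitter_sd_deg,
                noise_sd=spec.noise_sd,
                seed=int(master.integers(2**31)),
            )
            pre_template = template
            post_template = template
            post = replace(base, seed=int(master.integers(2**31)))
            if group == "V":
                post = replace(
                    post,
                    phase_jitter_sd_deg=spec.phase_jitter_sd_deg
                    * spec.effect_post_phase_sd,
                )
                amps = template.amplitudes.copy()
                amps[5:] *= spec.effect_post_high_harmonics
                post_template = BeatTemplate(
                    tuple(amps), template.harmonic_phases_deg, template.baseline_offset
                )
            elif group == "C":
                post = replace(
                    post, rr_mean=rr_mean * float(master.uniform(*spec.hr_shift_range_c))
                )
            recordings.append(
                simulate_recording(
                    pre_template, base, spec.duration_s, spec.fs,
                    subject_id=subject, session="M0",
                )
            )
            recordings.append(
                simulate_recording(
                    post_template, post, spec.duration_s, spec.fs,
                    subject_id=subject, session="M1",
                )
            )
            rows.append(
                {
                    "subject": subject,
                    "group": group,
                    "cv_flag": group in ("C", "V"),
                    "v_flag": group == "V",
                    "subgroup_AB": subgroup,
                }
            )
    labels = pd.DataFrame(rows)
    return Cohort(recordings=recordings, labels=labels, spec=spec)
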