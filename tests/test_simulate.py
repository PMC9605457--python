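import numpy as np
import pytest

from pulsevar import (
    BeatTemplate,
    CohortSpec,
    JitterModel,
    extract_profile,
    render_beat,
    simulate_cohort,
    simulate_recording,
)
from pulsevar.errors import InvalidParameterError
from pulsevar.simulate import calibrated_amp_sigmas, wrap_degrees


class TestRenderBeat:
    def test_single_harmonic_is_one_cosine_period(self):
        t = BeatTemplate(
            harmonic_amplitudes=(1.0,) + (0.0,) * 9,
            harmonic_phases_deg=(0.0,) * 10,
        )
        seg = render_beat(t, rr=1.0, fs=100.0)
        expected = np.cos(2 * np.pi * np.arange(100) / 100)
        assert seg.shape == (100,)
        np.testing.assert_allclose(seg, expected, atol=1e-12)

    def test_dft_recovers_amplitudes(self):
        # oracle: direct DFT of the rendered segment
        t = BeatTemplate(
            harmonic_amplitudes=(2.0, 1.0) + (0.0,) * 8,
            harmonic_phases_deg=(0.0,) * 10,
        )
        seg = render_beat(t, rr=0.8, fs=500.0)
        assert len(seg) == 400
        spectrum = np.fft.rfft(seg)
        a1 = 2 * abs(spectrum[1]) / 400  # bin 1 = 1.25 Hz
        a2 = 2 * abs(spectrum[2]) / 400  # bin 2 = 2.5 Hz
        assert abs(a1 - 2.0) / 2.0 < 0.01
        assert abs(a2 - 1.0) < 0.01

    @pytest.mark.parametrize("rr,fs", [(0.0, 500.0), (-1.0, 500.0), (0.8, 0.0)])
    def test_degenerate_parameters(self, rr, fs):
        with pytest.raises(InvalidParameterError):
            render_beat(BeatTemplate(), rr, fs)

    def test_too_few_samples_per_beat(self):
        with pytest.raises(InvalidParameterError):
            render_beat(BeatTemplate(), rr=0.5, fs=50.0)


class TestBeatTemplate:
    def test_wrong_harmonic_count(self):
        with pytest.raises(InvalidParameterError):
            BeatTemplate(harmonic_amplitudes=(1.0, 0.5))

    def test_negative_amplitude(self):
        amps = (1.0, -0.1) + (0.0,) * 8
        with pytest.raises(InvalidParameterError):
            BeatTemplate(harmonic_amplitudes=amps)

    def test_zero_fundamental(self):
        with pytest.raises(InvalidParameterError):
            BeatTemplate(harmonic_amplitudes=(0.0,) * 10)

    def test_default_is_pulse_like(self, template):
        # monotone decaying harmonic content
        assert np.all(np.diff(template.amplitudes) < 0)


class TestSimulateRecording:
    def test_zero_jitter_beat_count(self, zero_jitter_recording):
        rec = zero_jitter_recording
        assert len(rec.truth.rr_s) == 80  # floor(60 / 0.75)
        assert len(rec.samples) == 30000

    def test_zero_jitter_beats_identical(self, zero_jitter_recording):
        feet = zero_jitter_recording.truth.foot_indices
        beats = [
            zero_jitter_recording.samples[feet[i] : feet[i + 1]]
            for i in range(len(feet) - 1)
        ]
        for b in beats[1:]:
            np.testing.assert_array_equal(b, beats[0])

    def test_rr_cv_matches_drawn_sequence(self, template):
        # oracle: CV of the stored rr draws themselves
        jm = JitterModel(rr_mean=0.75, rr_cv=0.04, seed=11)
        rec = simulate_recording(template, jm, duration_s=120.0, fs=500.0)
        rr = rec.truth.rr_s
        cv = rr.std(ddof=1) / rr.mean()
        assert abs(cv - 0.04) < 0.012  # sampling error at ~160 beats

    def test_same_seed_is_bit_identical(self, template):
        jm = JitterModel(rr_mean=0.8, rr_cv=0.04, amp_jitter_cv=0.05,
                         phase_jitter_sd_deg=5.0, noise_sd=0.01, seed=42)
        a = simulate_recording(template, jm, 30.0, 500.0)
        b = simulate_recording(template, jm, 30.0, 500.0)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_duration_too_short(self, template):
        with pytest.raises(InvalidParameterError):
            simulate_recording(template, JitterModel(rr_mean=0.75), 2.0, 500.0)

    def test_truth_feet_bound_every_beat(self, template):
        jm = JitterModel(rr_mean=0.7, rr_cv=0.05, seed=5)
        rec = simulate_recording(template, jm, 30.0, 500.0)
        feet = rec.truth.foot_indices
        assert feet[0] == 0
        assert feet[-1] == len(rec.samples)
        np.testing.assert_array_equal(np.diff(feet), (rec.truth.rr_s * 500).round())


class TestJitterCalibration:
    def test_zero_target_gives_zero_sigmas(self, template):
        out = calibrated_amp_sigmas(template.proportions(), np.zeros(10))
        np.testing.assert_array_equal(out, np.zeros(10))

    def test_monte_carlo_cv_matches_target(self, template):
        # oracle: direct simulation of the closed composition
        rng = np.random.default_rng(0)
        target = np.full(10, 0.05)
        sigma = calibrated_amp_sigmas(template.proportions(), target)
        amps = template.amplitudes
        x = amps * np.exp(sigma * rng.standard_normal((20000, 10)) - sigma**2 / 2)
        c = 100 * x / x.sum(axis=1, keepdims=True)
        cv = c.std(axis=0, ddof=1) / c.mean(axis=0)
        np.testing.assert_allclose(cv, 0.05, rtol=0.06)


class TestZeroJitterExtraction:
    def test_cv_and_psd_vanish(self, zero_jitter_recording):
        prof = extract_profile(zero_jitter_recording, use_truth=True)
        np.testing.assert_allclose(prof.CV, 0.0, atol=1e-9)
        np.testing.assert_allclose(prof.P_SD, 0.0, atol=1e-9)

    def test_proportions_match_template(self, template, zero_jitter_recording):
        prof = extract_profile(zero_jitter_recording, use_truth=True)
        np.testing.assert_allclose(prof.C, 100 * template.proportions(), rtol=0.01)


class TestMonotonePhaseJitter:
    def test_extracted_psd_increases_with_configured_sd(self, template):
        means = []
        for sd in (2.0, 6.0, 12.0):
            vals = []
            for seed in range(3):
                jm = JitterModel(rr_mean=0.75, phase_jitter_sd_deg=sd, seed=seed)
                rec = simulate_recording(template, jm, 40.0, 500.0)
                vals.append(extract_profile(rec, use_truth=True).P_SD.mean())
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestSimulateCohort:
    def test_paper_group_sizes(self):
        spec = CohortSpec(n_per_group=(28, 34, 11), duration_s=4.0, fs=500.0)
        cohort = simulate_cohort(spec, seed=0)
        assert len(cohort.labels) == 73
        assert len(cohort.recordings) == 146
        counts = cohort.labels["group"].value_counts()
        assert counts["N"] == 28 and counts["C"] == 34 and counts["V"] == 11
        assert cohort.labels["cv_flag"].sum() == 45  # C union V

    def test_label_schema(self):
        spec = CohortSpec(n_per_group=(2, 1, 1), duration_s=4.0)
        cohort = simulate_cohort(spec, seed=1)
        assert set(cohort.labels.columns) >= {
            "subject", "group", "cv_flag", "v_flag", "subgroup_AB",
        }
        assert set(cohort.labels["subgroup_AB"]) <= {"A", "B"}

    def test_seed_reproducibility(self):
        spec = CohortSpec(n_per_group=(2, 1, 1), duration_s=5.0)
        a = simulate_cohort(spec, seed=7)
        b = simulate_cohort(spec, seed=7)
        for ra, rb in zip(a.recordings, b.recordings):
            np.testing.assert_array_equal(ra.samples, rb.samples)

    def test_group_v_effect_raises_scores(self):
        # oracle: recompute the score factors from the stored jitter draws
        spec = CohortSpec(
            n_per_group=(6, 0, 6), effect_post_phase_sd=2.5, duration_s=30.0
        )
        cohort = simulate_cohort(spec, seed=3)
        psd_ratio = {}
        for _, row in cohort.labels.iterrows():
            recs = {r.session: r for r in cohort.recordings
                    if r.subject_id == row["subject"]}
            pre = extract_profile(recs["M0"], use_truth=True)
            post = extract_profile(recs["M1"], use_truth=True)
            psd_ratio.setdefault(row["group"], []).append(
                np.prod(post.P_SD[:5] / pre.P_SD[:5])
            )
        assert np.mean(psd_ratio["V"]) > np.mean(psd_ratio["N"])


def test_wrap_degrees_range():
    vals = wrap_degrees(np.array([0.0, 180.0, -180.0, 270.0, -270.0, 540.0]))
    np.testing.assert_allclose(vals, [0.0, 180.0, 180.0, -90.0, 90.0, 180.0])
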