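"""Waveform simulator: kernel shape, determinism, noise model, composition."""

import numpy as np
import pytest
from scipy.optimize import brentq

from ergsynth import (FlickerParams, La3Params, SexEffect, default_sex_effect,
                      flicker_model, la3_model, make_study_fixture,
                      simulate_flicker30, simulate_la3)
from ergsynth.simulate import (FLICKER30, LA3, DEFAULT_FS, LA3_DURATION,
                               ParameterError, SubjectVariability)


class TestLa3Kernel:
    def test_trough_value_at_a_time(self):
        # narrow, well-separated lobes: value at a_time is the trough depth
        p = La3Params(a_amp=10, a_time=0.015, a_width=0.002, b_amp=25,
                      b_time=0.060, b_width=0.003, op_amp=0, noise_sd=0)
        assert la3_model(0.015, p) == pytest.approx(-10.0, abs=1e-6)

    def test_baseline_far_from_lobes(self):
        p = La3Params(a_amp=10, a_time=0.05, a_width=0.003, b_amp=25,
                      b_time=0.09, b_width=0.004, op_amp=0, noise_sd=0)
        assert abs(la3_model(0.0, p)) < 1e-10

    def test_grid_minimum_matches_analytic_stationary_point(self):
        # two-Gaussian sum: brute-force dense-grid argmin vs root of f'
        p = La3Params(a_amp=10, a_time=0.015, a_width=0.004, b_amp=25,
                      b_time=0.032, b_width=0.008, op_amp=0, noise_sd=0)
        t = np.linspace(0, 0.25, 250_001)
        t_grid = t[np.argmin(la3_model(t, p))]

        def deriv(x):
            ga = (x - p.a_time) / p.a_width**2 * p.a_amp * np.exp(
                -((x - p.a_time) ** 2) / (2 * p.a_width**2))
            gb = -(x - p.b_time) / p.b_width**2 * p.b_amp * np.exp(
                -((x - p.b_time) ** 2) / (2 * p.b_width**2))
            return ga + gb

        t_analytic = brentq(deriv, p.a_time - 2 * p.a_width, p.a_time + 2 * p.a_width)
        assert t_grid == pytest.approx(t_analytic, abs=2e-6)

    def test_op_free_kernel_is_two_gaussians(self):
        p = La3Params(op_amp=0.0, noise_sd=0)
        t = np.linspace(0, 0.25, 500)
        expected = (-p.a_amp * np.exp(-((t - p.a_time) ** 2) / (2 * p.a_width**2))
                    + p.b_amp * np.exp(-((t - p.b_time) ** 2) / (2 * p.b_width**2)))
        np.testing.assert_allclose(la3_model(t, p), expected, atol=1e-12)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ParameterError):
            La3Params(a_time=0.04, b_time=0.03)

    def test_spectral_energy_concentrated_below_300hz(self):
        # recording band is 0.1-300 Hz; the noiseless kernel must live inside it
        p = La3Params(noise_sd=0)
        t = np.arange(int(LA3_DURATION * DEFAULT_FS)) / DEFAULT_FS
        y = la3_model(t, p)
        spec = np.abs(np.fft.rfft(y)) ** 2
        freqs = np.fft.rfftfreq(y.size, 1 / DEFAULT_FS)
        assert spec[freqs > 300].sum() < 0.01 * spec.sum()


class TestSimulateLa3:
    def test_zero_noise_equals_kernel(self):
        p = La3Params(noise_sd=0)
        waves = simulate_la3(p, n_per_class={"male": 3, "female": 2}, seed=5)
        t = waves[0].times
        for w in waves:
            expected = la3_model(t, default_params_for(w.sex, p))
            np.testing.assert_array_equal(w.samples, expected)

    def test_seed_determinism(self):
        p = La3Params()
        a = simulate_la3(p, n_per_class={"male": 4, "female": 4}, seed=9)
        b = simulate_la3(p, n_per_class={"male": 4, "female": 4}, seed=9)
        for wa, wb in zip(a, b):
            np.testing.assert_array_equal(wa.samples, wb.samples)

    def test_noise_sd_recovered_across_replicates(self):
        # per-sample spread over 200 replicates matches the nominal 1 uV
        p = La3Params(noise_sd=1.0)
        waves = simulate_la3(p, SexEffect.identity(),
                             n_per_class={"male": 0, "female": 200}, seed=2)
        stack = np.stack([w.samples for w in waves])
        sds = stack.std(axis=0, ddof=1)
        assert abs(np.median(sds) - 1.0) < 0.15

    def test_too_short_duration_rejected(self):
        with pytest.raises(ParameterError):
            simulate_la3(La3Params(), duration=0.02, seed=0)


def default_params_for(sex, base):
    eff = SexEffect.identity()
    return eff.apply(base) if sex == "male" else base


class TestSimulateFlicker:
    def test_pure_tone_spectrum(self):
        p = FlickerParams(amp=10, harmonic_amps=(), noise_sd=0)
        (w,) = simulate_flicker30(p, n_per_class={"male": 0, "female": 1},
                                  duration=0.30, seed=0)
        mags = np.abs(np.fft.rfft(w.samples))
        freqs = np.fft.rfftfreq(w.samples.size, 1 / w.fs)
        # 0.30 s = 9 full cycles: energy sits in the 30 Hz bin
        assert freqs[np.argmax(mags)] == pytest.approx(30.0, abs=1e-9)
        others = mags[np.abs(freqs - 30.0) > 1.0]
        assert others.max() < 1e-9 * mags.max() + 1e-9

    def test_zero_amplitude_gives_zero_signal(self):
        p = FlickerParams(amp=0, harmonic_amps=(), noise_sd=0)
        (w,) = simulate_flicker30(p, n_per_class={"female": 1, "male": 0}, seed=0)
        np.testing.assert_array_equal(w.samples, np.zeros_like(w.samples))

    def test_peak_to_trough_is_twice_amplitude(self):
        p = FlickerParams(amp=7.5, harmonic_amps=(), noise_sd=0)
        (w,) = simulate_flicker30(p, n_per_class={"female": 1, "male": 0}, seed=0)
        # continuous-model peak-to-trough is exactly 2*amp; quantization
        # can only lose up to one sample step of the sinusoid slope
        step = 2 * np.pi * 30 / w.fs * p.amp
        assert np.ptp(w.samples) == pytest.approx(2 * p.amp, abs=step)


class TestSexEffect:
    def test_identity_leaves_parameters_unchanged(self):
        p = La3Params()
        assert SexEffect.identity().apply(p) == p

    def test_default_effect_scales_and_shifts(self):
        p = La3Params()
        q = default_sex_effect(LA3).apply(p)
        assert q.b_amp == pytest.approx(p.b_amp * 0.9)
        assert q.b_time == pytest.approx(p.b_time + 0.0015)
        assert q.a_amp == p.a_amp

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ParameterError):
            SexEffect(scale={"nope": 2.0}).apply(La3Params())


class TestStudyFixture:
    def test_composition_marginals(self, study_fixture):
        la3 = [w for w in study_fixture if w.stimulus == LA3]
        fl = [w for w in study_fixture if w.stimulus == FLICKER30]
        assert len(la3) == 170
        assert sum(w.sex == "male" for w in la3) == 60
        assert sum(w.sex == "female" for w in la3) == 110
        assert sum(w.eye == "left" for w in la3) == 85
        assert sum(w.eye == "right" for w in la3) == 85
        assert len(fl) == 67
        assert sum(w.sex == "male" for w in fl) == 18
        assert sum(w.sex == "female" for w in fl) == 49
        assert sum(w.eye == "left" for w in fl) == 33
        assert sum(w.eye == "right" for w in fl) == 34

    def test_composition_stable_across_seeds(self):
        def marginals(fx):
            return sorted((w.stimulus, w.sex, w.eye) for w in fx)

        a, b = make_study_fixture(seed=1), make_study_fixture(seed=2)
        assert marginals(a) == marginals(b)
        assert any(not np.array_equal(x.samples, y.samples) for x, y in zip(a, b))

    def test_same_seed_identical(self):
        a, b = make_study_fixture(seed=3), make_study_fixture(seed=3)
        for x, y in zip(a, b):
            assert x.key() == y.key()
            np.testing.assert_array_equal(x.samples, y.samples)

    def test_subjects_reused_across_eyes(self, study_fixture):
        la3 = [w for w in study_fixture if w.stimulus == LA3]
        by_subject = {}
        for w in la3:
            by_subject.setdefault(w.subject_id, set()).add(w.eye)
        assert any(len(eyes) == 2 for eyes in by_subject.values())
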