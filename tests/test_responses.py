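"""Ca²⁺ trace preprocessing, trial alignment, quality index, spectral contrast."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stimcal import responses
from stimcal.responses import (
    MarkerSeries,
    TrialMatrix,
    align_trials,
    fret_ratio,
    quality_index,
    spectral_contrast,
    synth_trials,
    znorm_detrend,
)


class TestFretRatio:
    def test_constant_ratio_is_flat(self):
        rng = np.random.default_rng(0)
        fd = 1.0 + 0.3 * np.abs(np.sin(np.linspace(0, 20, 2000))) + 0.5
        for scale in (1.0, 2.0):
            out = fret_ratio(scale * fd, fd, sample_rate=500.0)
            np.testing.assert_allclose(out.dr_over_r, 0.0, atol=1e-12)

    def test_step_response(self):
        """FA stepping from FD to 1.5·FD at 2 s gives ΔR/R stepping 0 → 0.5."""
        fs = 500.0
        t = np.arange(int(4 * fs)) / fs
        fd = np.full(t.size, 2.0)
        fa = fd * np.where(t < 2.0, 1.0, 1.5)
        out = fret_ratio(fa, fd, fs, baseline_window=(0.0, 1.0))
        assert out.dr_over_r[out.time < 1.9].max() == pytest.approx(0.0, abs=1e-12)
        assert out.dr_over_r[out.time > 2.1].min() == pytest.approx(0.5, rel=1e-9)

    def test_resampling_rate(self):
        fs_in = 31.25
        fa = np.ones(int(10 * fs_in))
        out = fret_ratio(fa, fa.copy(), fs_in, out_rate=500.0)
        assert out.sample_rate == 500.0
        dt = np.diff(out.time)
        np.testing.assert_allclose(dt, 1.0 / 500.0, rtol=1e-9)

    def test_bad_donor_fraction_rejected(self):
        fa = np.ones(100)
        fd = np.ones(100)
        fd[:5] = 0.0  # 5% non-positive
        with pytest.raises(ValueError, match="non-positive"):
            fret_ratio(fa, fd, 500.0)


class TestZnormDetrend:
    def test_baseline_interval_standardised(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(20 * 100.0))
        out = znorm_detrend(x, sample_rate=100.0)
        t = np.arange(x.size) / 100.0
        base = out[(t >= 1.0) & (t < 6.0)]
        assert base.mean() == pytest.approx(0.0, abs=1e-9)
        assert base.std() == pytest.approx(1.0, rel=1e-9)

    def test_slow_drift_strongly_attenuated(self):
        """A 0.01 Hz drift passes the 0.1 Hz high-pass >10× weaker than a
        2 Hz signal of equal amplitude."""
        fs, dur = 100.0, 400.0
        t = np.arange(int(dur * fs)) / fs
        slow = np.sin(2 * np.pi * 0.01 * t)
        fast = np.sin(2 * np.pi * 2.0 * t)
        out = znorm_detrend(slow + fast, fs)

        def amp(x, f):
            spec = np.abs(np.fft.rfft(x)) / x.size
            freqs = np.fft.rfftfreq(x.size, 1 / fs)
            return spec[np.argmin(np.abs(freqs - f))]

        ratio_in = 1.0
        ratio_out = amp(out, 0.01) / amp(out, 2.0)
        assert ratio_out < ratio_in / 10.0

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            znorm_detrend(np.ones(2000), sample_rate=100.0)


class TestAlignTrials:
    fs = 500.0

    def sine_trace(self, n_trials=4, trial_s=4.0, phase=0.0):
        t = np.arange(int(n_trials * trial_s * self.fs)) / self.fs
        return np.sin(2 * np.pi * 1.0 * (t - phase)), t

    def test_exact_markers_match_reshaping(self):
        x, t = self.sine_trace()
        markers = MarkerSeries(np.array([0.0, 4.0, 8.0, 12.0]))
        tm = align_trials(x, self.fs, markers, trial_duration=4.0)
        naive = x.reshape(4, -1).T
        np.testing.assert_allclose(tm.c, naive, atol=1e-9)

    def test_line_offset_shifts_each_trial(self):
        x, t = self.sine_trace()
        markers = MarkerSeries(np.array([0.0, 4.0, 8.0]), scan_line_period=2e-3)
        tm0 = align_trials(x, self.fs, markers, roi_line_index=0, trial_duration=3.9)
        tm1 = align_trials(x, self.fs, markers, roi_line_index=1, trial_duration=3.9)
        shift = np.interp(np.arange(tm0.n_time) / self.fs + 2e-3,
                          np.arange(x.size) / self.fs, x)
        np.testing.assert_allclose(tm1.c[:, 0], shift[: tm1.n_time], atol=1e-9)

    def test_phase_jitter_below_2ms(self):
        """Markers off the sample grid: recovered per-trial phases agree to
        better than 2 ms of stimulus time."""
        fs = self.fs
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * 1.0 * t)
        starts = np.array([0.2003, 4.2001, 8.1997, 12.2004])
        tm = align_trials(x, fs, MarkerSeries(starts), trial_duration=3.0)
        phases = []
        for r in range(tm.n_reps):
            spec = np.fft.rfft(tm.c[:, r])
            k = int(round(1.0 * tm.n_time / tm.sample_rate))
            phases.append(np.angle(spec[k]))
        sd_ms = np.std(phases) / (2 * np.pi * 1.0) * 1e3
        assert sd_ms < 2.0

    def test_window_longer_than_interval_rejected(self):
        x, _ = self.sine_trace()
        with pytest.raises(ValueError, match="marker"):
            align_trials(x, self.fs, MarkerSeries(np.array([0.0, 2.0])),
                         trial_duration=3.0)


class TestQualityIndex:
    def test_identical_repetitions_give_one(self):
        t = np.arange(500) / 500.0
        sig = np.sin(2 * np.pi * t)
        tm = TrialMatrix(np.tile(sig[:, None], (1, 5)), 500.0)
        assert quality_index(tm).qi == pytest.approx(1.0)
        assert quality_index(tm).passes

    def test_pure_noise_approaches_one_over_r(self):
        rng = np.random.default_rng(7)
        tm = TrialMatrix(rng.standard_normal((5000, 10)), 500.0)
        res = quality_index(tm)
        assert res.qi == pytest.approx(0.1, abs=0.02)
        assert not res.passes

    def test_mixed_signal_noise_expectation(self):
        """σ_signal = σ_noise, R = 4 → E[Qi] = (1 + 1/4)/2 = 0.625."""
        rng = np.random.default_rng(11)
        n_t, n_r = 5000, 4
        t = np.arange(n_t) / 500.0
        sig = np.sqrt(2.0) * np.sin(2 * np.pi * t)  # variance 1
        c = sig[:, None] + rng.standard_normal((n_t, n_r))
        qi = quality_index(TrialMatrix(c, 500.0)).qi
        assert qi == pytest.approx(0.625, abs=0.02)

    def test_constant_trials_undefined(self):
        tm = TrialMatrix(np.ones((100, 4)), 500.0)
        with pytest.raises(ZeroDivisionError):
            quality_index(tm)

    @settings(max_examples=15, derandomize=True)
    @given(a=st.floats(min_value=0.1, max_value=50.0),
           b=st.floats(min_value=-10.0, max_value=10.0))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(3)
        c = np.sin(np.linspace(0, 20, 400))[:, None] + 0.5 * rng.standard_normal((400, 4))
        q1 = quality_index(TrialMatrix(c, 100.0)).qi
        q2 = quality_index(TrialMatrix(a * c + b, 100.0)).qi
        assert q2 == pytest.approx(q1, rel=1e-9)


class TestSpectralContrast:
    def matrices(self, amp_g, amp_b, fs=500.0, dur=4.0, reps=3):
        t = np.arange(int(dur * fs)) / fs
        g = TrialMatrix(np.tile((amp_g * np.sin(2 * np.pi * t))[:, None], (1, reps)), fs)
        b = TrialMatrix(np.tile((amp_b * np.sin(2 * np.pi * t))[:, None], (1, reps)), fs)
        return g, b

    def test_symmetric_responses_zero(self):
        g, b = self.matrices(1.0, 1.0)
        assert spectral_contrast(g, b).sc == pytest.approx(0.0, abs=1e-12)

    def test_uv_only_is_minus_one(self):
        g, b = self.matrices(0.0, 1.0)
        assert spectral_contrast(g, b).sc == pytest.approx(-1.0)

    def test_power_ratio_four_to_one(self):
        """Green amplitude 2× the UV amplitude → powers 4:1 → SC = 0.6."""
        g, b = self.matrices(2.0, 1.0)
        res = spectral_contrast(g, b)
        assert res.p_g / res.p_b == pytest.approx(4.0, rel=1e-9)
        assert res.sc == pytest.approx(0.6, rel=1e-9)

    def test_antisymmetric_under_swap(self):
        g, b = self.matrices(1.7, 0.6)
        assert spectral_contrast(g, b).sc == pytest.approx(
            -spectral_contrast(b, g).sc, rel=1e-12)

    def test_amplitude_mode_same_sign_smaller_magnitude(self):
        g, b = self.matrices(2.0, 1.0)
        power = spectral_contrast(g, b).sc
        ampl = spectral_contrast(g, b, mode="amplitude").sc
        assert np.sign(ampl) == np.sign(power)
        assert abs(ampl) < abs(power)  # 1/3 vs 3/5 for a 2:1 amplitude ratio

    def test_non_integer_cycles_rejected(self):
        t = np.arange(1700) / 500.0
        m = TrialMatrix(np.sin(2 * np.pi * t)[:, None].repeat(2, 1), 500.0)
        with pytest.raises(ValueError, match="integer"):
            spectral_contrast(m, m)

    def test_zero_power_rejected(self):
        m = TrialMatrix(np.zeros((500, 2)), 500.0)
        with pytest.raises(ZeroDivisionError):
            spectral_contrast(m, m)


class TestSynthTrials:
    def test_deterministic_under_seed(self):
        a = synth_trials(0.3, 0.6, seed=5)
        b = synth_trials(0.3, 0.6, seed=5)
        np.testing.assert_array_equal(a[0].c, b[0].c)
        np.testing.assert_array_equal(a[1].c, b[1].c)

    def test_zero_noise_gives_qi_one(self):
        g, _ = synth_trials(0.5, 1.0, seed=2)
        assert quality_index(g).qi == pytest.approx(1.0)

    def test_low_noise_sc_recovery(self):
        g, b = synth_trials(0.5, 0.95, seed=3)
        assert spectral_contrast(g, b).sc == pytest.approx(0.5, abs=0.05)

    def test_qi_calibration(self):
        """Measured Qi lands near the requested target (balanced case)."""
        g, b = synth_trials(0.0, 0.6, n_reps=10, duration=8.0, seed=9)
        assert quality_index(g).qi == pytest.approx(0.6, abs=0.08)

    def test_infeasible_targets_rejected(self):
        with pytest.raises(ValueError):
            synth_trials(0.0, 1.5)
        with pytest.raises(ValueError):
            synth_trials(0.0, 0.2, n_reps=3)  # below the 1/R noise floor
        with pytest.raises(ValueError):
            synth_trials(1.5, 0.8)

    def test_recovery_across_grid(self):
        """Mean |SC error| < 0.1 over true SC × quality grid at R = 3."""
        errors = []
        for i, sc_true in enumerate((-1.0, -0.5, 0.0, 0.5, 1.0)):
            for j, qi in enumerate((0.4, 0.8)):
                g, b = synth_trials(sc_true, qi, n_reps=3, duration=4.0,
                                    seed=100 + 10 * i + j)
                errors.append(abs(spectral_contrast(g, b).sc - sc_true))
        assert np.mean(errors) < 0.1
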