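"""Trace processing: averaging, CWT analysis/denoising, gating, fits, dF/F."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import curve_fit

from pam3p.acoustics import RawTrace
from pam3p.dsp import (average_pulses, band_denoise, dff_and_correlation,
                       fit_exp_decay, fit_linear, fit_power_law, gated_peak,
                       scalogram)
from pam3p.errors import (AlignmentError, DegenerateBaselineError, DomainError,
                          InvalidArgumentError, WindowError)

FS_GHZ = 2.0
DT_US = 1e-3 / FS_GHZ


def tone_burst(f_mhz, n=6000, amp=1.0, t0_frac=0.3, t1_frac=0.7):
    """Windowed tone burst at f_mhz on the 2 GHz sample grid."""
    t = np.arange(n) * DT_US
    x = amp * np.sin(2 * np.pi * f_mhz * t)
    win = np.zeros(n)
    i0, i1 = int(n * t0_frac), int(n * t1_frac)
    win[i0:i1] = np.hanning(i1 - i0)
    return x * win


class TestAveragePulses:
    def test_single_trace_identity(self, rng):
        x = rng.standard_normal(256)
        out = average_pulses([RawTrace(x)], 1)
        assert np.allclose(out.samples_mv, x)

    def test_hand_computed_mean(self):
        traces = [np.array([1.0, 2.0, 3.0]), np.array([3.0, 4.0, 5.0]),
                  np.array([5.0, 6.0, 10.0])]
        out = average_pulses(traces, 3)
        assert np.array_equal(out.samples_mv, np.array([3.0, 4.0, 6.0]))

    def test_sqrt_n_noise_reduction_at_250(self, rng):
        # averaging 250 noise traces cuts the RMS by ~sqrt(250) = 15.8
        ratios = []
        for _ in range(20):
            traces = rng.standard_normal((250, 2000))
            avg = average_pulses(list(traces), 250)
            ratios.append(np.std(traces[0]) / np.std(avg.samples_mv))
        assert np.mean(ratios) == pytest.approx(math.sqrt(250), rel=0.10)

    def test_length_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            average_pulses([np.zeros(10), np.zeros(11)], 2)

    def test_too_few_traces(self):
        with pytest.raises(InvalidArgumentError):
            average_pulses([np.zeros(10)], 5)


class TestScalogram:
    def test_88_mhz_burst_peak(self):
        sg = scalogram(RawTrace(tone_burst(88.0)), 40.0, 160.0)
        assert sg.peak_frequency_mhz() == pytest.approx(88.0, abs=3.0)

    def test_10_mhz_tone_peak(self):
        sg = scalogram(RawTrace(tone_burst(10.0, n=12000)), 4.0, 40.0)
        assert sg.peak_frequency_mhz() == pytest.approx(10.0, abs=0.5)

    def test_two_tone_ridges_match_fft_oracle(self):
        x = tone_burst(30.0) + tone_burst(90.0)
        sg = scalogram(RawTrace(x), 15.0, 180.0)
        ridges = sg.ridge_frequencies_mhz(2)
        # FFT oracle on the same trace
        spec = np.abs(np.fft.rfft(x))
        freqs = np.fft.rfftfreq(x.size, DT_US)
        mask_lo = (freqs > 15) & (freqs < 55)
        mask_hi = (freqs >= 55) & (freqs < 180)
        f_lo = freqs[mask_lo][np.argmax(spec[mask_lo])]
        f_hi = freqs[mask_hi][np.argmax(spec[mask_hi])]
        assert ridges[0] == pytest.approx(f_lo, rel=0.05)
        assert ridges[1] == pytest.approx(f_hi, rel=0.05)

    def test_peak_invariant_to_amplitude(self):
        a = scalogram(RawTrace(tone_burst(70.0)), 40.0, 120.0).peak_frequency_mhz()
        b = scalogram(RawTrace(tone_burst(70.0, amp=37.0)), 40.0, 120.0).peak_frequency_mhz()
        assert a == b

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(InvalidArgumentError):
            scalogram(RawTrace(np.zeros(100)), 100.0, 1100.0)


class TestBandDenoise:
    def test_in_band_tone_amplitude_preserved(self):
        x = tone_burst(70.0)
        out = band_denoise(RawTrace(x), 50.0, 90.0)
        assert np.abs(out.samples_mv).max() == pytest.approx(np.abs(x).max(), rel=0.10)

    def test_out_of_band_tone_suppressed(self):
        x = tone_burst(10.0)
        out = band_denoise(RawTrace(x), 50.0, 90.0)
        assert np.abs(out.samples_mv).max() < np.abs(x).max() / 10.0

    def test_snr_improves_on_noisy_tone(self):
        # Monte-Carlo: peak / off-peak RMS before vs after, 20 seeds
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            clean = tone_burst(75.0, n=6000)
            noisy = clean + 0.5 * rng.standard_normal(6000)

            def snr(sig):
                peak = np.abs(sig[1800:4200]).max()
                off = np.std(np.concatenate([sig[200:1500], sig[4500:5800]]))
                return peak / off

            out = band_denoise(RawTrace(noisy), 60.0, 90.0)
            if snr(out.samples_mv) > snr(noisy):
                wins += 1
        assert wins >= 18

    def test_idempotent_within_tolerance(self):
        x = tone_burst(70.0)
        once = band_denoise(RawTrace(x), 50.0, 90.0)
        twice = band_denoise(once, 50.0, 90.0)
        change = np.sqrt(np.mean((twice.samples_mv - once.samples_mv) ** 2))
        assert change < 0.05 * np.sqrt(np.mean(once.samples_mv**2))

    def test_empty_band_rejected(self):
        with pytest.raises(InvalidArgumentError):
            band_denoise(RawTrace(np.zeros(1000)), 90.0, 50.0)


class TestGatedPeak:
    def test_zero_trace(self):
        assert gated_peak(RawTrace(np.zeros(4000)), 0.5, 0.2) == 0.0

    def test_rect_pulse_max_abs(self):
        x = np.zeros(4000)
        x[1000:1200] = 1.0
        assert gated_peak(RawTrace(x), 0.4, 0.3, "max_abs") == 1.0

    def test_peak_to_peak_hand_computed(self):
        x = np.array([0.0, 2.0, -3.0, 1.0, 5.0, -1.0, 0.5, 0.0])
        tr = RawTrace(x, fs_ghz=2.0)
        # whole trace window: max 5 - min -3 = 8
        assert gated_peak(tr, 0.0, 8 * DT_US) == 8.0

    def test_window_outside_trace_raises(self):
        with pytest.raises(WindowError):
            gated_peak(RawTrace(np.zeros(100)), 1.0, 1.0)


class TestFits:
    def test_cubic_exact(self):
        x = np.linspace(6.0, 25.0, 8)
        fit = fit_power_law(x, x**3)
        assert fit.params["exponent"] == pytest.approx(3.0, abs=1e-9)

    def test_linear_power_exact(self):
        x = np.linspace(1.0, 10.0, 6)
        fit = fit_power_law(x, 4.2 * x)
        assert fit.params["exponent"] == pytest.approx(1.0, abs=1e-9)

    def test_power_law_vs_nonlinear_oracle(self, rng):
        x = np.linspace(6.0, 25.0, 10)
        y = x**3 * np.exp(0.05 * rng.standard_normal(10))
        ols = fit_power_law(x, y)
        popt, pcov = curve_fit(lambda x, a, k: a * x**k, x, y, p0=[1.0, 3.0])
        joint = ols.stderr["exponent"] + math.sqrt(pcov[1, 1])
        assert abs(ols.params["exponent"] - popt[1]) < 2 * joint + 0.02

    def test_power_law_domain_error(self):
        with pytest.raises(DomainError):
            fit_power_law([1.0, 2.0, 3.0], [1.0, -2.0, 3.0])

    def test_linear_noiseless_r_is_one(self):
        x = np.array([1.0, 2.0, 4.6, 9.3, 18.75])
        fit = fit_linear(x, 3.0 * x + 1.0)
        assert fit.r == pytest.approx(1.0, abs=1e-12)
        assert fit.params["slope"] == pytest.approx(3.0)

    def test_pearson_r_vs_covariance_formula(self, rng):
        x = rng.uniform(0, 10, 20)
        y = 2 * x + rng.standard_normal(20)
        fit = fit_linear(x, y)
        r_oracle = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert fit.r == pytest.approx(r_oracle, abs=1e-12)

    def test_degenerate_x_raises(self):
        with pytest.raises(DomainError):
            fit_linear([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_exp_decay_noiseless(self):
        z = np.arange(0, 701, 100, dtype=float)
        fit = fit_exp_decay(z, np.exp(-z / 250.0))
        assert fit.params["length_um"] == pytest.approx(250.0, rel=1e-9)

    def test_exp_decay_constant_flagged(self):
        fit = fit_exp_decay([0.0, 100.0, 200.0], [2.0, 2.0, 2.0])
        assert fit.flags["non_decaying"]
        assert math.isinf(fit.params["length_um"])

    def test_exp_decay_noisy_recovery(self):
        # 10% multiplicative noise, median recovery within 5% over 50 seeds
        z = np.arange(0, 701, 100, dtype=float)
        clean = np.exp(-z / 250.0)
        lengths = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = clean * np.exp(0.1 * rng.standard_normal(z.size))
            lengths.append(fit_exp_decay(z, y).params["length_um"])
        assert np.median(lengths) == pytest.approx(250.0, rel=0.05)

    def test_exp_decay_domain_error(self):
        with pytest.raises(DomainError):
            fit_exp_decay([0.0, 1.0, 2.0], [1.0, 0.0, 1.0])


class TestDffAndCorrelation:
    def test_constant_trace_zero_dff(self):
        df = pd.DataFrame({"a": np.full(20, 7.0), "b": np.arange(1.0, 21.0)})
        dff, _ = dff_and_correlation(df)
        assert np.allclose(dff["a"], 0.0)

    def test_baseline_is_lowest_decile_mean(self):
        v = np.arange(1.0, 21.0)  # lowest 10% of 20 samples = {1, 2}
        df = pd.DataFrame({"a": v, "b": v[::-1].copy()})
        dff, _ = dff_and_correlation(df)
        baseline = 1.5
        assert np.allclose(dff["a"], (v - baseline) / baseline)

    def test_identical_traces_correlate_to_one(self, rng):
        v = rng.uniform(1, 2, 30)
        _, corr = dff_and_correlation(pd.DataFrame({"a": v, "b": v.copy()}))
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_pearson_vs_textbook_formula(self):
        a = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0, 5.0, 7.0, 6.0, 8.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0, 8.0, 7.0, 10.0, 9.0])
        _, corr = dff_and_correlation(pd.DataFrame({"a": a, "b": b}))

        def dff(v):
            base = np.sort(v)[:1].mean()
            return (v - base) / base

        x, y = dff(a), dff(b)
        r = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert corr.loc["a", "b"] == pytest.approx(r, abs=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 1000))
    def test_matrix_symmetric_unit_diagonal_bounded(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.uniform(1.0, 5.0, size=(15, 4)),
                          columns=list("abcd"))
        _, corr = dff_and_correlation(df)
        m = corr.to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert np.all(m <= 1.0 + 1e-12) and np.all(m >= -1.0 - 1e-12)

    def test_zero_baseline_raises(self):
        df = pd.DataFrame({"a": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0],
                           "b": np.ones(10)})
        with pytest.raises(DegenerateBaselineError):
            dff_and_correlation(df)

    def test_detrend_removes_bleaching_ramp(self):
        t = np.arange(50, dtype=float)
        df = pd.DataFrame({"a": 10.0 + 0.2 * t, "b": 10.0 - 0.2 * t})
        dff, _ = dff_and_correlation(df, detrend=True)
        assert np.abs(dff["a"]).max() < 0.05
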