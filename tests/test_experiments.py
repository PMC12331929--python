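"""End-to-end in-silico experiments and closed-form calculators."""

import math

import numpy as np
import pytest

from pam3p.errors import GeometryError, InvalidArgumentError
from pam3p.experiments import (child_seeds, depth_budget, measure_ascan,
                               reference_gel_measurement,
                               run_concentration_series, run_depth_sweep,
                               run_dual_channel_depth, run_power_series,
                               simulate_optical_image, simulate_scan,
                               timing_report)
from pam3p.optics import Chromophore, OpticsConfig
from pam3p.phantom import MEDIA, Phantom, make_cell_field, make_gel_cylinder
from pam3p.recon import ScanConfig, assemble_image


class TestTimingReport:
    def test_instrument_acquisition_settings(self):
        rep = timing_report(200.0, 20.0, 0.5, (256, 256))
        assert rep["pulses_per_pixel"] == 4
        assert rep["frame_rate_hz"] == pytest.approx(0.76, abs=0.005)
        assert rep["stretched_pulse_width_us"] == pytest.approx(2.5)

    def test_zero_duty_zero_width(self):
        assert timing_report(duty_target=0.0)["stretched_pulse_width_us"] == 0.0

    @pytest.mark.parametrize("rate,duty", [(100.0, 0.25), (200.0, 0.5),
                                           (400.0, 0.8)])
    def test_width_times_rate_equals_duty(self, rate, duty):
        width_us = timing_report(rate, 20.0, duty)["stretched_pulse_width_us"]
        assert width_us * 1e-6 * rate * 1e3 == pytest.approx(duty, rel=1e-12)

    def test_full_duty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            timing_report(duty_target=1.0)


class TestDepthBudget:
    def test_cortex_budget(self):
        b = depth_budget(2.7, 50.0, 100.0)
        assert b["optical_attenuation_factor"] == pytest.approx(3.5e-24, rel=0.01)
        assert b["acoustic_loss_db"] == pytest.approx(4.0, abs=0.01)
        assert 1e-4 < b["pressure_geometric_factor"] < 1e-3

    def test_zero_depth(self):
        b = depth_budget(0.0, 50.0, 100.0)
        assert b["optical_attenuation_factor"] == 1.0
        assert b["acoustic_loss_db"] == 0.0


class TestSeries:
    def test_concentration_series_noiseless_linear(self):
        df, fit = run_concentration_series()
        assert list(df["concentration_mm"]) == [1.0, 2.0, 4.6, 9.3, 18.75]
        assert fit.r == pytest.approx(1.0, abs=1e-6)
        # amplitude strictly increasing with concentration
        assert np.all(np.diff(df["pa_amplitude_mv"]) > 0)

    def test_concentration_slope_scales_with_cross_section(self):
        grid = [1.0, 5.0, 10.0]
        _, fit1 = run_concentration_series(grid)
        _, fit2 = run_concentration_series(
            grid, chrom=Chromophore(sigma3=2 * 4.29e-85))
        assert fit2.params["slope"] == pytest.approx(2 * fit1.params["slope"],
                                                     rel=1e-9)

    def test_concentration_noise_degrades_r_reproducibly(self):
        grid = (1.0, 2.0, 4.6, 9.3, 18.75)
        _, clean = run_concentration_series(grid)
        _, noisy_a = run_concentration_series(grid, noise_rms_mv=150.0, seed=4)
        _, noisy_b = run_concentration_series(grid, noise_rms_mv=150.0, seed=4)
        assert noisy_a.r == noisy_b.r
        assert abs(noisy_a.r) < clean.r

    def test_empty_concentration_list_rejected(self):
        with pytest.raises(InvalidArgumentError):
            run_concentration_series([])

    def test_power_series_cubic_and_quadratic(self):
        _, fit3 = run_power_series((6.0, 12.0, 25.0))
        assert fit3.params["exponent"] == pytest.approx(3.0, abs=1e-6)
        _, fit2 = run_power_series((6.0, 12.0, 25.0),
                                   optics=OpticsConfig(photon_order=2))
        assert fit2.params["exponent"] == pytest.approx(2.0, abs=1e-6)

    def test_nonpositive_powers_rejected(self):
        with pytest.raises(InvalidArgumentError):
            run_power_series((0.0, 5.0, 10.0))


class TestDepthSweep:
    def test_fitted_length_is_li_over_three(self):
        # closed-form identity of the model: signal 1/e length = L_I / n
        depths = tuple(range(0, 601, 150))
        for li in (600.0, 750.0, 1200.0):
            medium = dict(MEDIA["brain"], attenuation_length_um=li)
            grid = np.full((20, 20, 100), np.float32(10.0))
            slab = Phantom(grid, 10.0, **medium)
            center = 100.0
            margin = 60.0
            amps = [measure_ascan(slab, (center, center, z + margin)).clean_amplitude_mv
                    for z in depths]
            from pam3p.dsp import fit_exp_decay
            fit = fit_exp_decay(np.array(depths), amps)
            assert fit.params["length_um"] == pytest.approx(li / 3.0, rel=0.01)

    def test_zero_attenuation_flat_curve_flagged(self):
        df, fit = run_depth_sweep(tuple(range(0, 601, 200)), preset="gel",
                                  thickness_um=800.0)
        assert fit.flags["non_decaying"]

    def test_depth_grid_beyond_specimen_rejected(self):
        with pytest.raises(GeometryError):
            run_depth_sweep((0.0, 500.0, 2000.0), thickness_um=1000.0)

    def test_noisy_sweep_returns_per_seed_fits(self):
        _, fits = run_depth_sweep(tuple(range(0, 601, 200)), noise_frac=0.1,
                                  seed=1, n_seeds=3)
        assert len(fits) == 3
        lengths = [f.params["length_um"] for f in fits]
        assert len(set(lengths)) == 3  # distinct noise realizations


@pytest.fixture(scope="module")
def dual():
    return run_dual_channel_depth(tuple(range(0, 1101, 100)))


class TestDualChannel:

    def test_floor_crossing_ordering(self, dual):
        df, summary = dual
        # optical channel dies near 400 um; PA survives past the full depth
        assert 300.0 < summary["optical_crossing_um"] < 500.0
        assert summary["pa_crossing_um"] > 1100.0

    def test_snr_ordering_at_depth(self, dual):
        df, _ = dual
        row = df[df["depth_um"] == 1000.0].iloc[0]
        assert row["pa_snr"] > 5.0
        assert row["optical_snr"] < 1.0

    def test_brighter_fluorophore_extends_optical_depth(self, dual):
        # same absolute floor, 10x quantum yield: the crossing moves deeper
        _, base = dual
        _, bright = run_dual_channel_depth(
            tuple(range(0, 1101, 100)), chrom=Chromophore(quantum_yield=0.5),
            optical_floor=base["optical_floor"])
        assert bright["optical_crossing_um"] > base["optical_crossing_um"]


class TestReference:
    def test_worked_snr(self):
        ref = reference_gel_measurement()
        assert ref["signal_mv"] == pytest.approx(194.0, rel=0.02)
        assert ref["snr"] == pytest.approx(9.7, rel=0.02)

    def test_child_seeds_deterministic_and_bounded(self):
        a = child_seeds(42, 5)
        assert a == child_seeds(42, 5)
        assert len(set(a)) == 5
        assert all(0 <= s < 2**31 for s in a)


@pytest.fixture(scope="module")
def cell_scan():
    phantom = make_cell_field(3, cell_diameter_um=8.0, intra_mm=8.0,
                              background_mm=0.2, field_um=60.0,
                              pitch_um=2.0, seed=11, depth_um=40.0)
    scan = ScanConfig(pixels=(16, 16), dwell_us=20.0, rep_rate_khz=200.0,
                      fov_um=40.0, focus_depth_um=20.0, gate_width_us=0.2)
    traces = simulate_scan(phantom, scan, seed=5, add_noise=False,
                           apply_aperture=False)
    pa_img = assemble_image(traces, scan)
    opt_img = simulate_optical_image(phantom, scan)
    return phantom, scan, traces, pa_img, opt_img


class TestScanEndToEnd:
    def test_cell_maxima_within_one_pixel(self, cell_scan):
        phantom, scan, _, pa_img, _ = cell_scan
        cx = phantom.shape[0] * phantom.pitch_um / 2.0
        origin = cx - scan.fov_um / 2.0
        pitch = scan.pixel_pitch_um
        for x, y, _z in phantom.meta["cell_centers_um"]:
            col = (x - origin) / pitch - 0.5
            row = (y - origin) / pitch - 0.5
            if not (1 <= row <= 14 and 1 <= col <= 14):
                continue  # cell outside the scanned FOV interior
            r0, c0 = int(round(row)), int(round(col))
            window = pa_img.data[max(r0 - 2, 0):r0 + 3, max(c0 - 2, 0):c0 + 3]
            rr, cc = np.unravel_index(np.argmax(window), window.shape)
            peak = (max(r0 - 2, 0) + rr, max(c0 - 2, 0) + cc)
            assert abs(peak[0] - row) <= 1.5 and abs(peak[1] - col) <= 1.5

    def test_pa_and_optical_channels_correlate(self, cell_scan):
        _, _, _, pa_img, opt_img = cell_scan
        r = np.corrcoef(pa_img.data.ravel(), opt_img.data.ravel())[0, 1]
        assert r > 0.8

    def test_traceset_metadata_and_determinism(self, cell_scan):
        phantom, scan, traces, _, _ = cell_scan
        assert traces.meta["pulses_per_pixel"] == 4
        assert traces.voltage_mv.shape[0] == 256
        again = simulate_scan(phantom, scan, seed=5, add_noise=False,
                              apply_aperture=False)
        assert np.array_equal(again.voltage_mv, traces.voltage_mv)

    def test_noise_seed_reproducible(self, cell_scan):
        phantom, _, _, _, _ = cell_scan
        scan = ScanConfig(pixels=(2, 2), dwell_us=20.0, rep_rate_khz=200.0,
                          fov_um=10.0, focus_depth_um=20.0)
        a = simulate_scan(phantom, scan, seed=9)
        b = simulate_scan(phantom, scan, seed=9)
        assert np.array_equal(a.voltage_mv, b.voltage_mv)
        c = simulate_scan(phantom, scan, seed=10)
        assert not np.array_equal(a.voltage_mv, c.voltage_mv)


class TestChainLinearity:
    def test_amplitude_linear_in_concentration_through_chain(self):
        gel2 = make_gel_cylinder(2.0, 1.0, 0.5, 20.0)
        gel8 = make_gel_cylinder(8.0, 1.0, 0.5, 20.0)
        center = gel2.shape[0] * gel2.pitch_um / 2.0
        a2 = measure_ascan(gel2, (center, center, 100.0)).clean_amplitude_mv
        a8 = measure_ascan(gel8, (center, center, 100.0)).clean_amplitude_mv
        assert a8 == pytest.approx(4.0 * a2, rel=1e-9)

    def test_arrival_inside_gate(self):
        gel = make_gel_cylinder(10.0, 1.0, 0.5, 20.0)
        center = gel.shape[0] * gel.pitch_um / 2.0
        res = measure_ascan(gel, (center, center, 100.0))
        from pam3p.dsp import arrival_time
        t = arrival_time(res.trace, res.gate_start_us, res.gate_width_us)
        expect = 2.6 + res.r_mm * 1e3 / gel.sound_speed
        assert t == pytest.approx(expect, abs=5e-3)
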