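# pam3p

A desk-scale digital twin of a label-free multiphoton photoacoustic
microscope (LF-MP-PAM) for imaging endogenous NAD(P)H in brain cells,
slices and cerebral organoids.

NAD(P)H is a ubiquitous metabolic coenzyme with a low fluorescence quantum
yield (Φ ≈ 0.05) and near-UV emission (~450 nm) that tissue absorbs within
tens of micrometers — all-optical imaging of it dies a few hundred
micrometers down. Three-photon excitation at 1300 nm deposits most of the
absorbed energy as heat; the resulting thermoelastic pressure pulse travels
to an ultrasound transducer with minimal loss, so the *acoustic* channel
keeps reporting NAD(P)H a millimeter deep while the optical channel has long
since hit its noise floor. `pam3p` simulates that entire chain on synthetic
phantoms with known ground truth, and implements the instrument's trace
processing and image reconstruction, so every quantitative design claim of
the measurement can be exercised and checked numerically.

## Model

For a chromophore concentration field C(**r**) (mM) and a focal intensity
profile Î(**r**) (peak 1) whose *heated* profile Î&#8319; has calibrated widths
w_xy = 2.2 µm and w_z = 30 µm (FWHM, at NA 0.4 / λ 1300 nm; scaling λ/NA
laterally and λ/NA² axially), the per-pulse heat density is

    H(r) = C·N_A · σ₃ (φ T(z) Î)ⁿ τ_p · η_h · n·E_photon        [J/m³]

with φ the peak photon flux from the pulse energy E_p = P/f_rep, T(z) =
exp(−z/L_I) the excitation intensity transmission, n = 3 the photon order,
σ₃ = 4.29 × 10⁻⁸⁵ the three-photon cross-section, and η_h = 1 − Φλ_ex/(nλ_em)
≈ 0.952 the heat fraction. Initial pressure is p₀ = Γ·H (Γ = 0.2), and the
far-field element pressure is the superposition

    p(t) = Σ_v (a_eff / r_v) (dV / V_eff) p₀(r_v) · s(t − r_v/c)

over source voxels, with s a unit-peak derivative-of-Gaussian wavelet whose
timescale is set by the transverse heated width (the axial extent enters
through the arrival-time spread itself). The trace is then attenuated by
10^(−a·d·f^b/20) (a = 0.0148 dB/(mm·MHz), b = 1: −4 dB through 2.7 mm near
100 MHz), weighted by the 100 µm acceptance aperture, delayed 2.6 µs by the
transducer's delay line, band-limited (68–197 MHz transducer × 20–150 MHz
receiver), and scaled by 140 µV/Pa × 63 dB (×1412) of gain plus 20 mV RMS
white noise. The fluorescence channel integrates C σ₃ (φTÎ)ⁿ Φ over the
focal volume and decays with the emission extinction exp(−z/L_em),
L_em = 50 µm in tissue.

Consequences the package reproduces exactly: signal ∝ P³ (three-photon),
signal ∝ C (linear concentration response), and a photoacoustic depth decay
exp(−3z/L_I) whose 1/e length is L_I/3 = 250 µm for the brain preset.

## Worked example

```python
from pam3p.experiments import (reference_gel_measurement, run_power_series,
                               run_depth_sweep, timing_report)

ref = reference_gel_measurement()          # 10 mM NADH gel, 25 mW at focus
print(ref["signal_mv"], ref["snr"])        # 194.0  9.7
_, fit = run_power_series()                # 6-25 mW series, noiseless
print(fit.params["exponent"])              # 3.0000000000000018
_, fit = run_depth_sweep()                 # brain preset, 0-700 um
print(fit.params["length_um"])             # 250.0000142121733
print(timing_report(200.0, 20.0, 0.5))
# {'pulses_per_pixel': 4, 'frame_period_s': 1.31072,
#  'frame_rate_hz': 0.7629..., 'stretched_pulse_width_us': 2.5,
#  'samples_per_window': 5000}
```

The gel reference A-scan arrives 2.6 µs (delay line) + r/c after the laser
trigger and its gated peak-to-peak of 194 mV against the 20 mV noise RMS is
the instrument's worked 9.7:1 signal-to-noise ratio. The depth sweep fit
shows the photoacoustic signal decaying with the 250 µm excitation-limited
1/e length, while `run_dual_channel_depth()` shows the fluorescence channel
crossing its noise floor near 400 µm and the photoacoustic channel keeping
SNR > 5 at 1000 µm in an organoid-like sphere.

A command-line interface wraps the same functions:

```sh
pam3p timing                       # pulses/pixel, frame rate, pulse stretcher
pam3p budget                       # optical/acoustic depth budget
pam3p analyze power|concentration|depth|dual-depth
pam3p simulate --config cfg.yaml --out traces.h5
pam3p reconstruct traces.h5 --out image.tiff --deconvolve-iters 10
pam3p denoise trace.csv --band 50 90
pam3p dff rois.csv
```

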