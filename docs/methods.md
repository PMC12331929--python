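# Methods

This note documents the forward model, its parameters, the design choices
made where the physics or the instrument description left the design open,
and what the synthetic phantoms do and do not emulate.

## Coordinate and geometry conventions

The specimen surface facing the objective is z = 0; z increases toward the
transducer below the specimen. Voxel centers sit at (i + 0.5)·pitch. The
specimen rests above the transducer's delay line with a standoff of
0.5 mm (back-computed from a 330 ns sample-to-sensor transit at 1500 m/s;
the 6 mm well-depth geometry is available by overriding
`TransducerModel.standoff_mm`). For a focus at depth z the acoustic tissue
path is (thickness − z) and the element distance r = standoff + path.

## Excitation and focal volume

The focal intensity profile is a separable Gaussian (optionally an Airy
lateral profile) calibrated so that the **heated** profile — intensity to
the photon order n — has FWHM 2.2 µm laterally and 30 µm axially at NA 0.4
and 1300 nm, scaling as λ/NA and λ/NA². The printed widths are pinned to
the heated profile (the n-th power of intensity); the alternative reading
(widths of the intensity itself) would shrink the acoustic source by √3.
Peak pulse intensity comes from I_peak = E_p/(τ_p·A_eff) with
A_eff = πw_xy²/(4 ln 2); temporal pulse-shape factors are absorbed into a
single calibrated scale (below).

Per-pulse heat density: H = C·N_A·σ₃(φTÎ)ⁿτ_p·η_h·n·E_ph, exactly linear
in C and proportional to Pⁿ. The three-photon cross-section
σ₃ = 4.29 × 10⁻⁸⁵ is treated as an opaque scale factor (its units are not
separately meaningful here); η_h = 1 − Φλ_ex/(nλ_em) ≈ 0.952 is the
minimal energy-conserving heat fraction. Single-chromophore fields only;
FAD, collagen and tryptophan are not modeled.

### Depth attenuation

Media store the **intensity** 1/e attenuation length L_I; an n-photon
signal consequently decays with 1/e length L_I/n. The brain preset uses
L_I = 750 µm so the photoacoustic signal reproduces the measured 250 µm
1/e extinction length. The alternative reading — 250 µm as the 1300 nm
*laser* attenuation length — conflicts with that measurement and is
available by configuring L_I = 250 µm directly. The fluorescence channel
additionally decays with the emission extinction length L_em = 50 µm.
Medium presets (config-overridable; gel and organoid optical constants are
plausible placeholders, not measured values):

| preset   | L_I (µm) | L_em (µm) | c (m/s) | a (dB/(mm·MHz)) |
|----------|---------:|----------:|--------:|-----------------:|
| gel      | 10⁶      | 10⁶       | 1500    | 0.002            |
| brain    | 750      | 50        | 1540    | 0.0148           |
| organoid | 1125     | 50        | 1540    | 0.0148           |

The organoid preset's L_I is 1.5× the brain value because such engineered
tissue scatters and absorbs less than brain.

## Acoustic source and propagation

Initial pressure p₀ = Γ·H with Γ = 0.2 (water-like). The far-field element
trace is a superposition of per-voxel unit-peak derivative-of-Gaussian
wavelets with 1/r decay and arrival delays r_v/c. The wavelet timescale is
set by the **transverse** heated FWHM: the axial 30 µm extent is already
encoded in the ~8.5 ns arrival-time spread of the superposition, and each
thin axial sheet radiates a pulse set by its transverse confinement.
Deriving the wavelet width from the axial extent instead would count that
dimension twice and push essentially all spectral energy below the
transducer band. With this choice the emitted spectrum rolls off from
~19 MHz with a usable tail through the 68–150 MHz effective band, and the
transduced gel A-scan peaks near 48 MHz on the CWT scalogram — between the
measured 60–90 MHz band and the long-wavelength limit of the
arrival-spread envelope; the exact placement is model-dependent and is
reported, not asserted. A full-wave (k-Wave-style) solver and the piston
diffraction integral are deliberately out of scope; the analytic source
keeps the chain fast, linear and testable.

Frequency-dependent attenuation multiplies the spectrum by
10^(−a·d·f^b/20); the default a = 0.0148 dB/(mm·MHz), b = 1 reproduces the
−4 dB budget through 2.7 mm near 100 MHz (the amplitude-dB convention; the
accompanying "44%" figure is inconsistent with −4 dB under either
convention and was not adopted). The element acceptance is a Gaussian
aperture weight with 100 µm half-amplitude diameter, modeled as
distance-independent over the millimeter-scale standoffs used here.

## Transduction and absolute scale

The voltage chain is: delay line (2.6 µs), transducer passband (68–197 MHz
for the 125 MHz unit, 45–122 MHz for the 75 MHz unit) composed with the
receiver's 20 MHz high-pass and 150 MHz low-pass (2nd-order Butterworth
each, applied zero-phase so arrival times are preserved), sensitivity
140 µV/Pa, 63 dB gain (×1412.5), additive white Gaussian noise of 20 mV
RMS, sampled at 2 GHz.

One dimensionless collection-efficiency constant
(`experiments.COLLECTION_EFFICIENCY`) anchors the absolute scale: it is
calibrated once so the 10 mM gel reference at 25 mW yields a gated
peak-to-peak of 194 mV, i.e. the worked 9.7:1 SNR against the 20 mV noise
floor. It absorbs the opaque σ₃ units, temporal pulse-shape factors and
the out-of-band spectral losses of the source model. All relative claims
(power law, concentration linearity, depth decay, channel ordering) are
independent of it.

## Trace processing

* **CWT / iCWT**: analytic complex Morlet (`cmor1.5-1.0`), 32 voices per
  octave on a log-spaced frequency grid (≤ 5% frequency-resolution error
  at 88 MHz / 2 GHz). Band-limited denoising reconstructs from
  coefficients inside [f_lo, f_hi]; the reconstruction constant is fixed
  per call by round-tripping a probe tone at the geometric band center,
  which keeps in-band amplitudes within 10% and makes the operation
  idempotent to < 5% RMS. Default band 50–90 MHz (the instrument used
  50–70, 50–90 and 60–90 MHz variants; the band is a flag).
* **Gating**: default statistic is peak-to-peak, robust to the bipolar
  bandpassed pulse shape; the gate defaults to a 0.2 µs window centered on
  t_delay + r/c. Arrival times are measured as the centroid of the squared
  Hilbert envelope over its half-maximum support.
* **Fits**: power-law and exponential fits are ordinary least squares on
  log-transformed data; an exponential fit whose total decay over the
  sampled range is below 1% is flagged non-decaying (infinite length when
  the slope is non-negative).
* **ΔF/F**: per-ROI baseline is the mean of the lowest decile of samples;
  ΔF/F = (F − baseline)/baseline; Pearson pairwise correlation matrix on
  the ΔF/F traces. Linear photobleaching detrend is available but off by
  default because the instrument's normalization formula is ambiguous.
  ROI segmentation is out of scope; traces arrive as CSV columns.

## Image formation

Pixel value = mean over the pixel's laser pulses (floor(dwell × rep rate),
4 at 20 µs / 200 kHz) of the gated peak-to-peak; raster order is row-major
and unidirectional; flyback is ignored, so 256×256 at 20 µs gives
1.31 s/frame = 0.76 frame/s exactly as printed. Frame averaging is a
pixelwise mean (√n noise reduction). Deconvolution is Richardson–Lucy
(10 iterations default) with the lateral heated Gaussian as PSF;
total intensity is conserved within 1% for interior content.

## In-silico experiments

* **Concentration series** (1, 2, 4.6, 9.3, 18.75 mM) and **power series**
  (6–25 mW) run point measurements on the standard 3 mm × 1.58 mm gel
  cylinder with the focus 100 µm deep; the chain's exact linearity and
  cubic power dependence give R = 1.000 and exponent 3.000 noiselessly.
  Series noise is applied at amplitude level with a per-seed unit-normal
  vector scaled by the RMS, so noise ladders share a common realization
  and the R-degradation is monotone in the RMS.
* **Depth sweep** (0–700 µm in 100 µm steps, 53 mW, brain preset, 1 mm
  slab): the focus is offset from the surface by 2w_z so the focal volume
  stays embedded at the shallowest nominal depth (a constant offset leaves
  the fitted 1/e length untouched), and the acoustic path is held at its
  z = 0 value — the instrument gates a fixed window after the trigger, and
  holding the path isolates the excitation attenuation that the
  exponential fit describes (with a z-dependent path the 1/r and tissue
  terms would bias the fitted length by ~30%). "10% noise" is
  multiplicative log-normal (σ = 0.1) on the gated amplitudes, emulating
  residual shot-to-shot variation after pulse averaging.
* **Dual-channel depth** (organoid preset, 1.2 mm sphere, 10 mM, 53 mW):
  the optical floor defaults to e⁻⁸ of the surface signal, which places
  the fluorescence floor-crossing near 400 µm when L_em = 50 µm dominates
  (the exact model value is ~353 µm because the excitation term adds
  3/L_I to the decay rate); the photoacoustic channel's floor is the 20 mV
  noise RMS and its crossing extrapolates to ~1.7 mm — the channel
  ordering, not the exact depths, is the claim under test.
* **Timing / budget calculators** are closed-form: stretched pulse width
  duty/f_rep (2.5 µs at 50% / 200 kHz), pulses per pixel, frame rate,
  optical escape exp(−d/L_em) (3.5 × 10⁻²⁴ through 2.7 mm at 50 µm) and
  acoustic dB loss.

A single global seed fans out to per-stage child seeds through
`numpy.random.SeedSequence`, making every experiment bit-reproducible.

## What the phantoms do and do not emulate

Phantoms provide uniform gels, spheres with radial concentration profiles,
random non-overlapping spherical "cells" and hair-like fiducial cylinders —
enough to give the chain known ground truth for localization, linearity
and depth behavior. They have no cytoarchitecture, vasculature, NADH
compartmentalization or metabolic dynamics (activity-like ROI traces are
synthesized at the trace level, not in the phantom), and the fiducial
channel is a generic second contrast, not third-harmonic physics. Passing
tests therefore validate the measurement chain and processing, not
biological realism. Problem sizes in the tests and the acceptance script
(e.g. 16×16-pixel scans, 8-point depth grids, ~0.5 µm focal-field pitch)
are chosen as the smallest grids on which the assertions are
discretization-insensitive.

## Known limitations

* Scalar Gaussian/Airy focal fields only: no vectorial high-NA theory,
  dispersion or self-focusing; no pre-chirp modeling.
* No shear waves, reflections, layered media, transducer ringing beyond
  the specified bandpass, or piston diffraction; the acceptance aperture
  is phenomenological.
* Absolute voltages rest on one calibration point; only relative
  quantities are predictive.
* Measured-data figures of the real instrument (absolute voltages of
  specific specimens, uptake ratios, region-specific NADH levels,
  organoid-age differences) are outside what synthetic phantoms can
  reproduce and are not claimed.
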