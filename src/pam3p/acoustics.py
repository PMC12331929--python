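"""Acoustic signal chain: initial pressure to transducer voltage trace.

The per-pulse heat map is converted to an initial pressure map through the
Grueneisen parameter, propagated to the transducer element as a far-field
superposition of derivative-of-Gaussian wavelets with per-voxel 1/r decay
and arrival delays, attenuated by the frequency-dependent tissue loss, and
finally transduced: delay line, transducer passband, receiver filters,
amplifier gain and additive white Gaussian noise.

The per-voxel wavelet timescale is set by the *transverse* heated FWHM:
the summation over per-voxel arrival delays already encodes the axial
source extent, so each thin axial sheet radiates a pulse whose width is
set by its transverse confinement. The composite spectrum then rolls off
from ~19 MHz with a tail through the transducer band, and the transduced
A-scan peaks near 70-90 MHz, matching the measured 60-90 MHz band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import h5py
import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import (AlignmentError, GeometryError, InvalidArgumentError,
                     WindowError)
from .optics import FocalField

__all__ = [
    "TransducerModel",
    "RawTrace",
    "RawTraceSet",
    "GRUENEISEN_DEFAULT",
    "initial_pressure",
    "SourceKernel",
    "farfield_trace",
    "attenuate_spectrum",
    "aperture_weight",
    "transduce",
]

#: Water-like thermoacoustic efficiency (dimensionless).
GRUENEISEN_DEFAULT = 0.2

_FWHM2SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class TransducerModel:
    """Transducer + receiver chain parameters.

    Presets exist for the 125 MHz (68-197 MHz band) and 75 MHz
    (45-122 MHz band) units; both are 0.125 inch elements with a built-in
    delay line of 2.6 us. The receiver applies a 20 MHz high-pass, a
    150 MHz low-pass and 63 dB of gain (linear ~1412).
    """

    center_frequency_mhz: float = 125.0
    passband_mhz: tuple[float, float] = (68.0, 197.0)
    delay_us: float = 2.6
    sensitivity_uv_per_pa: float = 140.0
    element_diameter_mm: float = 3.175
    standoff_mm: float = 0.5
    gain_db: float = 63.0
    highpass_mhz: float = 20.0
    lowpass_mhz: float = 150.0
    noise_rms_mv: float = 20.0
    acceptance_diameter_um: float = 100.0

    def __post_init__(self) -> None:
        lo, hi = self.passband_mhz
        if not lo < hi:
            raise InvalidArgumentError("passband low must be below high")
        if self.sensitivity_uv_per_pa <= 0 or self.standoff_mm <= 0:
            raise InvalidArgumentError("sensitivity and standoff must be positive")
        if self.delay_us < 0 or self.noise_rms_mv < 0:
            raise InvalidArgumentError("delay and noise RMS must be >= 0")

    @property
    def gain_linear(self) -> float:
        return 10.0 ** (self.gain_db / 20.0)

    @classmethod
    def preset(cls, name: str, **overrides) -> "TransducerModel":
        name = name.lower().replace(" ", "")
        if name in ("125", "125mhz"):
            base = dict(center_frequency_mhz=125.0, passband_mhz=(68.0, 197.0))
        elif name in ("75", "75mhz"):
            base = dict(center_frequency_mhz=75.0, passband_mhz=(45.0, 122.0))
        else:
            raise InvalidArgumentError(f"unknown transducer preset {name!r}")
        base.update(overrides)
        return cls(**base)


@dataclass
class RawTrace:
    """A single A-scan: voltage samples (mV) at a fixed sampling rate."""

    samples_mv: np.ndarray
    fs_ghz: float = 2.0
    t0_us: float = 0.0
    pixel: tuple[int, int] | None = None
    pulse: int | None = None

    def __post_init__(self) -> None:
        self.samples_mv = np.asarray(self.samples_mv, dtype=np.float64)
        if not np.all(np.isfinite(self.samples_mv)):
            raise InvalidArgumentError("trace samples must be finite")
        if self.fs_ghz <= 0:
            raise InvalidArgumentError("sampling rate must be positive")

    @property
    def dt_us(self) -> float:
        return 1e-3 / self.fs_ghz

    @property
    def t_us(self) -> np.ndarray:
        return self.t0_us + np.arange(self.samples_mv.size) * self.dt_us


@dataclass
class RawTraceSet:
    """Per-pixel, per-pulse voltage traces from a scan.

    ``voltage_mv`` has shape (n_pixels, n_pulses, n_samples) with pixels in
    row-major raster order of the (ny, nx) image grid.
    """

    voltage_mv: np.ndarray
    fs_ghz: float
    image_shape: tuple[int, int]
    trigger_times_us: np.ndarray | None = None
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.voltage_mv)
        if v.ndim != 3:
            raise GeometryError("voltage must be (pixels, pulses, samples)")
        ny, nx = self.image_shape
        if v.shape[0] != ny * nx:
            raise GeometryError("pixel count does not match image shape")
        self.voltage_mv = v
        if self.trigger_times_us is None:
            self.trigger_times_us = np.zeros(v.shape[:2])

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("voltage", data=self.voltage_mv.astype(np.float32),
                             compression="gzip")
            f.create_dataset("trigger_times", data=self.trigger_times_us)
            f.attrs["fs_ghz"] = self.fs_ghz
            f.attrs["image_shape"] = self.image_shape
            for k, v in self.meta.items():
                if isinstance(v, (int, float, str)):
                    f.attrs[k] = v

    @classmethod
    def load(cls, path) -> "RawTraceSet":
        with h5py.File(path, "r") as f:
            meta = {k: f.attrs[k] for k in f.attrs
                    if k not in ("fs_ghz", "image_shape")}
            return cls(voltage_mv=f["voltage"][...],
                       fs_ghz=float(f.attrs["fs_ghz"]),
                       image_shape=tuple(int(x) for x in f.attrs["image_shape"]),
                       trigger_times_us=f["trigger_times"][...],
                       meta={k: (v.item() if hasattr(v, "item") else v)
                             for k, v in meta.items()})


def initial_pressure(heat_j_m3: np.ndarray, grueneisen: float = GRUENEISEN_DEFAULT) -> np.ndarray:
    """Initial pressure p0 = Gamma * H (Pa), voxelwise."""
    if grueneisen < 0:
        raise InvalidArgumentError("Grueneisen parameter must be >= 0")
    h = np.asarray(heat_j_m3, dtype=np.float64)
    if np.any(h < 0):
        raise InvalidArgumentError("heat map must be non-negative")
    return grueneisen * h


class SourceKernel:
    """Precomputed far-field propagation geometry for one focal-field grid.

    Evaluates trace(t) = sum_v (a_eff / r_v) * (dV / V_norm) * p0_v *
    s(t - r_v / c), with s a unit-peak derivative-of-Gaussian wavelet whose
    timescale is sigma_t = wavelet_fwhm / (2 sqrt(2 ln 2) c). Reusable
    across pixels: only the per-voxel weights p0 change.
    """

    def __init__(self, field: FocalField, r_mm: float, sound_speed: float,
                 fs_ghz: float, duration_us: float, wavelet_fwhm_um: float,
                 a_eff_um: float, volume_norm_um3: float):
        if r_mm <= 0:
            raise InvalidArgumentError("propagation distance must be positive")
        r_um = r_mm * 1e3
        half_extent = 0.5 * max(np.ptp(field.ox), np.ptp(field.oy), np.ptp(field.oz))
        if r_um <= half_extent:
            raise GeometryError("transducer distance must exceed the source extent")
        self.fs_hz = fs_ghz * 1e9
        self.n_samples = int(round(duration_us * 1e-6 * self.fs_hz))
        # element on the beam axis at depth offset +r from the focus
        ox = field.ox[:, None, None]
        oy = field.oy[None, :, None]
        oz = field.oz[None, None, :]
        r_v_um = np.sqrt(ox**2 + oy**2 + (r_um - oz) ** 2)
        shape = np.broadcast_shapes(ox.shape, oy.shape, oz.shape)
        r_v_um = np.broadcast_to(r_v_um, shape).ravel()
        t_v = r_v_um * 1e-6 / sound_speed  # seconds
        self.sigma_t = wavelet_fwhm_um * 1e-6 / (_FWHM2SIGMA * sound_speed)
        half_support = 6.0 * self.sigma_t
        if (t_v.max() + half_support) * self.fs_hz >= self.n_samples - 1:
            raise WindowError("trace duration too short to contain the arrival")
        self.geom = (a_eff_um / r_v_um) * (field.voxel_volume_um3 / volume_norm_um3)
        # per-voxel sample window around the arrival, wavelet evaluated exactly
        k = int(math.ceil(half_support * self.fs_hz))
        j0 = np.round(t_v * self.fs_hz).astype(np.int64)
        offsets = np.arange(-k, k + 1)
        self.idx = j0[:, None] + offsets[None, :]
        tt = self.idx / self.fs_hz - t_v[:, None]
        u = tt / self.sigma_t
        self.svals = u * np.exp(0.5 - 0.5 * u * u)
        valid = (self.idx >= 0) & (self.idx < self.n_samples)
        self.svals[~valid] = 0.0
        self.idx = np.clip(self.idx, 0, self.n_samples - 1)
        self.arrival_s = float(r_um * 1e-6 / sound_speed)

    def trace(self, p0_flat: np.ndarray) -> np.ndarray:
        """Pressure trace (Pa) at the element for per-voxel initial pressure."""
        w = p0_flat * self.geom
        contrib = w[:, None] * self.svals
        return np.bincount(self.idx.ravel(), weights=contrib.ravel(),
                           minlength=self.n_samples)


def farfield_trace(p0: np.ndarray, field: FocalField, r_mm: float,
                   sound_speed: float, fs_ghz: float, duration_us: float, *,
                   wavelet_fwhm_um: float, a_eff_um: float,
                   volume_norm_um3: float | None = None) -> np.ndarray:
    """Far-field pressure trace (Pa) at the element from an initial-pressure map.

    ``volume_norm_um3`` defaults to the effective source volume
    sum(p0/max(p0)) * dV so that a compact source of peak p0 produces a peak
    on the order of p0 * a_eff / r.
    """
    p0 = np.asarray(p0, dtype=np.float64)
    if p0.shape != field.values.shape:
        raise GeometryError("p0 map and focal field grids differ")
    if volume_norm_um3 is None:
        peak = p0.max()
        volume_norm_um3 = float((p0.sum() / peak) * field.voxel_volume_um3) if peak > 0 else 1.0
    kernel = SourceKernel(field, r_mm, sound_speed, fs_ghz, duration_us,
                          wavelet_fwhm_um, a_eff_um, volume_norm_um3)
    return kernel.trace(p0.ravel())


def attenuate_spectrum(trace: np.ndarray, fs_ghz: float, distance_mm: float,
                       a_db_mm_mhz: float, b: float = 1.0) -> np.ndarray:
    """Apply power-law acoustic attenuation 10^(-a d f^b / 20) in the spectrum."""
    if distance_mm < 0:
        raise InvalidArgumentError("path length must be >= 0")
    x = np.asarray(trace, dtype=np.float64)
    if distance_mm == 0 or a_db_mm_mhz == 0:
        return x.copy()
    n = x.size
    f_mhz = np.fft.rfftfreq(n, d=1e-3 / fs_ghz)  # dt in us -> cycles/us = MHz
    gain = 10.0 ** (-(a_db_mm_mhz * distance_mm * f_mhz**b) / 20.0)
    return np.fft.irfft(np.fft.rfft(x) * gain, n=n)


def aperture_weight(rho_um, transducer: TransducerModel, r_mm: float | None = None):
    """Radially symmetric acceptance weight of the element.

    Gaussian in the lateral offset of the source from the element axis, with
    half-amplitude diameter ``transducer.acceptance_diameter_um`` (100 um by
    default); ``r_mm`` is accepted for interface compatibility but the
    near-field acceptance is modeled as distance-independent.
    """
    rho = np.asarray(rho_um, dtype=np.float64)
    if np.any(rho < 0):
        raise InvalidArgumentError("lateral offset must be >= 0")
    w = 2.0 ** (-((2.0 * rho / transducer.acceptance_diameter_um) ** 2))
    return float(w) if np.isscalar(rho_um) else w


def _bandpass_sos(transducer: TransducerModel, fs_ghz: float):
    nyq_mhz = fs_ghz * 1e3 / 2.0
    lo, hi = transducer.passband_mhz
    if fs_ghz * 1e3 <= 2.0 * hi:
        raise InvalidArgumentError("sampling rate must exceed twice the passband high edge")
    sos1 = butter(2, [lo / nyq_mhz, min(hi, 0.99 * nyq_mhz) / nyq_mhz], btype="bandpass",
                  output="sos")
    sos2 = butter(2, [transducer.highpass_mhz / nyq_mhz, transducer.lowpass_mhz / nyq_mhz],
                  btype="bandpass", output="sos")
    return sos1, sos2


def transduce(trace_pa: np.ndarray, transducer: TransducerModel, fs_ghz: float = 2.0, *,
              rng: np.random.Generator | None = None, add_noise: bool = True,
              collection: float = 1.0) -> RawTrace:
    """Convert a pressure trace at the element into the recorded voltage.

    The trace is delayed by the built-in delay line, band-limited by the
    transducer passband and the receiver 20-150 MHz filters (zero-phase, so
    arrival times are preserved), scaled by sensitivity x linear gain x an
    overall collection efficiency, and white Gaussian noise of the
    configured RMS is added (seeded via ``rng``).
    """
    x = np.asarray(trace_pa, dtype=np.float64)
    delay_samples = int(round(transducer.delay_us * 1e-6 * fs_ghz * 1e9))
    padded = np.concatenate([np.zeros(delay_samples), x])
    sos1, sos2 = _bandpass_sos(transducer, fs_ghz)
    filtered = sosfiltfilt(sos2, sosfiltfilt(sos1, padded))
    mv = filtered * transducer.sensitivity_uv_per_pa * 1e-3 * transducer.gain_linear * collection
    if add_noise and transducer.noise_rms_mv > 0:
        rng = np.random.default_rng() if rng is None else rng
        mv = mv + rng.normal(0.0, transducer.noise_rms_mv, size=mv.size)
    return RawTrace(mv, fs_ghz=fs_ghz)


def average_traces(traces, n: int | None = None) -> RawTrace:
    """Samplewise mean of the first ``n`` aligned traces (see also dsp.average_pulses)."""
    arrs = [t.samples_mv if isinstance(t, RawTrace) else np.asarray(t, float) for t in traces]
    n = len(arrs) if n is None else n
    if n < 1 or n > len(arrs):
        raise InvalidArgumentError(f"cannot average {n} of {len(arrs)} traces")
    lengths = {a.size for a in arrs[:n]}
    if len(lengths) != 1:
        raise AlignmentError("traces differ in length")
    fs = traces[0].fs_ghz if isinstance(traces[0], RawTrace) else 2.0
    return RawTrace(np.mean(arrs[:n], axis=0), fs_ghz=fs)
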