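"""Image formation: scan timing, per-pixel gating/averaging, frame assembly,
frame averaging and Richardson-Lucy deconvolution.

Pixel values are the mean over that pixel's laser pulses of a gated
amplitude statistic (peak-to-peak by default) taken in a fixed window
after the laser trigger — the same bookkeeping the real-time acquisition
performs. Raster order is row-major and unidirectional; flyback is
ignored, so the frame period is simply pixels x lines x dwell.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import tifffile
from skimage.restoration import richardson_lucy

from .acoustics import RawTraceSet
from .dsp import gated_peak
from .errors import (CompletenessError, GeometryError, InvalidArgumentError)
from .optics import OpticsConfig

__all__ = [
    "ScanConfig",
    "PAImage",
    "pulses_per_pixel",
    "frame_period",
    "assemble_image",
    "frame_average",
    "psf_kernel",
    "deconvolve",
]


@dataclass
class ScanConfig:
    """Raster-scan acquisition parameters."""

    pixels: tuple[int, int] = (256, 256)  # (ny lines, nx pixels per line)
    dwell_us: float = 20.0
    rep_rate_khz: float = 200.0
    fov_um: float = 230.0
    frame_averages: int = 4
    gate_start_us: float | None = None  # default: delay + r/c, set by the simulator
    gate_width_us: float = 0.2
    focus_depth_um: float = 100.0

    def __post_init__(self) -> None:
        ny, nx = self.pixels
        if ny < 1 or nx < 1:
            raise InvalidArgumentError("pixel counts must be >= 1")
        if self.dwell_us <= 0 or self.rep_rate_khz <= 0 or self.fov_um <= 0:
            raise InvalidArgumentError("dwell, rep rate and FOV must be positive")
        if self.dwell_us * 1e-6 * self.rep_rate_khz * 1e3 < 1.0 - 1e-9:
            raise InvalidArgumentError("dwell x rep rate must give >= 1 pulse per pixel")
        if self.gate_width_us <= 0:
            raise InvalidArgumentError("gate width must be positive")

    @property
    def pixel_pitch_um(self) -> float:
        return self.fov_um / self.pixels[1]


@dataclass
class PAImage:
    """Reconstructed 2-D image (mV pixel values) with provenance."""

    data: np.ndarray
    pixel_pitch_um: float
    channel: str = "PA"
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=np.float32)
        if d.ndim != 2:
            raise GeometryError("image must be 2-D")
        if not np.all(np.isfinite(d)):
            raise InvalidArgumentError("image pixels must be finite")
        if self.pixel_pitch_um <= 0:
            raise InvalidArgumentError("pixel pitch must be positive")
        self.data = d

    def to_tiff(self, path) -> None:
        """32-bit float TIFF with pitch/provenance in the description tag + sidecar JSON."""
        desc = json.dumps({"pixel_pitch_um": self.pixel_pitch_um,
                           "channel": self.channel, **self.meta})
        tifffile.imwrite(path, self.data, description=desc)
        with open(str(path) + ".json", "w") as f:
            f.write(desc)

    @classmethod
    def from_tiff(cls, path) -> "PAImage":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
        meta = json.loads(desc) if desc else {}
        pitch = meta.pop("pixel_pitch_um", 1.0)
        channel = meta.pop("channel", "PA")
        return cls(data, pitch, channel, meta)


def pulses_per_pixel(scan: ScanConfig) -> int:
    """Laser pulses landing in one pixel dwell: floor(dwell x rep rate)."""
    n = int(math.floor(scan.dwell_us * 1e-6 * scan.rep_rate_khz * 1e3 + 1e-9))
    if n < 1:
        raise InvalidArgumentError("configuration yields < 1 pulse per pixel")
    return n


def frame_period(scan: ScanConfig) -> tuple[float, float]:
    """(seconds per frame, frames per second); flyback ignored."""
    ny, nx = scan.pixels
    period = ny * nx * scan.dwell_us * 1e-6
    return period, 1.0 / period


def assemble_image(raw: RawTraceSet, scan: ScanConfig,
                   statistic: str = "peak_to_peak") -> PAImage:
    """Gate + average each pixel's pulses into an image.

    Pixel value = mean over the pixel's pulses of ``gated_peak`` in the scan
    gate. The gate defaults to the trace set's recorded gate (from the
    simulator) when ``scan.gate_start_us`` is None.
    """
    ny, nx = scan.pixels
    npix, npulse, nsamp = raw.voltage_mv.shape
    if npix != ny * nx:
        raise CompletenessError(
            f"trace set has {npix} pixels, scan expects {ny * nx}")
    need = pulses_per_pixel(scan)
    if npulse < need:
        raise CompletenessError(f"need >= {need} pulses per pixel, got {npulse}")
    gate_start = scan.gate_start_us
    if gate_start is None:
        gate_start = float(raw.meta.get("gate_start_us", 0.0))
    dt_us = 1e-3 / raw.fs_ghz
    i0 = int(round(gate_start / dt_us))
    i1 = int(round((gate_start + scan.gate_width_us) / dt_us))
    if i0 < 0 or i1 > nsamp:
        raise CompletenessError("gate window outside the recorded traces")
    seg = raw.voltage_mv[:, :need, i0:i1].astype(np.float64)
    if statistic == "peak_to_peak":
        vals = seg.max(axis=2) - seg.min(axis=2)
    elif statistic == "max_abs":
        vals = np.abs(seg).max(axis=2)
    elif statistic == "mean_abs":
        vals = np.abs(seg).mean(axis=2)
    else:
        raise InvalidArgumentError(f"unknown statistic {statistic!r}")
    img = vals.mean(axis=1).reshape(ny, nx)
    meta = {"statistic": statistic, "pulses_averaged": need,
            "gate_start_us": gate_start, "gate_width_us": scan.gate_width_us,
            **{k: v for k, v in raw.meta.items() if isinstance(v, (int, float, str))}}
    return PAImage(img, scan.pixel_pitch_um, channel="PA", meta=meta)


def frame_average(frames) -> PAImage:
    """Pixelwise mean of repeated frames of identical geometry."""
    frames = list(frames)
    if not frames:
        raise InvalidArgumentError("no frames to average")
    shape = frames[0].data.shape
    pitch = frames[0].pixel_pitch_um
    for f in frames[1:]:
        if f.data.shape != shape or f.pixel_pitch_um != pitch:
            raise GeometryError("frames differ in shape or pitch")
    data = np.mean([f.data for f in frames], axis=0)
    meta = {"frame_average_n": len(frames),
            "source_frames": [f.meta.get("frame_id", i) for i, f in enumerate(frames)]}
    return PAImage(data, pitch, channel=frames[0].channel, meta={**frames[0].meta, **meta})


def psf_kernel(optics: OpticsConfig, pixel_pitch_um: float,
               truncate_fwhm: float = 2.0) -> np.ndarray:
    """Normalized 2-D Gaussian kernel of the lateral heated profile."""
    if pixel_pitch_um <= 0:
        raise InvalidArgumentError("pixel pitch must be positive")
    w = optics.w_xy_um
    half = max(1, int(math.ceil(truncate_fwhm * w / pixel_pitch_um)))
    ax = np.arange(-half, half + 1) * pixel_pitch_um
    g = np.exp(-4.0 * math.log(2.0) * (ax / w) ** 2)
    k = g[:, None] * g[None, :]
    return k / k.sum()


def deconvolve(image: PAImage, psf: np.ndarray, iterations: int = 10) -> PAImage:
    """Richardson-Lucy deconvolution (non-negative, approximately flux-conserving)."""
    psf = np.asarray(psf, dtype=np.float64)
    if psf.sum() <= 0 or np.any(psf < 0):
        raise InvalidArgumentError("psf must be non-negative with positive sum")
    psf = psf / psf.sum()
    data = image.data.astype(np.float64)
    if data.min() < 0:
        # round-off negatives are clipped silently; material ones get a warning
        if data.min() < -1e-9 * max(data.max(), 1e-300):
            warnings.warn("negative pixels clipped to zero before deconvolution",
                          stacklevel=2)
        data = np.clip(data, 0.0, None)
    scale = data.max()
    if scale == 0:
        return PAImage(data, image.pixel_pitch_um, image.channel,
                       {**image.meta, "deconvolved": True})
    dec = richardson_lucy(data / scale, psf, num_iter=iterations, clip=False)
    dec = np.clip(dec, 0.0, None) * scale
    return PAImage(dec, image.pixel_pitch_um, image.channel,
                   {**image.meta, "deconvolved": True, "rl_iterations": iterations})
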