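"""Synthetic specimens with known ground truth.

A :class:`Phantom` is a 3-D voxel grid of chromophore concentration (mM)
plus the optical and acoustic bulk properties of the embedding medium.
Generators produce the specimen types used on the instrument: uniform
NADH gel cylinders, spherical cerebral-organoid-like bodies, fields of
cells, and hair-like fiducial fibers.

Coordinate convention: z = 0 at the specimen top surface (objective side),
z increases toward the transducer below the specimen. Voxel centers sit at
(i + 0.5) * pitch along every axis; arrays are indexed ``[ix, iy, iz]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable

import h5py
import numpy as np
import tifffile

from .errors import GeometryError, InvalidArgumentError, PlacementError

__all__ = [
    "Phantom",
    "MEDIA",
    "make_gel_cylinder",
    "make_organoid",
    "make_cell_field",
    "add_fiducial_fiber",
    "save_phantom",
    "load_phantom",
]

#: Bulk-medium presets. ``attenuation_length_um`` is the 1/e length of the
#: excitation *intensity* (L_I); the n-photon signal then decays with
#: 1/e length L_I / n. ``emission_length_um`` is the 1/e extinction length
#: of the ~450 nm fluorescence (L_em). Acoustic attenuation follows
#: a * d_mm * f_MHz**b in dB. The gel preset is optically transparent with
#: water-like acoustics; the organoid preset scatters/absorbs less than
#: brain tissue (L_I 1.5x longer).
MEDIA: dict[str, dict[str, float]] = {
    "gel": dict(
        attenuation_length_um=1.0e6,
        emission_length_um=1.0e6,
        sound_speed=1500.0,
        acoustic_attenuation=0.002,
        acoustic_exponent=1.0,
    ),
    "brain": dict(
        attenuation_length_um=750.0,
        emission_length_um=50.0,
        sound_speed=1540.0,
        acoustic_attenuation=0.0148,
        acoustic_exponent=1.0,
    ),
    "organoid": dict(
        attenuation_length_um=1125.0,
        emission_length_um=50.0,
        sound_speed=1540.0,
        acoustic_attenuation=0.0148,
        acoustic_exponent=1.0,
    ),
}


@dataclass
class Phantom:
    """Voxelized specimen.

    Attributes
    ----------
    concentration:
        Chromophore concentration per voxel, mM, shape ``(nx, ny, nz)``.
    pitch_um:
        Isotropic voxel pitch in micrometers.
    attenuation_length_um:
        1/e attenuation length of the excitation intensity, L_I (um).
    emission_length_um:
        1/e extinction length of the fluorescence emission, L_em (um).
    sound_speed:
        Speed of sound in m/s.
    acoustic_attenuation, acoustic_exponent:
        Power-law acoustic attenuation a (dB / (mm * MHz**b)) and b.
    medium:
        Name of the preset the constants came from ("custom" otherwise).
    """

    concentration: np.ndarray
    pitch_um: float
    attenuation_length_um: float
    emission_length_um: float
    sound_speed: float
    acoustic_attenuation: float
    acoustic_exponent: float = 1.0
    medium: str = "custom"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.concentration)
        if c.ndim != 3 or min(c.shape) < 1:
            raise GeometryError("concentration grid must be 3-D with >=1 voxel per axis")
        if not np.all(np.isfinite(c)) or c.min() < 0:
            raise InvalidArgumentError("concentration must be finite and non-negative")
        if self.pitch_um <= 0:
            raise InvalidArgumentError("voxel pitch must be positive")
        if self.attenuation_length_um <= 0 or self.emission_length_um <= 0:
            raise InvalidArgumentError("optical lengths must be positive")
        if self.sound_speed <= 0:
            raise InvalidArgumentError("sound speed must be positive")
        if self.acoustic_attenuation < 0:
            raise InvalidArgumentError("acoustic attenuation must be non-negative")
        self.concentration = c.astype(np.float32, copy=False)

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.concentration.shape)  # type: ignore[return-value]

    @property
    def thickness_um(self) -> float:
        """Specimen extent along z (top surface to bottom), um."""
        return self.shape[2] * self.pitch_um

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (um) along one axis."""
        n = self.shape[axis]
        return (np.arange(n) + 0.5) * self.pitch_um

    def sample(self, x_um: np.ndarray, y_um: np.ndarray, z_um: np.ndarray) -> np.ndarray:
        """Nearest-voxel concentration at arbitrary points; 0 outside the grid."""
        p = self.pitch_um
        ix = np.floor(np.asarray(x_um) / p).astype(np.int64)
        iy = np.floor(np.asarray(y_um) / p).astype(np.int64)
        iz = np.floor(np.asarray(z_um) / p).astype(np.int64)
        nx, ny, nz = self.shape
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (iz >= 0) & (iz < nz)
        out = np.zeros(np.broadcast(ix, iy, iz).shape, dtype=np.float64)
        out[inside] = self.concentration[ix[inside], iy[inside], iz[inside]]
        return out


def _medium_kwargs(medium: str) -> dict[str, float]:
    try:
        return dict(MEDIA[medium])
    except KeyError:  # pragma: no cover - defensive
        raise InvalidArgumentError(f"unknown medium preset {medium!r}") from None


def make_gel_cylinder(
    concentration_mm: float,
    diameter_mm: float = 3.0,
    height_mm: float = 1.58,
    pitch_um: float = 10.0,
    medium: str = "gel",
) -> Phantom:
    """Uniform chromophore gel in a cylindrical mold.

    Defaults follow the standard sample geometry: 3 mm diameter, 1.58 mm
    height. Concentration is uniform inside the cylinder and zero outside
    its bounding box corners.
    """
    if concentration_mm < 0:
        raise InvalidArgumentError("concentration must be >= 0")
    if diameter_mm <= 0 or height_mm <= 0 or pitch_um <= 0:
        raise InvalidArgumentError("cylinder geometry must be positive")
    d_um, h_um = diameter_mm * 1e3, height_mm * 1e3
    nx = int(np.ceil(d_um / pitch_um))
    nz = int(np.ceil(h_um / pitch_um))
    x = (np.arange(nx) + 0.5) * pitch_um - d_um / 2.0
    rho2 = x[:, None] ** 2 + x[None, :] ** 2
    disk = rho2 <= (d_um / 2.0) ** 2
    grid = np.where(disk[:, :, None], np.float32(concentration_mm), np.float32(0.0))
    grid = np.broadcast_to(grid, (nx, nx, nz)).copy()
    return Phantom(grid, pitch_um, medium=medium, **_medium_kwargs(medium),
                   meta={"kind": "gel_cylinder", "diameter_mm": diameter_mm,
                         "height_mm": height_mm, "concentration_mm": concentration_mm})


def make_organoid(
    diameter_mm: float = 1.2,
    concentration_profile: float | Callable[[np.ndarray], np.ndarray] = 1.0,
    pitch_um: float = 10.0,
    medium: str = "organoid",
) -> Phantom:
    """Spherical organoid-like specimen.

    ``concentration_profile`` is either a scalar (uniform mM) or a callable
    mapping radius (um, array) to mM; it must be non-negative.
    """
    if diameter_mm <= 0 or pitch_um <= 0:
        raise InvalidArgumentError("organoid geometry must be positive")
    d_um = diameter_mm * 1e3
    n = int(np.ceil(d_um / pitch_um))
    x = (np.arange(n) + 0.5) * pitch_um - d_um / 2.0
    r = np.sqrt(x[:, None, None] ** 2 + x[None, :, None] ** 2 + x[None, None, :] ** 2)
    if callable(concentration_profile):
        prof = np.asarray(concentration_profile(r), dtype=np.float64)
    else:
        prof = np.full_like(r, float(concentration_profile))
    if np.any(prof < 0):
        raise InvalidArgumentError("concentration profile must be non-negative")
    grid = np.where(r <= d_um / 2.0, prof, 0.0).astype(np.float32)
    return Phantom(grid, pitch_um, medium=medium, **_medium_kwargs(medium),
                   meta={"kind": "organoid", "diameter_mm": diameter_mm})


def make_cell_field(
    n_cells: int,
    cell_diameter_um: float = 10.0,
    intra_mm: float = 5.0,
    background_mm: float = 0.5,
    field_um: float = 100.0,
    pitch_um: float = 2.0,
    seed: int = 0,
    depth_um: float | None = None,
    medium: str = "brain",
    max_tries_per_cell: int = 200,
) -> Phantom:
    """Random field of non-overlapping spherical cells in a background medium.

    Cells are spheres of ``cell_diameter_um`` at ``intra_mm`` concentration on
    a ``background_mm`` background; positions are drawn reproducibly from
    ``seed`` and rejected on overlap. Raises :class:`PlacementError` if the
    field cannot host ``n_cells`` after bounded retries.
    """
    if n_cells < 0:
        raise InvalidArgumentError("n_cells must be >= 0")
    if not (intra_mm >= background_mm >= 0):
        raise InvalidArgumentError("require intra >= background >= 0")
    if cell_diameter_um <= 0 or field_um <= 0 or pitch_um <= 0:
        raise InvalidArgumentError("geometry must be positive")
    depth_um = field_um if depth_um is None else depth_um
    nx = int(np.ceil(field_um / pitch_um))
    nz = int(np.ceil(depth_um / pitch_um))
    grid = np.full((nx, nx, nz), np.float32(background_mm))
    rng = np.random.default_rng(seed)
    radius = cell_diameter_um / 2.0
    centers: list[np.ndarray] = []
    lo = radius
    hix = field_um - radius
    hiz = depth_um - radius
    if n_cells > 0 and (hix <= lo or hiz <= lo):
        raise PlacementError("field too small for even one cell")
    for _ in range(n_cells):
        for _try in range(max_tries_per_cell):
            c = np.array([rng.uniform(lo, hix), rng.uniform(lo, hix), rng.uniform(lo, hiz)])
            if all(np.linalg.norm(c - p) >= cell_diameter_um for p in centers):
                centers.append(c)
                break
        else:
            raise PlacementError(
                f"could not place cell {len(centers) + 1}/{n_cells} without overlap")
    if centers:
        ax = (np.arange(nx) + 0.5) * pitch_um
        az = (np.arange(nz) + 0.5) * pitch_um
        for c in centers:
            r2 = ((ax - c[0])[:, None, None] ** 2
                  + (ax - c[1])[None, :, None] ** 2
                  + (az - c[2])[None, None, :] ** 2)
            grid[r2 <= radius**2] = intra_mm
    return Phantom(grid, pitch_um, medium=medium, **_medium_kwargs(medium),
                   meta={"kind": "cell_field", "seed": seed,
                         "cell_centers_um": [list(map(float, c)) for c in centers],
                         "cell_diameter_um": cell_diameter_um})


def add_fiducial_fiber(
    phantom: Phantom,
    p0_um: tuple[float, float, float],
    p1_um: tuple[float, float, float],
    diameter_um: float = 80.0,
    contrast_mm: float = 10.0,
) -> Phantom:
    """Overwrite a cylindrical fiber (hair fiducial) along segment p0->p1.

    Returns a new phantom; voxels within ``diameter_um/2`` of the segment are
    set to ``contrast_mm``.
    """
    a = np.asarray(p0_um, dtype=np.float64)
    b = np.asarray(p1_um, dtype=np.float64)
    ab = b - a
    length = np.linalg.norm(ab)
    if length == 0:
        raise InvalidArgumentError("fiber line has zero length")
    if diameter_um <= 0 or contrast_mm < 0:
        raise InvalidArgumentError("fiber diameter must be > 0 and contrast >= 0")
    nx, ny, nz = phantom.shape
    ax = phantom.axis_centers(0)
    ay = phantom.axis_centers(1)
    az = phantom.axis_centers(2)
    X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1) - a
    t = np.clip(pts @ ab / length**2, 0.0, 1.0)
    closest = t[..., None] * ab
    dist2 = np.sum((pts - closest) ** 2, axis=-1)
    mask = dist2 <= (diameter_um / 2.0) ** 2
    if not mask.any():
        raise GeometryError("fiber does not intersect the phantom grid")
    grid = phantom.concentration.copy()
    grid[mask] = contrast_mm
    return replace(phantom, concentration=grid,
                   meta={**phantom.meta, "fiducial": {"p0_um": list(map(float, a)),
                                                      "p1_um": list(map(float, b)),
                                                      "diameter_um": diameter_um,
                                                      "contrast_mm": contrast_mm}})


# -- serialization --------------------------------------------------------

def save_phantom(phantom: Phantom, path) -> None:
    """Write the phantom to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("concentration", data=phantom.concentration, compression="gzip")
        f.attrs["pitch_um"] = phantom.pitch_um
        f.attrs["attenuation_length_um"] = phantom.attenuation_length_um
        f.attrs["emission_length_um"] = phantom.emission_length_um
        f.attrs["sound_speed"] = phantom.sound_speed
        f.attrs["acoustic_attenuation"] = phantom.acoustic_attenuation
        f.attrs["acoustic_exponent"] = phantom.acoustic_exponent
        f.attrs["medium"] = phantom.medium
        f.attrs["meta_json"] = json.dumps(phantom.meta)


def load_phantom(path) -> Phantom:
    with h5py.File(path, "r") as f:
        return Phantom(
            concentration=f["concentration"][...],
            pitch_um=float(f.attrs["pitch_um"]),
            attenuation_length_um=float(f.attrs["attenuation_length_um"]),
            emission_length_um=float(f.attrs["emission_length_um"]),
            sound_speed=float(f.attrs["sound_speed"]),
            acoustic_attenuation=float(f.attrs["acoustic_attenuation"]),
            acoustic_exponent=float(f.attrs["acoustic_exponent"]),
            medium=str(f.attrs["medium"]),
            meta=json.loads(str(f.attrs.get("meta_json", "{}"))),
        )


def phantom_to_tiff(phantom: Phantom, path) -> None:
    """Export the concentration grid as a multi-page 32-bit float TIFF (z pages)."""
    stack = np.moveaxis(phantom.concentration.astype(np.float32), 2, 0)
    tifffile.imwrite(path, stack, metadata={"pitch_um": phantom.pitch_um,
                                            "axes_order": "ZXY"})
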