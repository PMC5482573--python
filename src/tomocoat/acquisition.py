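"""Tilt-series simulation and weighted back-projection reconstruction.

Models the acquisition used for coated-vesicle tomography: a dose-symmetric
tilt scheme over ±60° in 3° steps, ~85 e/Å² total exposure spread uniformly
over the tilts in acquisition order, per-series defocus in the −2 to −5 µm
range, an oscillatory phase-contrast transfer function, exposure-dependent
low-pass ("dose") filtering, and ramp-weighted back-projection about a fixed
y tilt axis.  The limited tilt range leaves a missing wedge in Fourier
space; :func:`wedge_mask` builds the corresponding weight volumes used by
the constrained-correlation alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .core import DensityMap, WedgeSpec
from .geometry import rotation_about_axis, transform_volume

__all__ = [
    "TiltSeries",
    "CTFParams",
    "DoseFilterParams",
    "dose_symmetric_order",
    "project_scene",
    "dose_filter",
    "ctf_correct",
    "reconstruct_wbp",
    "wedge_mask",
    "apply_wedge_filter",
]


@dataclass(frozen=True)
class CTFParams:
    """Microscope optics for the contrast transfer function.

    Defaults: 300 kV, Cs 2.7 mm, 7% amplitude contrast.
    """

    voltage_kv: float = 300.0
    cs_mm: float = 2.7
    amplitude_contrast: float = 0.07

    @property
    def wavelength(self) -> float:
        """Relativistic electron wavelength in Å."""
        v = self.voltage_kv * 1e3
        return 12.2639 / np.sqrt(v + 0.97845e-6 * v * v)


@dataclass(frozen=True)
class DoseFilterParams:
    """Critical-exposure curve Ne(k) = a * k**b + c, k in 1/Å.

    Defaults are the published exposure-filtering constants
    (a=0.245, b=-1.665, c=2.81).
    """

    a: float = 0.245
    b: float = -1.665
    c: float = 2.81

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b < 0 and self.c > 0):
            raise ValueError("require a > 0, b < 0, c > 0")

    def critical_exposure(self, k: np.ndarray) -> np.ndarray:
        k = np.asarray(k, dtype=float)
        with np.errstate(divide="ignore"):
            return np.where(k > 0, self.a * np.power(np.maximum(k, 1e-30), self.b) + self.c, np.inf)


@dataclass
class TiltSeries:
    """A stack of projection images with per-image acquisition metadata.

    ``acquisition_order[i]`` is the time rank of image ``i`` (0 = first
    exposure); ``accumulated_dose[i]`` is the total e/Å² deposited up to and
    including that image, so it is non-decreasing along acquisition order.
    """

    images: np.ndarray
    tilt_angles: np.ndarray
    acquisition_order: np.ndarray
    accumulated_dose: np.ndarray
    defocus_um: np.ndarray
    pixel_size: float
    ctf: CTFParams | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.tilt_angles = np.asarray(self.tilt_angles, dtype=float)
        n = len(self.images)
        if len(self.tilt_angles) != n:
            raise ValueError("len(images) != len(tilt_angles)")
        if len(np.unique(self.tilt_angles)) != n:
            raise ValueError("tilt angles must be unique")
        dose_in_time = np.asarray(self.accumulated_dose)[np.argsort(self.acquisition_order)]
        if np.any(np.diff(dose_in_time) < -1e-9):
            raise ValueError("accumulated dose must be non-decreasing in acquisition order")

    @property
    def wedge(self) -> WedgeSpec:
        return WedgeSpec(float(self.tilt_angles.min()), float(self.tilt_angles.max()))


def dose_symmetric_order(max_tilt: float, step: float) -> list[float]:
    """Dose-symmetric tilt ordering: 0, +s, -s, -2s, +2s, +3s, -3s, ...

    Starts at zero and alternates sides in groups of two with increasing
    magnitude, so low-tilt (high-value) images receive the least exposure.
    The list index is the dose rank.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    n_side = max_tilt / step
    if abs(n_side - round(n_side)) > 1e-9:
        raise ValueError(f"max_tilt {max_tilt} is not a multiple of step {step}")
    n_side = int(round(n_side))
    order = [0.0]
    if n_side == 0:
        return order
    pos = [step * (i + 1) for i in range(n_side)]
    neg = [-step * (i + 1) for i in range(n_side)]
    order.append(pos.pop(0))
    side_pos = False  # next group comes from the negative branch
    while pos or neg:
        branch = pos if side_pos else neg
        for _ in range(2):
            if branch:
                order.append(branch.pop(0))
        side_pos = not side_pos
    return order


def project_scene(
    scene: DensityMap,
    tilts: list[float] | None = None,
    ctf_params: CTFParams | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    total_dose: float = 85.0,
    defocus_range_um: tuple[float, float] = (-5.0, -2.0),
) -> TiltSeries:
    """Forward-project a cubic scene into a tilt series.

    Each image is the parallel-beam projection along the beam (z) after
    rotating the scene about the y tilt axis, optionally multiplied by the
    CTF in Fourier space, plus seeded white Gaussian noise.  One defocus
    value is drawn per series from ``defocus_range_um``.
    """
    if not scene.is_cubic:
        raise ValueError("scene must be cubic")
    if tilts is None:
        tilts = dose_symmetric_order(60.0, 3.0)
    tilts = list(tilts)
    rng = np.random.default_rng(seed)
    n = scene.shape[0]
    defocus = float(rng.uniform(*sorted(defocus_range_um)))
    images = np.empty((len(tilts), n, n), dtype=np.float32)
    for i, angle in enumerate(tilts):
        if abs(angle) < 1e-12:
            proj = scene.data.sum(axis=0)
        else:
            rotated = transform_volume(scene.data, rotation_about_axis([0.0, 1.0, 0.0], angle))
            proj = rotated.sum(axis=0)
        if ctf_params is not None:
            proj = _apply_ctf(proj, scene.voxel_size, defocus, ctf_params)
        images[i] = proj
    if noise_sigma > 0:
        images = images + rng.normal(scale=noise_sigma, size=images.shape).astype(np.float32)
    # dose rank = position in the provided (acquisition-ordered) tilt list
    acquisition_order = np.arange(len(tilts))
    per_tilt = total_dose / len(tilts)
    accumulated = per_tilt * (acquisition_order + 1)
    return TiltSeries(
        images=images,
        tilt_angles=np.array(tilts),
        acquisition_order=acquisition_order,
        accumulated_dose=accumulated,
        defocus_um=np.full(len(tilts), defocus),
        pixel_size=scene.voxel_size,
        ctf=ctf_params,
    )


def _ctf_2d(shape, pixel_size, defocus_um, params: CTFParams) -> np.ndarray:
    ky = np.fft.fftfreq(shape[0], d=pixel_size)[:, None]
    kx = np.fft.fftfreq(shape[1], d=pixel_size)[None, :]
    k2 = kx * kx + ky * ky
    lam = params.wavelength
    z = abs(defocus_um) * 1e4  # underfocus magnitude, Å
    cs = params.cs_mm * 1e7
    chi = np.pi * lam * z * k2 - 0.5 * np.pi * cs * lam**3 * k2 * k2
    a = params.amplitude_contrast
    # sign chosen so contrast is positive at low frequency (CTF(0) = +A)
    return np.sqrt(1.0 - a * a) * np.sin(chi) + a * np.cos(chi)


def _apply_ctf(image, pixel_size, defocus_um, params) -> np.ndarray:
    ctf = _ctf_2d(image.shape, pixel_size, defocus_um, params)
    return np.fft.ifft2(np.fft.fft2(image) * ctf).real.astype(np.float32)


def dose_filter(
    image: np.ndarray,
    accumulated_dose: float,
    pixel_size: float,
    params: DoseFilterParams = DoseFilterParams(),
) -> np.ndarray:
    """Exposure-dependent low-pass: amplitudes times exp(-N / (2 Ne(k))).

    ``Ne(k) -> inf`` as ``k -> 0`` (b < 0), so low frequencies are untouched;
    zero dose is the identity.
    """
    if accumulated_dose < 0:
        raise ValueError("accumulated dose must be >= 0")
    ky = np.fft.fftfreq(image.shape[0], d=pixel_size)[:, None]
    kx = np.fft.fftfreq(image.shape[1], d=pixel_size)[None, :]
    k = np.sqrt(kx * kx + ky * ky)
    with np.errstate(divide="ignore"):
        attenuation = np.exp(-accumulated_dose / (2.0 * params.critical_exposure(k)))
    return np.fft.ifft2(np.fft.fft2(image) * attenuation).real.astype(image.dtype)


def dose_filter_series(series: TiltSeries, params: DoseFilterParams = DoseFilterParams()) -> TiltSeries:
    images = np.stack(
        [
            dose_filter(img, dose, series.pixel_size, params)
            for img, dose in zip(series.images, series.accumulated_dose)
        ]
    )
    out = TiltSeries(**{**series.__dict__, "images": images})
    return out


def ctf_correct(series: TiltSeries) -> TiltSeries:
    """Whole-image phase flipping: negate Fourier components where CTF < 0.

    Involutive — applying it twice returns the original series.
    """
    if series.ctf is None:
        raise ValueError("series has no CTF parameters; nothing to correct")
    if np.any(~np.isfinite(series.defocus_um)):
        raise ValueError("missing defocus value in tilt series")
    out_images = np.empty_like(series.images)
    for i, img in enumerate(series.images):
        ctf = _ctf_2d(img.shape, series.pixel_size, series.defocus_um[i], series.ctf)
        sign = np.where(ctf < 0, -1.0, 1.0)
        out_images[i] = np.fft.ifft2(np.fft.fft2(img) * sign).real
    return TiltSeries(**{**series.__dict__, "images": out_images})


def reconstruct_wbp(series: TiltSeries, size: int, interpolation_order: int = 1) -> DensityMap:
    """Ramp-weighted back-projection about the y tilt axis.

    Linear in the input images; the ±60° wedge leaves the reconstruction
    elongated along the beam axis as in real tomograms.
    """
    n_img, ny, nx = series.images.shape
    if ny != nx:
        raise ValueError("projection images must be square")
    ramp = np.abs(np.fft.fftfreq(nx))[None, :]
    out = np.zeros((size, size, size), dtype=np.float64)
    c_out = size // 2
    c_img = nx // 2
    zz, yy, xx = np.meshgrid(
        np.arange(size) - c_out, np.arange(size) - c_out, np.arange(size) - c_out, indexing="ij"
    )
    step = np.radians(np.median(np.abs(np.diff(np.sort(series.tilt_angles))))) if n_img > 1 else 1.0
    for img, angle in zip(series.images, series.tilt_angles):
        filtered = np.fft.ifft(np.fft.fft(img, axis=1) * ramp, axis=1).real
        a = np.radians(angle)
        # detector coords of voxel (x, z) after rotating the scene by +angle
        xd = np.cos(a) * xx + np.sin(a) * zz + c_img
        yd = yy + c_img
        out += map_coordinates(filtered, [yd, xd], order=interpolation_order, mode="constant", cval=0.0)
    out *= step
    return DensityMap(data=out, voxel_size=series.pixel_size)


def wedge_mask(
    shape: tuple[int, int, int] | int,
    wedge: WedgeSpec,
    softness: float = 0.0,
) -> np.ndarray:
    """Fourier-space sampling weights in [0, 1] for a tilt range.

    A frequency (kx, ky, kz) is sampled when some tilt in the range puts it
    on a measured central section; for a y tilt axis that depends only on
    the angle of (kx, kz).  ``softness`` is a cosine edge width in degrees.
    Friedel symmetry holds exactly by construction.  Unshifted fft layout.
    """
    if isinstance(shape, int):
        shape = (shape,) * 3
    nz, ny, nx = shape
    if not (nz == ny == nx):
        raise ValueError("wedge mask requires a cubic shape")
    if wedge.is_full:
        return np.ones(shape, dtype=np.float64)
    kz = np.fft.fftfreq(nz)[:, None, None]
    kx = np.fft.fftfreq(nx)[None, None, :]
    kz = np.broadcast_to(kz, shape)
    kx = np.broadcast_to(kx, shape)
    alpha = np.degrees(np.arctan2(-kz, kx))
    # fold onto (-90, 90]: alpha and alpha±180 index the same central section
    alpha = (alpha + 90.0) % 180.0 - 90.0
    d = np.minimum.reduce(
        [
            np.maximum(wedge.tilt_min - a, a - wedge.tilt_max)
            for a in (alpha - 180.0, alpha, alpha + 180.0)
        ]
    )
    if softness <= 0:
        mask = (d <= 0).astype(np.float64)
    else:
        mask = np.where(
            d <= 0, 1.0, np.where(d >= softness, 0.0, 0.5 * (1.0 + np.cos(np.pi * d / softness)))
        )
    # the tilt-axis line kx = kz = 0 is always measured
    mask[0, :, 0] = 1.0
    # enforce exact Friedel symmetry (guards the soft edge against ulp noise)
    inv = (-np.arange(nz)) % nz
    mask = 0.5 * (mask + mask[inv][:, inv][:, :, inv])
    return mask


def apply_wedge_filter(data: np.ndarray, wedge: WedgeSpec | np.ndarray, softness: float = 0.0) -> np.ndarray:
    """Zero the Fourier components of a volume inside the missing wedge."""
    mask = wedge if isinstance(wedge, np.ndarray) else wedge_mask(data.shape, wedge, softness)
    return np.fft.ifftn(np.fft.fftn(data) * mask).real.astype(np.float32)
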