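"""Core volume and wedge types shared by every stage of the pipeline.

Conventions
-----------
* Density arrays are C-ordered with axes ``[z, y, x]`` (section, row, column),
  the layout used by MRC2014 readers.  Coordinate vectors handed to users are
  always ``(x, y, z)`` in voxels unless a docstring says Ångström.
* The rotation/FFT center of an ``n``-voxel axis is voxel ``n // 2``, matching
  the zero-frequency voxel after ``np.fft.fftshift``.
* Fourier-space masks are stored in the *unshifted* ``np.fft`` layout.
* The electron beam travels along ``z``; the tilt axis is ``y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class DensityMap:
    """A 3D scalar grid with voxel spacing and origin.

    The universal volume currency: tomograms, references, masks, and
    difference maps are all ``DensityMap`` instances.

    Parameters
    ----------
    data
        3D float array indexed ``[z, y, x]``.
    voxel_size
        Isotropic voxel edge in Å.
    origin
        Position of voxel (0, 0, 0) in Å, ``(x, y, z)`` order.
    """

    data: np.ndarray
    voxel_size: float = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"DensityMap requires a 3D array, got shape {self.data.shape}")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_cubic(self) -> bool:
        nz, ny, nx = self.data.shape
        return nz == ny == nx

    def copy(self) -> "DensityMap":
        return replace(self, data=self.data.copy())

    def with_data(self, data: np.ndarray) -> "DensityMap":
        """New map on the same grid with different values."""
        return replace(self, data=np.asarray(data, dtype=np.float32))

    def center(self) -> np.ndarray:
        """Grid center voxel ``(x, y, z)`` — the fftshift zero-frequency voxel."""
        nz, ny, nx = self.data.shape
        return np.array([nx // 2, ny // 2, nz // 2], dtype=float)


@dataclass(frozen=True)
class WedgeSpec:
    """Tilt range defining the sampled region of Fourier space.

    A tomogram acquired over ``[tilt_min, tilt_max]`` degrees about the y
    axis samples only the Fourier components whose implied tilt lies in that
    interval; the complement is the missing wedge.
    """

    tilt_min: float = -60.0
    tilt_max: float = 60.0

    def __post_init__(self) -> None:
        if not (self.tilt_min < self.tilt_max):
            raise ValueError("tilt_min must be < tilt_max")
        if self.tilt_min < -90.0 or self.tilt_max > 90.0:
            raise ValueError("tilt range must lie within [-90, 90] degrees")

    @property
    def is_full(self) -> bool:
        return self.tilt_min <= -90.0 + 1e-9 and self.tilt_max >= 90.0 - 1e-9


def fourier_radius_grid(shape: tuple[int, int, int], voxel_size: float = 1.0) -> np.ndarray:
    """Radial spatial-frequency magnitude |k| in 1/Å, unshifted fft layout."""
    nz, ny, nx = shape
    kz = np.fft.fftfreq(nz, d=voxel_size)[:, None, None]
    ky = np.fft.fftfreq(ny, d=voxel_size)[None, :, None]
    kx = np.fft.fftfreq(nx, d=voxel_size)[None, None, :]
    return np.sqrt(kz * kz + ky * ky + kx * kx)


def shell_mask(
    shape: tuple[int, int, int],
    voxel_size: float,
    lowpass: float | None = None,
    highpass: float | None = None,
) -> np.ndarray:
    """Binary band-pass mask between real-space resolutions given in Å.

    ``lowpass`` keeps frequencies below 1/lowpass; ``highpass`` removes
    frequencies below 1/highpass.  ``None`` disables the corresponding edge.
    """
    k = fourier_radius_grid(shape, voxel_size)
    mask = np.ones(shape, dtype=np.float64)
    if lowpass is not None:
        if lowpass < 2.0 * voxel_size:
            raise ValueError("lowpass resolution finer than Nyquist (2 * voxel_size)")
        mask *= (k <= 1.0 / lowpass).astype(np.float64)
    if highpass is not None:
        mask *= (k >= 1.0 / highpass).astype(np.float64)
    return mask
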