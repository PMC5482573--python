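"""Rigid-body poses, Euler conventions, rotation grids and volume resampling.

A :class:`Pose` maps the *reference* frame onto the *particle* frame: a
particle subvolume is modelled as the reference rotated by ``R`` and then
shifted by ``t`` voxels,

    particle(r) = reference(R^{-1} (r - c - t) + c)

with ``c`` the grid center.  Euler angles follow the ZXZ intrinsic
convention (``rot``, ``tilt``, ``psi`` in degrees) of the classical
subtomogram-averaging packages; ``psi`` is the in-plane angle about the
reference z axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import affine_transform
from scipy.spatial.transform import Rotation

EULER_CONVENTION = "ZXZ"  # intrinsic


@dataclass(frozen=True)
class Pose:
    """Rigid transform: three ZXZ intrinsic Euler angles plus a voxel shift."""

    euler: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shift: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @classmethod
    def identity(cls) -> "Pose":
        return cls()

    @classmethod
    def from_rotation(cls, rotation: Rotation, shift=(0.0, 0.0, 0.0)) -> "Pose":
        import warnings

        with warnings.catch_warnings():
            # gimbal lock at tilt = 0 has a valid canonical representation
            warnings.simplefilter("ignore", UserWarning)
            e = rotation.as_euler(EULER_CONVENTION, degrees=True)
        return cls(euler=tuple(float(a) for a in e), shift=tuple(float(s) for s in shift))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, shift=(0.0, 0.0, 0.0)) -> "Pose":
        return cls.from_rotation(Rotation.from_matrix(matrix), shift)

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_euler(EULER_CONVENTION, self.euler, degrees=True)

    @property
    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix acting on (x, y, z) column vectors."""
        return self.rotation.as_matrix()

    @property
    def shift_vector(self) -> np.ndarray:
        return np.asarray(self.shift, dtype=float)

    def compose(self, other: "Pose") -> "Pose":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        r = self.rotation * other.rotation
        t = self.matrix @ other.shift_vector + self.shift_vector
        return Pose.from_rotation(r, t)

    def inverse(self) -> "Pose":
        rinv = self.rotation.inv()
        return Pose.from_rotation(rinv, -(rinv.as_matrix() @ self.shift_vector))

    def angular_distance(self, other: "Pose") -> float:
        """Geodesic rotation angle between the two poses, degrees."""
        return rotation_angle_deg(self.rotation * other.rotation.inv())


def rotation_angle_deg(rotation: Rotation) -> float:
    """Magnitude of a rotation in degrees (geodesic distance from identity)."""
    return float(np.degrees(rotation.magnitude()))


def align_z_to(direction: np.ndarray) -> Rotation:
    """Minimal rotation taking the +z axis onto ``direction`` (x, y, z)."""
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("zero direction vector")
    d = d / n
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, d)
    s = np.linalg.norm(v)
    c = float(np.dot(z, d))
    if s < 1e-12:
        if c > 0:
            return Rotation.identity()
        # antiparallel: rotate 180 deg about x
        return Rotation.from_rotvec([np.pi, 0.0, 0.0])
    axis = v / s
    angle = np.arctan2(s, c)
    return Rotation.from_rotvec(axis * angle)


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> Rotation:
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    return Rotation.from_rotvec(a * np.radians(angle_deg))


# ---------------------------------------------------------------------------
# Volume resampling


def _as_index_matrix(matrix_xyz: np.ndarray) -> np.ndarray:
    # change of basis from (x,y,z) vectors to (z,y,x) array indices
    return matrix_xyz[::-1, ::-1]


def transform_volume(
    data: np.ndarray,
    rotation: Rotation | np.ndarray | None = None,
    shift=(0.0, 0.0, 0.0),
    order: int = 1,
) -> np.ndarray:
    """Apply a rigid transform (rotate about grid center, then shift).

    ``out(r) = data(R^{-1}(r - c - t) + c)`` with ``c = n // 2`` per axis.
    Linear interpolation by default; out-of-field voxels are zero.
    """
    if rotation is None:
        rmat = np.eye(3)
    elif isinstance(rotation, Rotation):
        rmat = rotation.as_matrix()
    else:
        rmat = np.asarray(rotation, dtype=float)
    t = np.asarray(shift, dtype=float)
    c = np.array([data.shape[2] // 2, data.shape[1] // 2, data.shape[0] // 2], dtype=float)
    rinv = rmat.T
    # in_xyz = Rinv @ (out_xyz - c - t) + c  ->  offset_xyz = c - Rinv @ (c + t)
    offset_xyz = c - rinv @ (c + t)
    m_idx = _as_index_matrix(rinv)
    return affine_transform(
        data, m_idx, offset=offset_xyz[::-1], order=order, mode="constant", cval=0.0,
        prefilter=(order > 1),
    )


def apply_pose(data: np.ndarray, pose: Pose, order: int = 1) -> np.ndarray:
    """Render the reference-frame volume in the particle frame."""
    return transform_volume(data, pose.rotation, pose.shift_vector, order=order)


def apply_pose_inverse(data: np.ndarray, pose: Pose, order: int = 1) -> np.ndarray:
    """Bring a particle-frame volume back into the reference frame."""
    inv = pose.inverse()
    return transform_volume(data, inv.rotation, inv.shift_vector, order=order)


def rotate_fourier_mask(mask: np.ndarray, rotation: Rotation, order: int = 1) -> np.ndarray:
    """Rotate a Fourier-space weight volume (unshifted layout) by ``rotation``.

    When a real-space volume is rotated by R its Fourier support rotates by
    R as well, so wedge masks follow their particles through alignment.
    """
    shifted = np.fft.fftshift(mask)
    rotated = transform_volume(shifted, rotation, order=order)
    return np.clip(np.fft.ifftshift(rotated), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Rotation search grids


def inplane_rotations(range_deg: float, step_deg: float) -> list[Rotation]:
    """Rotations about the reference z axis covering ±range at ~step spacing.

    ``range_deg=180`` scans the full circle without duplicating ±180.
    """
    if step_deg <= 0:
        raise ValueError("step_deg must be positive")
    if range_deg <= 0:
        return [Rotation.identity()]
    if range_deg >= 180.0:
        n = max(1, int(round(360.0 / step_deg)))
        angles = np.arange(n) * (360.0 / n) - 180.0
    else:
        angles = np.arange(-range_deg, range_deg + 0.5 * step_deg, step_deg)
    return [Rotation.from_euler("z", a, degrees=True) for a in angles]


def cone_rotations(
    cone_deg: float,
    step_deg: float,
    inplane_range_deg: float = 0.0,
    inplane_step_deg: float = 10.0,
) -> list[Rotation]:
    """Delta-rotation grid: cone tilt of the z axis crossed with in-plane spins.

    The cone is sampled on rings at multiples of ``step_deg`` up to
    ``cone_deg``, with ring point counts chosen for ~uniform angular density.
    The identity (cone apex) is always included.  Each returned rotation is
    meant to be composed on the right of the current pose rotation.
    """
    if step_deg <= 0:
        raise ValueError("step_deg must be positive")
    cone_dirs: list[Rotation] = [Rotation.identity()]
    theta = step_deg
    while theta <= cone_deg + 1e-9:
        n_phi = max(1, int(round(2.0 * np.pi * np.sin(np.radians(theta)) / np.radians(step_deg))))
        for i in range(n_phi):
            phi = 360.0 * i / n_phi
            cone_dirs.append(
                Rotation.from_euler("z", phi, degrees=True)
                * Rotation.from_euler("x", theta, degrees=True)
                * Rotation.from_euler("z", -phi, degrees=True)
            )
        theta += step_deg
    spins = inplane_rotations(inplane_range_deg, inplane_step_deg)
    return [d * s for d in cone_dirs for s in spins]
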