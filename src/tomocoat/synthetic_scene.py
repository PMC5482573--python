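"""Ground-truth phantoms and coated-vesicle scenes.

The coat is modelled at desk scale: the asymmetric unit ("leaf", one
coatomer plus two Arf1 molecules) is a handful of Gaussian blobs with
distinct weights, three leaves form a C3 "triad" around an outward-pointing
axis, and triads tile a spherical membrane shell.  A subset of leaves can
carry one extra "GAP" blob emulating a bound ArfGAP catalytic domain.
Every placement is recorded in a ground-truth table so downstream alignment,
classification and difference-density stages can be validated against known
poses and labels.

All randomness flows from a single integer seed through a named
``numpy.random.Generator``; scene generation is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core import DensityMap, WedgeSpec
from .geometry import Pose, align_z_to, rotation_about_axis

__all__ = [
    "PhantomSpec",
    "SceneSpec",
    "default_leaf_spec",
    "build_leaf_phantom",
    "build_vesicle_scene",
    "gap_assignment",
    "simulate_leaf_stack",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Blob model of the coat asymmetric unit.

    Blob centers are Å offsets from the leaf frame origin (the box center);
    the leaf axis (membrane normal when assembled) is +z.  The layout must be
    asymmetric — no nontrivial rotation maps it onto itself — so that pose
    recovery against this phantom is well-posed.
    """

    leaf_blob_centers: tuple[tuple[float, float, float], ...]
    leaf_blob_sigmas: tuple[float, ...]
    leaf_blob_weights: tuple[float, ...]
    gap_blob: tuple[tuple[float, float, float], float, float] | None = None
    symmetry_order: int = 3
    box_size: int = 32
    voxel_size: float = 4.0

    def __post_init__(self) -> None:
        n = len(self.leaf_blob_centers)
        if len(self.leaf_blob_sigmas) != n or len(self.leaf_blob_weights) != n:
            raise ValueError("blob centers, sigmas and weights must have equal length")
        if self.symmetry_order < 1:
            raise ValueError("symmetry_order must be >= 1")


def default_leaf_spec(box_size: int = 32, voxel_size: float = 4.0) -> PhantomSpec:
    """A four-blob asymmetric leaf ~60 Å across with a peripheral GAP site.

    Distinct weights and a non-planar arrangement guarantee the layout has
    no rotational self-symmetry.
    """
    return PhantomSpec(
        leaf_blob_centers=((0.0, 0.0, 4.0), (16.0, 2.0, 8.0), (-6.0, 14.0, 12.0), (4.0, -12.0, 18.0)),
        leaf_blob_sigmas=(10.0, 8.0, 7.0, 6.0),
        leaf_blob_weights=(1.0, 0.8, 0.6, 0.45),
        gap_blob=((12.0, 10.0, 22.0), 7.0, 0.7),
        symmetry_order=3,
        box_size=box_size,
        voxel_size=voxel_size,
    )


def _grid_coords_angstrom(box_size: int, voxel_size: float) -> tuple[np.ndarray, ...]:
    c = box_size // 2
    ax = (np.arange(box_size) - c) * voxel_size
    z = ax[:, None, None]
    y = ax[None, :, None]
    x = ax[None, None, :]
    return z, y, x


def _add_gaussian(data: np.ndarray, center_vox: np.ndarray, sigma_vox: float, weight: float) -> None:
    """Accumulate one isotropic Gaussian, evaluated within a 4-sigma cube."""
    nz, ny, nx = data.shape
    cx, cy, cz = center_vox
    r = max(2, int(np.ceil(4.0 * sigma_vox)))
    z0, z1 = max(0, int(cz) - r), min(nz, int(cz) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(ny, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(nx, int(cx) + r + 1)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zz = (np.arange(z0, z1) - cz)[:, None, None]
    yy = (np.arange(y0, y1) - cy)[None, :, None]
    xx = (np.arange(x0, x1) - cx)[None, None, :]
    r2 = zz * zz + yy * yy + xx * xx
    data[z0:z1, y0:y1, x0:x1] += weight * np.exp(-r2 / (2.0 * sigma_vox**2))


def build_leaf_phantom(spec: PhantomSpec, with_gap: bool = False) -> DensityMap:
    """Render the leaf blob model on its grid; deterministic for a fixed spec.

    Raises if any blob (plus a 3-sigma margin) extends outside the box,
    naming the offending blob.
    """
    half = spec.box_size // 2 * spec.voxel_size
    blobs = list(zip(spec.leaf_blob_centers, spec.leaf_blob_sigmas, spec.leaf_blob_weights))
    names = [f"leaf blob {i}" for i in range(len(blobs))]
    if with_gap:
        if spec.gap_blob is None:
            raise ValueError("with_gap=True but spec has no gap_blob")
        center, sigma, weight = spec.gap_blob
        blobs.append((center, sigma, weight))
        names.append("gap blob")
    data = np.zeros((spec.box_size,) * 3, dtype=np.float64)
    for name, (center, sigma, weight) in zip(names, blobs):
        c = np.asarray(center, dtype=float)
        if np.any(np.abs(c) + 3.0 * sigma > half):
            raise ValueError(f"{name} at {tuple(c)} Å (sigma {sigma} Å) exceeds the box")
        center_vox = c / spec.voxel_size + spec.box_size // 2
        _add_gaussian(data, center_vox, sigma / spec.voxel_size, weight)
    return DensityMap(data=data, voxel_size=spec.voxel_size)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic coated-vesicle field.

    ``membrane_shell`` is (radial offset Å, Gaussian thickness Å, amplitude);
    ``leaf_radial_offset`` places leaf centers above the membrane radius and
    ``leaf_lateral_offset`` displaces each leaf from its triad axis so the
    three C3 copies are distinct.  ``tilt_jitter_deg`` tips leaf axes away
    from the surface normal to emulate coat flexibility (0 = rigidly normal).
    """

    vesicle_radii: tuple[float, ...] = (120.0,)
    n_vesicles: int = 1
    triads_per_vesicle: int = 4
    membrane_shell: tuple[float, float, float] = (0.0, 12.0, 0.35)
    gap_fraction: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0
    box_size: int = 96
    voxel_size: float = 4.0
    min_triad_separation_deg: float = 40.0
    leaf_radial_offset: float = 30.0
    leaf_lateral_offset: float = 28.0
    tilt_jitter_deg: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gap_fraction <= 1.0:
            raise ValueError("gap_fraction must lie in [0, 1]")
        if self.n_vesicles < 1:
            raise ValueError("n_vesicles must be >= 1")


def _sample_triad_directions(rng: np.random.Generator, n: int, min_sep_deg: float) -> np.ndarray:
    """Rejection-sample unit vectors with pairwise great-circle separation."""
    min_cos = np.cos(np.radians(min_sep_deg))
    dirs: list[np.ndarray] = []
    for attempt in range(1000):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        if all(np.dot(v, d) < min_cos for d in dirs):
            dirs.append(v)
            if len(dirs) == n:
                return np.array(dirs)
    raise RuntimeError(
        f"could not place {n} triads at >= {min_sep_deg} deg separation after 1000 tries; "
        f"achieved {len(dirs)}"
    )


def build_vesicle_scene(scene: SceneSpec, phantom: PhantomSpec) -> tuple[DensityMap, pd.DataFrame]:
    """Render vesicles + coat lattice and return the scene with ground truth.

    Ground truth holds one row per placed leaf: voxel-center coordinates,
    ZXZ Euler angles of the leaf pose, vesicle and triad ids, the triad
    axis, and the GAP class label (assigned later by :func:`gap_assignment`;
    initialised here from ``scene.gap_fraction``).
    """
    rng = np.random.default_rng(scene.seed)
    n = scene.box_size
    data = np.zeros((n,) * 3, dtype=np.float64)
    z, y, x = _grid_coords_angstrom(n, scene.voxel_size)
    half = n // 2 * scene.voxel_size

    # vesicle centers on a jittered grid so they never collide
    radii = [scene.vesicle_radii[i % len(scene.vesicle_radii)] for i in range(scene.n_vesicles)]
    max_extent = max(radii) + scene.leaf_radial_offset + 3 * max(phantom.leaf_blob_sigmas)
    if max_extent > half:
        raise ValueError(
            f"vesicle of radius {max(radii):.0f} Å plus coat does not fit in a "
            f"{n}-voxel box at {scene.voxel_size} Å/voxel"
        )
    centers = _vesicle_centers(rng, scene.n_vesicles, radii, half)

    m_off, m_thick, m_amp = scene.membrane_shell
    rows: list[dict] = []
    pid = 0
    for vid, (vc, radius) in enumerate(zip(centers, radii), start=1):
        if m_amp > 0:
            r = np.sqrt((x - vc[0]) ** 2 + (y - vc[1]) ** 2 + (z - vc[2]) ** 2)
            data += m_amp * np.exp(-((r - (radius + m_off)) ** 2) / (2.0 * m_thick**2))
        dirs = _sample_triad_directions(rng, scene.triads_per_vesicle, scene.min_triad_separation_deg)
        for tid, u in enumerate(dirs):
            azimuth = rng.uniform(0.0, 360.0)
            base = align_z_to(u)
            if scene.tilt_jitter_deg > 0:
                jitter = Rotation.from_rotvec(
                    rng.normal(scale=np.radians(scene.tilt_jitter_deg), size=3)
                )
                base = jitter * base
            triad_center = vc + (radius + scene.leaf_radial_offset) * u
            for k in range(phantom.symmetry_order):
                leaf_rot = rotation_about_axis(u, azimuth + 360.0 * k / phantom.symmetry_order) * base
                leaf_center = triad_center + leaf_rot.as_matrix() @ np.array(
                    [scene.leaf_lateral_offset, 0.0, 0.0]
                )
                _render_leaf(data, phantom, leaf_center, leaf_rot, half, scene.voxel_size, False)
                pose = Pose.from_rotation(leaf_rot)
                vox = leaf_center / scene.voxel_size + n // 2
                pid += 1
                rows.append(
                    {
                        "particle_id": pid,
                        "vesicle_id": vid,
                        "triad_id": tid,
                        "x": vox[0], "y": vox[1], "z": vox[2],
                        "rot": pose.euler[0], "tilt": pose.euler[1], "psi": pose.euler[2],
                        "axis_x": u[0], "axis_y": u[1], "axis_z": u[2],
                        "class": 0,
                    }
                )
    truth = pd.DataFrame(rows)
    if scene.gap_fraction > 0:
        truth = gap_assignment(truth, scene.gap_fraction, seed=scene.seed + 1)
        for _, row in truth[truth["class"] == 1].iterrows():
            pose = Pose(euler=(row["rot"], row["tilt"], row["psi"]))
            center = (np.array([row["x"], row["y"], row["z"]]) - n // 2) * scene.voxel_size
            _render_gap_blob(data, phantom, center, pose.rotation, scene.voxel_size, n)
    if scene.noise_sigma > 0:
        data += rng.normal(scale=scene.noise_sigma, size=data.shape)
    return DensityMap(data=data, voxel_size=scene.voxel_size), truth


def _vesicle_centers(rng, n_vesicles, radii, half) -> np.ndarray:
    if n_vesicles == 1:
        return np.zeros((1, 3))
    # spread on a coarse lattice with jitter; guaranteed non-overlapping for
    # the supported desk-scale counts
    per_axis = int(np.ceil(n_vesicles ** (1.0 / 3.0)))
    pitch = 2.0 * half / (per_axis + 1)
    centers = []
    idx = 0
    for i in range(per_axis):
        for j in range(per_axis):
            for k in range(per_axis):
                if idx >= n_vesicles:
                    break
                base = (np.array([i, j, k]) - (per_axis - 1) / 2.0) * pitch
                centers.append(base + rng.uniform(-0.05 * pitch, 0.05 * pitch, size=3))
                idx += 1
    return np.array(centers)


def _render_leaf(data, phantom, center_ang, rotation, half, voxel_size, with_gap) -> None:
    n = data.shape[0]
    rmat = rotation.as_matrix()
    blobs = list(zip(phantom.leaf_blob_centers, phantom.leaf_blob_sigmas, phantom.leaf_blob_weights))
    for bc, sigma, weight in blobs:
        world = center_ang + rmat @ np.asarray(bc, dtype=float)
        _add_gaussian(data, world / voxel_size + n // 2, sigma / voxel_size, weight)


def _render_gap_blob(data, phantom, center_ang, rotation, voxel_size, n) -> None:
    bc, sigma, weight = phantom.gap_blob
    world = center_ang + rotation.as_matrix() @ np.asarray(bc, dtype=float)
    _add_gaussian(data, world / voxel_size + n // 2, sigma / voxel_size, weight)


def gap_assignment(truth: pd.DataFrame, gap_fraction: float, seed: int) -> pd.DataFrame:
    """Label exactly ``round(N * gap_fraction)`` leaves GAP-positive.

    Sampling is without replacement from a generator seeded with ``seed``;
    the count is deterministic, the identity of the positives is random.
    """
    if not 0.0 <= gap_fraction <= 1.0:
        raise ValueError("gap_fraction must lie in [0, 1]")
    out = truth.copy()
    n = len(out)
    n_pos = int(np.floor(n * gap_fraction + 0.5))
    rng = np.random.default_rng(seed)
    positives = rng.choice(n, size=n_pos, replace=False)
    labels = np.zeros(n, dtype=int)
    labels[positives] = 1
    out["class"] = labels
    return out


def simulate_leaf_stack(
    phantom: DensityMap,
    n_particles: int,
    wedge: WedgeSpec,
    snr: float,
    seed: int,
    gap_phantom: DensityMap | None = None,
    gap_fraction: float = 0.0,
    shift_limit: float = 2.0,
) -> tuple[list[DensityMap], list[WedgeSpec], pd.DataFrame]:
    """Direct particle-stack simulator used for alignment/classification tests.

    Each particle is the phantom (or the GAP-carrying phantom for positives)
    under a uniformly random rotation and a random subvoxel shift, filtered
    by the missing wedge, plus white Gaussian noise at the requested SNR
    (variance of the wedge-filtered signal over the box divided by noise
    variance).  Returns subvolumes, per-particle wedges and a ground-truth
    table with poses and class labels.
    """
    from .acquisition import apply_wedge_filter  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    rotations = Rotation.random(n_particles, random_state=np.random.RandomState(seed + 1))
    n_pos = int(np.floor(n_particles * gap_fraction + 0.5))
    labels = np.zeros(n_particles, dtype=int)
    labels[rng.choice(n_particles, size=n_pos, replace=False)] = 1
    subs: list[DensityMap] = []
    rows = []
    for i in range(n_particles):
        shift = rng.uniform(-shift_limit, shift_limit, size=3)
        pose = Pose.from_rotation(rotations[i], shift)
        source = gap_phantom if (labels[i] == 1 and gap_phantom is not None) else phantom
        from .geometry import apply_pose

        signal = apply_pose(source.data, pose)
        signal = apply_wedge_filter(signal, wedge)
        if snr > 0 and np.isfinite(snr):
            noise_sd = float(np.std(signal)) / np.sqrt(snr)
            signal = signal + rng.normal(scale=noise_sd, size=signal.shape)
        subs.append(phantom.with_data(signal))
        rows.append(
            {
                "particle_id": i + 1,
                "vesicle_id": (i % 2) + 1,
                "x": phantom.shape[2] // 2, "y": phantom.shape[1] // 2, "z": phantom.shape[0] // 2,
                "rot": pose.euler[0], "tilt": pose.euler[1], "psi": pose.euler[2],
                "shift_x": shift[0], "shift_y": shift[1], "shift_z": shift[2],
                "class": int(labels[i]),
            }
        )
    truth = pd.DataFrame(rows)
    return subs, [wedge] * n_particles, truth
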