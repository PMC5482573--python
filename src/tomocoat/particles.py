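"""Particle bookkeeping: surface picking, subvolume extraction, half-sets.

A particle table is a pandas DataFrame with the mandatory columns
``particle_id, vesicle_id, x, y, z, rot, tilt, psi`` (0-based voxel-center
coordinates, ZXZ intrinsic Euler angles in degrees) and optional
``shift_x/y/z, cc, half_set, class`` columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import DensityMap, WedgeSpec
from .geometry import Pose, align_z_to


def pose_from_row(row) -> Pose:
    shift = (
        (row["shift_x"], row["shift_y"], row["shift_z"])
        if "shift_x" in row.index
        else (0.0, 0.0, 0.0)
    )
    return Pose(euler=(row["rot"], row["tilt"], row["psi"]), shift=shift)


def set_pose_columns(table: pd.DataFrame, poses: list[Pose]) -> pd.DataFrame:
    out = table.copy()
    out["rot"] = [p.euler[0] for p in poses]
    out["tilt"] = [p.euler[1] for p in poses]
    out["psi"] = [p.euler[2] for p in poses]
    out["shift_x"] = [p.shift[0] for p in poses]
    out["shift_y"] = [p.shift[1] for p in poses]
    out["shift_z"] = [p.shift[2] for p in poses]
    return out


def refined_positions(table: pd.DataFrame) -> np.ndarray:
    """Particle centers with pose shifts folded in, (n, 3) in (x, y, z)."""
    pos = table[["x", "y", "z"]].to_numpy(dtype=float)
    if "shift_x" in table.columns:
        pos = pos + table[["shift_x", "shift_y", "shift_z"]].to_numpy(dtype=float)
    return pos


def sample_vesicle_surface(
    center: np.ndarray,
    radius: float,
    spacing: float,
    vesicle_id: int = 1,
    start_id: int = 1,
) -> pd.DataFrame:
    """Quasi-uniform picks on a sphere via a Fibonacci lattice.

    Point count is ``round(4 pi r^2 / spacing^2)``; each initial pose aligns
    the reference z axis with the outward normal with zero azimuth.
    Deterministic — no seed involved.  ``center``/``radius``/``spacing`` are
    in voxels.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    center = np.asarray(center, dtype=float)
    n = max(1, int(round(4.0 * np.pi * radius**2 / spacing**2)))
    i = np.arange(n)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    normals = np.stack([rho * np.cos(theta), rho * np.sin(theta), z], axis=1)
    rows = []
    for j, nrm in enumerate(normals):
        pose = Pose.from_rotation(align_z_to(nrm))
        p = center + radius * nrm
        rows.append(
            {
                "particle_id": start_id + j,
                "vesicle_id": vesicle_id,
                "x": p[0], "y": p[1], "z": p[2],
                "rot": pose.euler[0], "tilt": pose.euler[1], "psi": pose.euler[2],
                "normal_x": nrm[0], "normal_y": nrm[1], "normal_z": nrm[2],
            }
        )
    return pd.DataFrame(rows)


def extract_subtomogram(
    tomo: DensityMap,
    center: np.ndarray,
    box: int,
    wedge: WedgeSpec | None = None,
) -> tuple[DensityMap, WedgeSpec]:
    """Cut a cubic subvolume centered on the voxel nearest ``center``.

    Refuses to extract boxes that extend outside the tomogram — no silent
    padding.  The subvolume inherits the tomogram's missing wedge.
    """
    if box % 2 != 0:
        raise ValueError("box size must be even")
    nz, ny, nx = tomo.shape
    cx, cy, cz = (int(round(v)) for v in np.asarray(center, dtype=float))
    h = box // 2
    lo = np.array([cz - h, cy - h, cx - h])
    hi = np.array([cz + h, cy + h, cx + h])
    if np.any(lo < 0) or np.any(hi > np.array([nz, ny, nx])):
        raise ValueError(
            f"box {box} at center ({cx},{cy},{cz}) extends outside tomogram {tomo.shape}"
        )
    sub = tomo.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].copy()
    return tomo.with_data(sub), (wedge if wedge is not None else WedgeSpec(-90.0, 90.0))


def split_halves(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gold-standard split: half 1 = odd vesicle ids, half 2 = even.

    Whole vesicles go to one half so neighboring particles can never leak
    information across the gold-standard boundary.
    """
    if "vesicle_id" not in table.columns:
        raise ValueError("table has no vesicle_id column")
    odd = table[table["vesicle_id"] % 2 == 1].copy()
    even = table[table["vesicle_id"] % 2 == 0].copy()
    odd["half_set"] = 1
    even["half_set"] = 2
    return odd, even
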