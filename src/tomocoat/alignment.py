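"""Missing-wedge-aware subtomogram alignment and averaging.

The engine follows the classical constrained-correlation approach: scores
are normalized correlations computed only over the Fourier region sampled
by *both* volumes (intersection of their wedges, within a band-pass), so a
particle is never rewarded for matching frequencies it does not contain.
Averaging divides the summed Fourier terms by the summed rotated wedge
weights, which compensates the anisotropic coverage once enough orientations
contribute.

Alignment iterates: orient every particle against a low-pass-filtered
reference, re-average, optionally symmetrize, and repeat until the median
pose change stalls.  Cleaning (CC threshold) and distance deduplication
mirror the standard post-alignment hygiene of subtomogram averaging
pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .acquisition import wedge_mask
from .core import DensityMap, WedgeSpec, shell_mask
from .geometry import (
    Pose,
    apply_pose_inverse,
    cone_rotations,
    rotate_fourier_mask,
    rotation_about_axis,
    transform_volume,
)
from .particles import pose_from_row, refined_positions, set_pose_columns

__all__ = [
    "ScheduleStep",
    "AlignmentSchedule",
    "SymmetrySpec",
    "constrained_cc",
    "align_particle",
    "average_particles",
    "apply_symmetry",
    "expand_to_asymmetric_units",
    "iterate_alignment",
    "clean_by_cc",
    "remove_duplicates",
    "lowpass_map",
]


@dataclass(frozen=True)
class ScheduleStep:
    """Search parameters for one alignment iteration."""

    cone_deg: float = 15.0
    cone_step_deg: float = 7.5
    inplane_range_deg: float = 15.0
    inplane_step_deg: float = 7.5
    shift_limit: float = 4.0
    lowpass: float | None = 35.0

    def __post_init__(self) -> None:
        if self.cone_step_deg <= 0 or self.inplane_step_deg <= 0:
            raise ValueError("angular steps must be positive")


@dataclass
class AlignmentSchedule:
    """Per-iteration steps plus a convergence rule.

    Convergence: median angular change below half the finest angular step
    AND median shift change below 0.5 voxel.  Iteration ``i`` uses
    ``steps[min(i, len(steps) - 1)]``.
    """

    steps: list[ScheduleStep] = field(default_factory=lambda: [ScheduleStep()])
    max_iterations: int = 10

    def step_for(self, iteration: int) -> ScheduleStep:
        return self.steps[min(iteration, len(self.steps) - 1)]


@dataclass(frozen=True)
class SymmetrySpec:
    """Cn point-group symmetry about the reference z axis."""

    order: int = 1

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("symmetry order must be >= 1")

    @property
    def group(self) -> str:
        return f"C{self.order}"


def lowpass_map(data: np.ndarray, voxel_size: float, resolution: float | None) -> np.ndarray:
    """Sharp-shell low-pass at a real-space resolution in Å."""
    if resolution is None:
        return data
    m = shell_mask(data.shape, voxel_size, lowpass=resolution)
    return np.fft.ifftn(np.fft.fftn(data) * m).real.astype(np.float32)


def _as_mask(mask_like, shape) -> np.ndarray | None:
    if mask_like is None:
        return None
    if isinstance(mask_like, WedgeSpec):
        return wedge_mask(shape, mask_like)
    return np.asarray(mask_like, dtype=np.float64)


def _fourier_region(shape, voxel_size, wedge_a, wedge_b, bandpass) -> np.ndarray:
    region = np.ones(shape, dtype=np.float64)
    for w in (wedge_a, wedge_b):
        m = _as_mask(w, shape)
        if m is not None:
            region *= m
    if bandpass is not None:
        if isinstance(bandpass, tuple):
            lowpass, highpass = bandpass
            region *= shell_mask(shape, voxel_size, lowpass=lowpass, highpass=highpass)
        else:
            region *= np.asarray(bandpass, dtype=np.float64)
    region[0, 0, 0] = 0.0  # DC carries mean offsets, never similarity
    return region


def constrained_cc(
    a: DensityMap | np.ndarray,
    b: DensityMap | np.ndarray,
    wedge_a: WedgeSpec | np.ndarray | None = None,
    wedge_b: WedgeSpec | np.ndarray | None = None,
    bandpass: tuple[float | None, float | None] | np.ndarray | None = None,
    voxel_size: float | None = None,
) -> float:
    """Normalized cross-correlation over the jointly sampled Fourier region.

    Symmetric in its arguments, invariant to positive rescaling of either
    map, and equal to the real-space normalized dot product of the
    band-limited, wedge-filtered volumes (Parseval).  Value in [-1, 1].
    """
    da = a.data if isinstance(a, DensityMap) else np.asarray(a)
    db = b.data if isinstance(b, DensityMap) else np.asarray(b)
    if da.shape != db.shape:
        raise ValueError("maps must share a shape")
    vs = voxel_size or (a.voxel_size if isinstance(a, DensityMap) else 1.0)
    region = _fourier_region(da.shape, vs, wedge_a, wedge_b, bandpass)
    if not np.any(region > 0):
        raise ValueError("empty Fourier intersection region")
    fa = np.fft.fftn(da) * region
    fb = np.fft.fftn(db) * region
    na = np.linalg.norm(fa)
    nb = np.linalg.norm(fb)
    if na == 0 or nb == 0:
        raise ValueError("map is all-zero after wedge/band-pass filtering")
    return float(np.sum(fa * np.conj(fb)).real / (na * nb))


def _wrapped_window(ccvol: np.ndarray, limit: int) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(-limit, limit + 1)
    wrapped = idx % ccvol.shape[0]
    win = ccvol[np.ix_(wrapped, wrapped, wrapped)]
    return win, idx


def _refine_peak(values: np.ndarray, peak: tuple[int, int, int]) -> tuple[list[float], float]:
    """Per-axis parabolic subvoxel offsets and the interpolated peak height.

    Candidates must be ranked on interpolated heights: with integer-only
    shift sampling a small off-rotation can mimic a subvoxel translation
    and outscore the true rotation at the grid points.
    """
    offsets: list[float] = []
    height = float(values[peak])
    for axis_idx in range(3):
        sel = list(peak)
        if sel[axis_idx] == 0 or sel[axis_idx] == values.shape[axis_idx] - 1:
            offsets.append(0.0)
            continue
        lo, mid, hi = (
            float(values[tuple(sel[:axis_idx] + [sel[axis_idx] + d] + sel[axis_idx + 1:])])
            for d in (-1, 0, 1)
        )
        denom = lo - 2.0 * mid + hi
        if abs(denom) < 1e-12:
            offsets.append(0.0)
            continue
        offsets.append(float(np.clip(0.5 * (lo - hi) / denom, -0.5, 0.5)))
        height += -((hi - lo) ** 2) / (8.0 * denom)
    return offsets, height


def align_particle(
    sub: DensityMap | np.ndarray,
    ref: DensityMap | np.ndarray,
    wedge: WedgeSpec | np.ndarray,
    step: ScheduleStep,
    mask: np.ndarray | None = None,
    current_pose: Pose = Pose(),
    voxel_size: float | None = None,
) -> tuple[Pose, float]:
    """Best pose of ``ref`` explaining ``sub`` over a local rotation grid.

    For every candidate rotation (cone about the current orientation crossed
    with in-plane spins) the translation is read off the constrained
    cross-correlation peak, limited to ``step.shift_limit`` voxels and
    refined to subvoxel precision by parabolic interpolation.
    """
    ds = sub.data if isinstance(sub, DensityMap) else np.asarray(sub)
    dr = ref.data if isinstance(ref, DensityMap) else np.asarray(ref)
    if ds.shape != dr.shape:
        raise ValueError("particle and reference must share a shape")
    vs = voxel_size or (sub.voxel_size if isinstance(sub, DensityMap) else 1.0)
    region = _fourier_region(ds.shape, vs, wedge, None, (step.lowpass, None))
    sub_masked = ds * mask if mask is not None else ds
    fs = np.fft.fftn(sub_masked) * region
    ns = np.linalg.norm(fs)
    if ns == 0:
        raise ValueError("particle is all-zero after filtering")
    deltas = cone_rotations(
        step.cone_deg, step.cone_step_deg, step.inplane_range_deg, step.inplane_step_deg
    )
    limit = int(round(step.shift_limit))
    best = (-np.inf, None, None)
    n_vox = ds.size
    for delta in deltas:
        rot = current_pose.rotation * delta
        rotated = transform_volume(dr, rot)
        if mask is not None:
            rotated = rotated * mask
        fr = np.fft.fftn(rotated) * region
        nr = np.linalg.norm(fr)
        if nr == 0:
            continue
        ccvol = np.fft.ifftn(fs * np.conj(fr)).real * (n_vox / (ns * nr))
        win, idx = _wrapped_window(ccvol, limit)
        peak = np.unravel_index(np.argmax(win), win.shape)
        sub_off, score = _refine_peak(win, peak)
        if score > best[0]:
            shift = np.array(
                [idx[peak[2]] + sub_off[2], idx[peak[1]] + sub_off[1], idx[peak[0]] + sub_off[0]]
            )
            best = (score, rot, shift)
    score, rot, shift = best
    if rot is None:
        raise ValueError("empty rotation search grid")
    return Pose.from_rotation(rot, shift), score


def average_particles(
    subs: list[DensityMap | np.ndarray],
    poses: list[Pose],
    wedges: list[WedgeSpec | np.ndarray],
    floor_fraction: float = 0.1,
    voxel_size: float | None = None,
) -> DensityMap:
    """Wedge-compensated average in the reference frame.

    Fourier numerator: sum of back-rotated particles.  Denominator: sum of
    the correspondingly rotated wedge weights, floored at
    ``floor_fraction * n`` to avoid amplifying pure-noise frequencies;
    frequencies with (near) zero coverage are set to zero.
    """
    if len(subs) == 0:
        raise ValueError("need at least one particle")
    if not (len(subs) == len(poses) == len(wedges)):
        raise ValueError("subs, poses and wedges must have equal length")
    first = subs[0]
    shape = first.data.shape if isinstance(first, DensityMap) else np.asarray(first).shape
    vs = voxel_size or (first.voxel_size if isinstance(first, DensityMap) else 1.0)
    num = np.zeros(shape, dtype=np.complex128)
    den = np.zeros(shape, dtype=np.float64)
    for sub, pose, wedge in zip(subs, poses, wedges):
        data = sub.data if isinstance(sub, DensityMap) else np.asarray(sub)
        num += np.fft.fftn(apply_pose_inverse(data, pose))
        wmask = _as_mask(wedge, shape)
        den += rotate_fourier_mask(wmask, pose.rotation.inv())
    n = len(subs)
    floor = floor_fraction * n
    avg_f = np.where(den > 1e-3, num / np.maximum(den, floor), 0.0)
    return DensityMap(np.fft.ifftn(avg_f).real.astype(np.float32), voxel_size=vs)


def apply_symmetry(
    density: DensityMap, sym: SymmetrySpec, axis=(0.0, 0.0, 1.0), order: int = 1
) -> DensityMap:
    """Mean over the n rotated copies about ``axis`` (default z).

    ``order`` selects the interpolation (1 linear, 3 cubic spline); cubic
    keeps the result rotation-invariant to a much tighter tolerance.
    """
    if sym.order == 1:
        return density
    acc = np.zeros_like(density.data, dtype=np.float64)
    for k in range(sym.order):
        rot = rotation_about_axis(axis, 360.0 * k / sym.order)
        acc += density.data if k == 0 else transform_volume(density.data, rot, order=order)
    return density.with_data(acc / sym.order)


def expand_to_asymmetric_units(
    table: pd.DataFrame,
    sym: SymmetrySpec,
    leaf_offset=(0.0, 0.0, 0.0),
) -> pd.DataFrame:
    """Expand each symmetric particle into its n asymmetric-unit records.

    Asymmetric-unit pose k composes the particle pose with an in-plane
    (reference z) rotation of k*360/n degrees; centers are displaced by the
    rotated ``leaf_offset`` (reference-frame voxels).  Output has n rows per
    input row with fresh particle ids and a ``triad_id`` pointing back.
    """
    offset = np.asarray(leaf_offset, dtype=float)
    rows = []
    pid = 0
    for _, row in table.iterrows():
        pose = pose_from_row(row)
        for k in range(sym.order):
            spin = Rotation.from_euler("z", 360.0 * k / sym.order, degrees=True)
            leaf_pose = Pose.from_rotation(pose.rotation * spin, pose.shift_vector)
            disp = leaf_pose.matrix @ offset
            pid += 1
            new = row.to_dict()
            new.update(
                {
                    "particle_id": pid,
                    "triad_id": row["particle_id"],
                    "x": row["x"] + disp[0], "y": row["y"] + disp[1], "z": row["z"] + disp[2],
                    "rot": leaf_pose.euler[0], "tilt": leaf_pose.euler[1], "psi": leaf_pose.euler[2],
                }
            )
            rows.append(new)
    return pd.DataFrame(rows)


def iterate_alignment(
    subs: list[DensityMap],
    wedges: list[WedgeSpec | np.ndarray],
    table: pd.DataFrame,
    initial_ref: DensityMap,
    schedule: AlignmentSchedule,
    sym: SymmetrySpec = SymmetrySpec(1),
    mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, list[DensityMap], list[dict]]:
    """Iterative rotational/translational refinement against an evolving reference.

    Per iteration: low-pass the reference per the schedule, align every
    particle, re-average with wedge compensation, apply symmetry.  Stops at
    the convergence rule (median pose change below half the finest angular
    step and 0.5 voxel) or ``max_iterations``.  If the mean CC decreases
    three iterations running a divergence warning is issued and the best
    iteration's state is returned.

    Returns the updated table (poses, ``cc``), the reference history, and a
    per-iteration statistics log.
    """
    ref = initial_ref
    vs = initial_ref.voxel_size
    poses = [pose_from_row(row) for _, row in table.iterrows()]
    history: list[DensityMap] = []
    log: list[dict] = []
    best = (-np.inf, None, None)
    decreasing = 0
    prev_cc = None
    for it in range(schedule.max_iterations):
        step = schedule.step_for(it)
        ref_f = ref.with_data(lowpass_map(ref.data, vs, step.lowpass))
        new_poses = []
        scores = []
        for sub, wedge, pose in zip(subs, wedges, poses):
            p, cc = align_particle(sub, ref_f, wedge, step, mask=mask, current_pose=pose)
            new_poses.append(p)
            scores.append(cc)
        ang_changes = [p.angular_distance(q) for p, q in zip(new_poses, poses)]
        shift_changes = [
            float(np.linalg.norm(p.shift_vector - q.shift_vector))
            for p, q in zip(new_poses, poses)
        ]
        poses = new_poses
        ref = average_particles(subs, poses, wedges, voxel_size=vs)
        if sym.order > 1:
            ref = apply_symmetry(ref, sym)
        history.append(ref)
        mean_cc = float(np.mean(scores))
        finest = min(step.cone_step_deg, step.inplane_step_deg)
        converged = (
            float(np.median(ang_changes)) < 0.5 * finest
            and float(np.median(shift_changes)) < 0.5
        )
        log.append(
            {
                "iteration": it,
                "mean_cc": mean_cc,
                "median_angular_change_deg": float(np.median(ang_changes)),
                "median_shift_change_vox": float(np.median(shift_changes)),
                "lowpass": step.lowpass,
                "converged": converged,
            }
        )
        if mean_cc > best[0]:
            best = (mean_cc, list(poses), ref)
        if prev_cc is not None and mean_cc < prev_cc:
            decreasing += 1
            if decreasing >= 3:
                warnings.warn("alignment diverging: mean CC decreased 3 iterations running")
                _, poses, ref = best
                break
        else:
            decreasing = 0
        prev_cc = mean_cc
        if converged:
            break
    out = set_pose_columns(table, poses)
    out["cc"] = [float(s) for s in _final_scores(subs, ref, wedges, poses, schedule, vs)]
    return out, history, log


def _render(ref: DensityMap, pose: Pose) -> DensityMap:
    from .geometry import apply_pose

    return ref.with_data(apply_pose(ref.data, pose))


def _final_scores(subs, ref, wedges, poses, schedule, vs):
    step = schedule.step_for(schedule.max_iterations)
    ref_f = lowpass_map(ref.data, vs, step.lowpass)
    for sub, pose, wedge in zip(subs, poses, wedges):
        rendered = _render(ref.with_data(ref_f), pose)
        yield constrained_cc(sub, rendered, wedge_a=wedge, voxel_size=vs)


def pose_recovery_errors(
    estimated: list[Pose], truth: list[Pose]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-particle angular (deg) and shift (voxel) errors, gauge-corrected.

    Iterative refinement against an evolving reference only determines poses
    up to one global rigid transform of the reference (the gauge).  The best
    common correction ``g`` (chordal-mean rotation and mean shift of
    ``est_i^{-1} . true_i``) is removed before measuring errors, so the
    returned values reflect genuine per-particle misalignment.
    """
    if len(estimated) != len(truth):
        raise ValueError("pose lists must have equal length")
    gauges = [e.inverse().compose(t) for e, t in zip(estimated, truth)]
    quats = np.array([g.rotation.as_quat() for g in gauges])
    quats[quats[:, 3] < 0] *= -1  # hemisphere-align before averaging
    mean_q = quats.mean(axis=0)
    mean_q /= np.linalg.norm(mean_q)
    g_rot = Rotation.from_quat(mean_q)
    g_shift = np.mean([g.shift_vector for g in gauges], axis=0)
    g = Pose.from_rotation(g_rot, g_shift)
    corrected = [e.compose(g) for e in estimated]
    ang = np.array([c.angular_distance(t) for c, t in zip(corrected, truth)])
    shift = np.array(
        [np.linalg.norm(c.shift_vector - t.shift_vector) for c, t in zip(corrected, truth)]
    )
    return ang, shift


def clean_by_cc(table: pd.DataFrame, rule: tuple[str, float]) -> pd.DataFrame:
    """Remove low-scoring particles.

    ``rule`` is ``("absolute", t)`` keeping ``cc >= t`` or ``("sigma", k)``
    keeping ``cc >= mean - k * SD``.  An empty result raises, advising a
    threshold review.
    """
    if "cc" not in table.columns:
        raise ValueError("table has no cc column")
    kind, value = rule
    scores = table["cc"].to_numpy(dtype=float)
    if kind == "absolute":
        thr = value
    elif kind == "sigma":
        thr = scores.mean() - value * scores.std()
    else:
        raise ValueError(f"unknown cleaning rule {kind!r}")
    kept = table[table["cc"] >= thr]
    if len(kept) == 0:
        raise ValueError(f"CC threshold {thr:.3f} removes every particle; review the rule")
    return kept.copy()


def remove_duplicates(table: pd.DataFrame, min_distance: float) -> pd.DataFrame:
    """Greedy deduplication by refined position.

    Particles are visited in descending CC order (ties broken by particle
    id); one is kept iff no already-kept particle lies *strictly* closer
    than ``min_distance`` voxels.  Never increases the count; idempotent.
    """
    if len(table) == 0:
        return table.copy()
    pos = refined_positions(table)
    cc = table["cc"].to_numpy(dtype=float) if "cc" in table.columns else np.zeros(len(table))
    order = np.lexsort((table["particle_id"].to_numpy(), -cc))
    kept_idx: list[int] = []
    for i in order:
        d = [np.linalg.norm(pos[i] - pos[j]) for j in kept_idx]
        if all(dist >= min_distance for dist in d):
            kept_idx.append(i)
    kept_idx.sort()
    return table.iloc[kept_idx].copy()
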