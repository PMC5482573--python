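"""Multireference classification, model densities, difference maps,
extra-density segmentation, rigid-body fitting and geometric validation.

This is the machinery used to localize a substoichiometric binder (the
ArfGAP2 problem): particles already aligned to a consensus are scored
against competing references by constrained cross-correlation and assigned
to the best class; class averages are re-formed and the process iterated.
Unmodelled density is then quantified by subtracting a model-simulated map
("molmap"-style Gaussian rendering) from the experimental map, segmenting
the suprathreshold difference into connected components, and ranking them
by voxel volume.  Cross-link distance screening applies the strict
below-35-Å criterion used for validating fitted models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .core import DensityMap, WedgeSpec
from .geometry import Pose
from .alignment import average_particles, constrained_cc, _render
from .particles import pose_from_row

__all__ = [
    "AtomSet",
    "ClassificationParams",
    "SegmentationParams",
    "CrosslinkCriterion",
    "read_pdb_atoms",
    "multireference_classify",
    "simulate_model_density",
    "difference_map",
    "segment_extra_densities",
    "permutation_control_volumes",
    "rigid_body_fit",
    "crosslink_distances",
    "max_linker_extension",
]


@dataclass
class AtomSet:
    """Atomic positions (Å) with unitless mass weights and optional labels."""

    positions: np.ndarray
    masses: np.ndarray
    labels: pd.DataFrame | None = None  # chain, resid, atom_name per row

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.masses = np.asarray(self.masses, dtype=float).ravel()
        if len(self.masses) != len(self.positions):
            raise ValueError("positions and masses length mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite atom coordinates")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    def __len__(self) -> int:
        return len(self.positions)

    def transformed(self, rotation: Rotation, translation: np.ndarray, pivot: np.ndarray | None = None) -> "AtomSet":
        pivot = self.positions.mean(axis=0) if pivot is None else np.asarray(pivot, float)
        pos = (rotation.as_matrix() @ (self.positions - pivot).T).T + pivot + translation
        return AtomSet(pos, self.masses.copy(), self.labels)


def read_pdb_atoms(path) -> AtomSet:
    """Read coordinates from a PDB file; elements map to atomic weights."""
    import gemmi

    st = gemmi.read_structure(str(path))
    rows = []
    pos = []
    masses = []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    pos.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    masses.append(atom.element.weight if atom.element.weight > 0 else 12.0)
                    rows.append(
                        {"chain": chain.name, "resid": res.seqid.num,
                         "resname": res.name, "atom_name": atom.name}
                    )
        break  # first model only
    if not pos:
        raise ValueError(f"no atoms found in {path}")
    return AtomSet(np.array(pos), np.array(masses), pd.DataFrame(rows))


@dataclass(frozen=True)
class ClassificationParams:
    n_classes: int = 2
    n_iterations: int = 3

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass(frozen=True)
class SegmentationParams:
    """Threshold in map-sigma units, voxel connectivity, components to report."""

    threshold: float = 1.0
    connectivity: int = 26
    top_k: int = 7

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass(frozen=True)
class CrosslinkCriterion:
    cutoff: float = 35.0  # Å

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


def multireference_classify(
    subs: list[DensityMap],
    wedges: list[WedgeSpec | np.ndarray],
    table: pd.DataFrame,
    refs: list[DensityMap],
    params: ClassificationParams = ClassificationParams(),
    mask: np.ndarray | None = None,
    bandpass=None,
) -> tuple[np.ndarray, list[DensityMap], list[dict]]:
    """Iterative competitive assignment against multiple references.

    Particles keep their refined poses; at each iteration every particle is
    scored against each reference rendered at the particle's pose (masked,
    wedge-constrained CC) and assigned to the argmax, ties going to the
    lowest class index.  Class averages are re-formed from their members; a
    class that empties keeps its previous average and a warning is issued.

    Returns 1-based labels, final class averages, and a per-iteration log.
    """
    if len(refs) < params.n_classes:
        raise ValueError("need at least n_classes references")
    refs = list(refs[: params.n_classes])
    poses = [pose_from_row(row) for _, row in table.iterrows()]
    vs = subs[0].voxel_size
    labels = np.zeros(len(subs), dtype=int)
    log: list[dict] = []
    for it in range(params.n_iterations):
        scores = np.zeros((len(subs), len(refs)))
        for j, ref in enumerate(refs):
            for i, (sub, pose, wedge) in enumerate(zip(subs, poses, wedges)):
                rendered = _render(ref, pose)
                data = rendered.data * mask if mask is not None else rendered.data
                scores[i, j] = constrained_cc(
                    sub.data * mask if mask is not None else sub.data,
                    data, wedge_a=wedge, bandpass=bandpass, voxel_size=vs,
                )
        labels = np.argmax(scores, axis=1) + 1  # argmax takes the first max: lowest index wins ties
        new_refs = []
        for j in range(len(refs)):
            members = np.flatnonzero(labels == j + 1)
            if len(members) == 0:
                warnings.warn(f"class {j + 1} emptied at iteration {it}; keeping previous average")
                new_refs.append(refs[j])
                continue
            new_refs.append(
                average_particles(
                    [subs[i] for i in members],
                    [poses[i] for i in members],
                    [wedges[i] for i in members],
                    voxel_size=vs,
                )
            )
        refs = new_refs
        log.append(
            {
                "iteration": it,
                "class_sizes": [int(np.sum(labels == j + 1)) for j in range(len(refs))],
                "mean_best_cc": float(scores.max(axis=1).mean()),
            }
        )
    return labels, refs, log


DEFAULT_SIGMA_FACTOR = 0.225  # Gaussian sigma = factor * resolution, the
# convention of the standard model-to-map rendering tools


def simulate_model_density(
    atoms: AtomSet,
    resolution: float,
    voxel_size: float,
    box: int,
    origin: np.ndarray | None = None,
    sigma_factor: float = DEFAULT_SIGMA_FACTOR,
) -> DensityMap:
    """Render atoms as mass-weighted 3D Gaussians at a target resolution.

    Each atom becomes an isotropic Gaussian with sigma =
    ``sigma_factor * resolution`` normalized so its grid integral (sum times
    voxel volume) equals the atom mass.  ``origin`` is the Å position of
    voxel (0,0,0); by default the atom centroid is placed at the box center.
    Raises if any atom falls outside the box, listing the offenders.
    """
    sigma = sigma_factor * resolution
    if origin is None:
        centroid = atoms.positions.mean(axis=0)
        origin = centroid - (box // 2) * voxel_size
    origin = np.asarray(origin, dtype=float)
    vox = (atoms.positions - origin) / voxel_size
    outside = np.flatnonzero(np.any((vox < 0) | (vox > box - 1), axis=1))
    if len(outside) > 0:
        raise ValueError(f"atoms outside the box: indices {outside.tolist()[:10]}")
    data = np.zeros((box,) * 3, dtype=np.float64)
    sig_vox = sigma / voxel_size
    amp = 1.0 / ((2.0 * np.pi) ** 1.5 * sigma**3)  # per-Å^3 density, unit integral
    r = max(2, int(np.ceil(4.0 * sig_vox)))
    for p, m in zip(vox, atoms.masses):
        cx, cy, cz = p
        z0, z1 = max(0, int(cz) - r), min(box, int(cz) + r + 1)
        y0, y1 = max(0, int(cy) - r), min(box, int(cy) + r + 1)
        x0, x1 = max(0, int(cx) - r), min(box, int(cx) + r + 1)
        zz = (np.arange(z0, z1) - cz)[:, None, None]
        yy = (np.arange(y0, y1) - cy)[None, :, None]
        xx = (np.arange(x0, x1) - cx)[None, None, :]
        r2 = (zz * zz + yy * yy + xx * xx) * voxel_size**2
        data[z0:z1, y0:y1, x0:x1] += m * amp * np.exp(-r2 / (2.0 * sigma**2))
    return DensityMap(data, voxel_size=voxel_size, origin=tuple(origin))


def difference_map(
    em_map: DensityMap,
    model_map: DensityMap,
    mask: np.ndarray | None = None,
) -> tuple[DensityMap, float]:
    """Experimental minus amplitude-scaled model density.

    The scale is the least-squares fit of the model to the map over the
    mask (whole map if none), a declared normalization choice.  Returns the
    difference map and the scale used.
    """
    if em_map.shape != model_map.shape:
        raise ValueError("maps must share a grid")
    em = em_map.data.astype(np.float64)
    mod = model_map.data.astype(np.float64)
    w = np.ones_like(em) if mask is None else np.asarray(mask, dtype=np.float64)
    denom = float(np.sum(w * mod * mod))
    if denom <= 0:
        raise ValueError("model is all-zero inside the mask")
    s = float(np.sum(w * em * mod)) / denom
    return em_map.with_data(em - s * mod), s


_CONN_RANK = {6: 1, 18: 2, 26: 3}


def segment_extra_densities(
    diff: DensityMap,
    params: SegmentationParams = SegmentationParams(),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Connected components of the suprathreshold difference density.

    Threshold is ``params.threshold`` map standard deviations.  Components
    are ranked by voxel volume (descending; ties by centroid for
    determinism).  Returns the ``top_k`` table (rank, volume, centroid in
    voxels) and the full volume distribution.
    """
    data = diff.data
    thr = params.threshold * float(np.std(data))
    binary = data > thr
    if not binary.any():
        return (
            pd.DataFrame(columns=["rank", "volume_voxels", "centroid_x", "centroid_y", "centroid_z"]),
            np.array([], dtype=int),
        )
    structure = ndimage.generate_binary_structure(3, _CONN_RANK[params.connectivity])
    labels, n = ndimage.label(binary, structure=structure)
    volumes = np.bincount(labels.ravel())[1:]
    centroids = ndimage.center_of_mass(binary, labels, index=np.arange(1, n + 1))
    order = sorted(
        range(n), key=lambda i: (-volumes[i], centroids[i][2], centroids[i][1], centroids[i][0])
    )
    rows = []
    for rank, i in enumerate(order[: params.top_k], start=1):
        cz, cy, cx = centroids[i]
        rows.append(
            {"rank": rank, "volume_voxels": int(volumes[i]),
             "centroid_x": cx, "centroid_y": cy, "centroid_z": cz}
        )
    return pd.DataFrame(rows), np.sort(volumes)[::-1]


def permutation_control_volumes(
    subs: list[DensityMap],
    wedges,
    table: pd.DataFrame,
    n_permutations: int,
    seed: int,
    seg_params: SegmentationParams = SegmentationParams(),
) -> np.ndarray:
    """Largest difference-map component under random label permutations.

    The null distribution for class-difference segmentation: particles are
    split into two random halves, the two averages subtracted, and the
    biggest suprathreshold component recorded.  Returns one maximal volume
    per permutation (0 when nothing crosses the threshold).
    """
    rng = np.random.default_rng(seed)
    poses = [pose_from_row(row) for _, row in table.iterrows()]
    vs = subs[0].voxel_size
    n = len(subs)
    out = []
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        g1, g2 = perm[: n // 2], perm[n // 2:]
        a1 = average_particles([subs[i] for i in g1], [poses[i] for i in g1], [wedges[i] for i in g1], voxel_size=vs)
        a2 = average_particles([subs[i] for i in g2], [poses[i] for i in g2], [wedges[i] for i in g2], voxel_size=vs)
        dmap = a1.with_data(a1.data - a2.data)
        _, volumes = segment_extra_densities(dmap, seg_params)
        out.append(int(volumes[0]) if len(volumes) else 0)
    return np.array(out)


def rigid_body_fit(
    atoms: AtomSet,
    density: DensityMap,
    init: Pose = Pose(),
    resolution: float = 9.0,
) -> tuple[Pose, float, bool]:
    """Local CC maximization of a rigid atom model against a map.

    The model is rendered at ``resolution`` and compared by real-space
    correlation; optimization is derivative-free (Powell) over three
    rotation-vector components (degrees) and three shifts (voxels) starting
    from ``init``, which must be within the capture range (about half a blob
    width).  Returns (pose, cc, improved); on failure to improve, ``init``
    comes back with ``improved=False``.  The returned CC is never below the
    CC at ``init``.
    """
    box = density.shape[0]
    vs = density.voxel_size
    target = density.data.ravel()
    tnorm = np.linalg.norm(target - target.mean())

    def cc_of(x: np.ndarray) -> float:
        rot = Rotation.from_rotvec(np.radians(x[:3]))
        moved = atoms.transformed(rot, x[3:] * vs)
        try:
            rendered = simulate_model_density(
                moved, resolution, vs, box, origin=np.asarray(density.origin, float)
            )
        except ValueError:
            return -1.0
        r = rendered.data.ravel()
        rn = np.linalg.norm(r - r.mean())
        if rn == 0 or tnorm == 0:
            return -1.0
        return float((r - r.mean()) @ (target - target.mean()) / (rn * tnorm))

    x0 = np.concatenate([np.degrees(init.rotation.as_rotvec()), init.shift_vector])
    cc0 = cc_of(x0)
    res = optimize.minimize(
        lambda x: -cc_of(x), x0, method="Powell",
        options={"xtol": 1e-2, "ftol": 1e-5, "maxiter": 2000},
    )
    cc1 = -float(res.fun)
    if cc1 <= cc0 + 1e-12:
        return init, cc0, False
    pose = Pose.from_rotation(Rotation.from_rotvec(np.radians(res.x[:3])), res.x[3:])
    return pose, cc1, True


def crosslink_distances(
    atoms: AtomSet,
    pairs: list[tuple[tuple, tuple]],
    crit: CrosslinkCriterion = CrosslinkCriterion(),
) -> pd.DataFrame:
    """Distance screen for cross-linked residue pairs.

    Each selector is ``(chain, resid, atom_name)`` and must resolve to a
    unique atom.  A pair satisfies the criterion iff its Euclidean distance
    is strictly below the cutoff.
    """
    if atoms.labels is None:
        raise ValueError("atom set carries no labels; cannot resolve selectors")
    rows = []
    for sel_a, sel_b in pairs:
        pa = _resolve(atoms, sel_a)
        pb = _resolve(atoms, sel_b)
        d = float(np.linalg.norm(pa - pb))
        rows.append(
            {"selector_a": _fmt(sel_a), "selector_b": _fmt(sel_b),
             "distance_A": d, "satisfied": d < crit.cutoff}
        )
    return pd.DataFrame(rows)


def _resolve(atoms: AtomSet, selector: tuple) -> np.ndarray:
    chain, resid, atom_name = selector
    lab = atoms.labels
    hit = (lab["chain"] == chain) & (lab["resid"] == resid) & (lab["atom_name"] == atom_name)
    idx = np.flatnonzero(hit.to_numpy())
    if len(idx) != 1:
        raise ValueError(f"selector {_fmt(selector)} resolves to {len(idx)} atoms, need exactly 1")
    return atoms.positions[idx[0]]


def _fmt(sel: tuple) -> str:
    return f"{sel[0]}/{sel[1]}/{sel[2]}"


def max_linker_extension(n_residues: int, rise_per_residue: float = 3.6) -> float:
    """Fully extended polypeptide length: residues times per-residue rise (Å).

    At ~3.6 Å per residue, a 103-residue unstructured linker can span about
    370 Å when fully extended.
    """
    if n_residues < 0:
        raise ValueError("n_residues must be >= 0")
    return n_residues * rise_per_residue
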