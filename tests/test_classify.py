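"""Multireference classification, model densities, difference segmentation,
rigid-body fitting and cross-link screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from tomocoat.core import DensityMap, WedgeSpec
from tomocoat.acquisition import wedge_mask
from tomocoat.classify import (
    AtomSet,
    ClassificationParams,
    CrosslinkCriterion,
    SegmentationParams,
    crosslink_distances,
    difference_map,
    max_linker_extension,
    multireference_classify,
    read_pdb_atoms,
    rigid_body_fit,
    segment_extra_densities,
    simulate_model_density,
)
from tomocoat.geometry import Pose
from tomocoat.particles import pose_from_row
from tomocoat.synthetic_scene import simulate_leaf_stack


class TestMultireference:
    def _stack(self, leaf, gap_leaf, wedge, n, snr, seed, fraction):
        subs, wedges, truth = simulate_leaf_stack(
            leaf, n, wedge, snr=snr, seed=seed, gap_phantom=gap_leaf, gap_fraction=fraction
        )
        masks = [wedge_mask(leaf.shape[0], w) for w in wedges]
        return subs, masks, truth

    def test_identical_references_all_land_in_class_one(self, leaf, wedge60):
        subs, masks, truth = self._stack(leaf, None, wedge60, 8, np.inf, 41, 0.0)
        labels, _, _ = multireference_classify(
            subs, masks, truth, [leaf, leaf], ClassificationParams(2, 1)
        )
        assert np.all(labels == 1)

    def test_noise_free_mixture_fully_recovered_in_one_iteration(self, leaf, gap_leaf, wedge60):
        subs, masks, truth = self._stack(leaf, gap_leaf, wedge60, 20, np.inf, 42, 0.5)
        labels, _, _ = multireference_classify(
            subs, masks, truth, [gap_leaf, leaf], ClassificationParams(2, 1)
        )
        predicted_gap = labels == 1
        assert np.array_equal(predicted_gap, truth["class"].to_numpy() == 1)

    def test_empty_class_keeps_previous_reference(self, leaf, wedge60):
        subs, masks, truth = self._stack(leaf, None, wedge60, 6, np.inf, 43, 0.0)
        far = leaf.with_data(-leaf.data)  # nothing will match the inverted map
        with pytest.warns(UserWarning, match="emptied"):
            labels, refs, _ = multireference_classify(
                subs, masks, truth, [leaf, far], ClassificationParams(2, 2)
            )
        assert np.all(labels == 1)
        assert np.allclose(refs[1].data, far.data)


class TestModelDensity:
    def test_single_atom_peak_and_mass_integral(self):
        atoms = AtomSet(np.array([[0.0, 0.0, 0.0]]), np.array([12.0]))
        m = simulate_model_density(atoms, resolution=10.0, voxel_size=1.0, box=32)
        assert np.unravel_index(np.argmax(m.data), m.shape) == (16, 16, 16)
        assert m.data.sum() * 1.0**3 == pytest.approx(12.0, rel=0.01)

    def test_two_separated_atoms_sum_linearly(self):
        a = AtomSet(np.array([[-8.0, 0.0, 0.0]]), np.array([1.0]))
        b = AtomSet(np.array([[8.0, 0.0, 0.0]]), np.array([1.0]))
        both = AtomSet(np.array([[-8.0, 0.0, 0.0], [8.0, 0.0, 0.0]]), np.ones(2))
        origin = np.array([-16.0, -16.0, -16.0])
        kw = dict(resolution=6.0, voxel_size=1.0, box=32, origin=origin)
        m_a = simulate_model_density(a, **kw)
        m_b = simulate_model_density(b, **kw)
        m_ab = simulate_model_density(both, **kw)
        assert np.abs(m_ab.data - m_a.data - m_b.data).max() < 1e-9

    def test_fwhm_scales_with_resolution(self):
        atoms = AtomSet(np.array([[0.0, 0.0, 0.0]]), np.array([1.0]))
        m1 = simulate_model_density(atoms, resolution=8.0, voxel_size=0.5, box=96)
        m2 = simulate_model_density(atoms, resolution=16.0, voxel_size=0.5, box=96)
        assert _fwhm(m2.data[48, 48, :]) / _fwhm(m1.data[48, 48, :]) == pytest.approx(2.0, rel=0.03)

    def test_atom_outside_box_listed(self):
        atoms = AtomSet(np.array([[0.0, 0.0, 0.0], [500.0, 0.0, 0.0]]), np.ones(2))
        with pytest.raises(ValueError, match=r"\[1\]"):
            simulate_model_density(atoms, 9.0, 1.0, 32, origin=np.array([-16.0, -16.0, -16.0]))


def _fwhm(profile):
    half = profile.max() / 2.0
    above = np.flatnonzero(profile >= half)
    # linear sub-sample interpolation at both edges
    lo, hi = above[0], above[-1]
    left = lo - (profile[lo] - half) / (profile[lo] - profile[lo - 1])
    right = hi + (profile[hi] - half) / (profile[hi] - profile[hi + 1])
    return right - left


class TestDifferenceMap:
    def test_exact_model_leaves_no_residual(self, leaf):
        diff, scale = difference_map(leaf, leaf.with_data(2.0 * leaf.data))
        assert scale == pytest.approx(0.5, rel=1e-6)
        assert np.sqrt((diff.data**2).mean()) < 1e-6 * np.sqrt((leaf.data**2).mean())

    def test_extra_blob_recovered(self, leaf, gap_leaf, leaf_spec):
        diff, _ = difference_map(gap_leaf, leaf)
        expected = gap_leaf.data - leaf.data
        support = expected > 0.05 * expected.max()
        cc = np.corrcoef(diff.data[support], expected[support])[0, 1]
        assert cc > 0.99

    def test_linear_in_experimental_map(self, leaf, gap_leaf, rng):
        extra = DensityMap(rng.normal(size=leaf.shape), leaf.voxel_size)
        d1, _ = difference_map(gap_leaf, leaf)
        d2, _ = difference_map(gap_leaf.with_data(gap_leaf.data + extra.data), leaf)
        d3, _ = difference_map(extra, leaf)
        assert np.allclose(d2.data, d1.data + d3.data, atol=1e-4)

    def test_zero_model_errors(self, leaf):
        with pytest.raises(ValueError, match="all-zero"):
            difference_map(leaf, leaf.with_data(np.zeros(leaf.shape)))


class TestSegmentation:
    def test_two_blobs_ranked_by_volume(self):
        vol = np.zeros((32,) * 3, dtype=np.float32)
        vol[4:8, 4:8, 4:8] = 10.0       # 64 voxels
        vol[20:23, 20:23, 20:25] = 10.0  # 45 voxels
        comps, dist = segment_extra_densities(
            DensityMap(vol, 1.0), SegmentationParams(threshold=2.0, top_k=7)
        )
        assert list(comps["volume_voxels"]) == [64, 45]
        assert list(dist) == [64, 45]

    def test_threshold_above_max_gives_empty(self, leaf):
        comps, dist = segment_extra_densities(leaf, SegmentationParams(threshold=1e6))
        assert len(comps) == 0 and len(dist) == 0

    def test_matches_flood_fill_oracle(self, rng):
        # random blob fields vs an independent BFS flood fill at 26-connectivity
        for trial in range(3):
            vol = rng.normal(size=(24,) * 3)
            vol[vol < 1.2] = 0.0
            dm = DensityMap(vol, 1.0)
            params = SegmentationParams(threshold=1.0, connectivity=26, top_k=1000)
            comps, dist = segment_extra_densities(dm, params)
            thr = 1.0 * vol.std()
            binary = vol > thr
            sizes = _flood_fill_sizes(binary)
            assert sorted(dist) == sorted(sizes)
            assert dist.sum() == binary.sum()  # conservation

    def test_total_volume_conserved(self, leaf):
        comps, dist = segment_extra_densities(leaf, SegmentationParams(threshold=1.0, top_k=1000))
        thr = leaf.data.std()
        assert dist.sum() == (leaf.data > thr).sum()


def _flood_fill_sizes(binary):
    visited = np.zeros_like(binary, dtype=bool)
    sizes = []
    dirs = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)]
    nz, ny, nx = binary.shape
    for start in zip(*np.nonzero(binary)):
        if visited[start]:
            continue
        stack, size = [start], 0
        visited[start] = True
        while stack:
            z, y, x = stack.pop()
            size += 1
            for dz, dy, dx in dirs:
                p = (z + dz, y + dy, x + dx)
                if 0 <= p[0] < nz and 0 <= p[1] < ny and 0 <= p[2] < nx:
                    if binary[p] and not visited[p]:
                        visited[p] = True
                        stack.append(p)
        sizes.append(size)
    return sizes


class TestRigidBodyFit:
    @pytest.fixture
    def atoms(self):
        rng = np.random.default_rng(7)
        pos = rng.uniform(-8, 8, size=(12, 3))
        return AtomSet(pos, np.full(12, 12.0))

    def test_identity_recovered_from_own_density(self, atoms):
        target = simulate_model_density(atoms, 9.0, 2.0, 24)
        pose, cc, improved = rigid_body_fit(atoms, target, Pose(), resolution=9.0)
        assert pose.angular_distance(Pose()) < 1.0
        assert np.linalg.norm(pose.shift_vector) < 0.5
        assert cc > 0.99

    def test_perturbed_start_recovers(self, atoms):
        target = simulate_model_density(atoms, 9.0, 2.0, 24)
        start = Pose(euler=(0.0, 10.0, 0.0), shift=(1.5, -1.0, 0.5))
        pose, cc, improved = rigid_body_fit(atoms, target, start, resolution=9.0)
        assert improved
        assert pose.angular_distance(Pose()) < 2.0
        assert np.linalg.norm(pose.shift_vector) < 1.0

    def test_returned_cc_never_below_initial(self, atoms):
        target = simulate_model_density(atoms, 9.0, 2.0, 24)
        start = Pose(euler=(0.0, 8.0, 0.0), shift=(1.0, 0.0, 0.0))
        def cc_at(p):
            rendered = simulate_model_density(
                atoms.transformed(p.rotation, p.shift_vector * 2.0), 9.0, 2.0, 24,
                origin=np.asarray(target.origin, float),
            )
            r, t = rendered.data.ravel(), target.data.ravel()
            return np.corrcoef(r, t)[0, 1]
        _, cc, _ = rigid_body_fit(atoms, target, start, resolution=9.0)
        assert cc >= cc_at(start) - 1e-9


class TestCrosslinks:
    @pytest.fixture
    def atoms(self):
        pos = np.array([[0.0, 0.0, 0.0], [34.9, 0.0, 0.0], [35.0, 0.0, 0.0],
                        [0.0, 36.0, 0.0]])
        labels = pd.DataFrame(
            {"chain": ["A"] * 4, "resid": [1, 2, 3, 4], "resname": ["LYS"] * 4,
             "atom_name": ["NZ"] * 4}
        )
        return AtomSet(pos, np.full(4, 14.0), labels)

    def test_strictly_below_cutoff_rule(self, atoms):
        table = crosslink_distances(
            atoms,
            [(("A", 1, "NZ"), ("A", 2, "NZ")),
             (("A", 1, "NZ"), ("A", 3, "NZ")),
             (("A", 1, "NZ"), ("A", 4, "NZ"))],
        )
        assert list(table["satisfied"]) == [True, False, False]
        assert list(table["distance_A"]) == pytest.approx([34.9, 35.0, 36.0])

    def test_batch_matches_scalar_oracle(self, atoms, rng):
        pairs = [(("A", 1, "NZ"), ("A", i, "NZ")) for i in (2, 3, 4)]
        table = crosslink_distances(atoms, pairs)
        for row, (sa, sb) in zip(table.itertuples(), pairs):
            pa = atoms.positions[sa[1] - 1]
            pb = atoms.positions[sb[1] - 1]
            assert row.distance_A == pytest.approx(float(np.linalg.norm(pa - pb)), abs=1e-12)

    def test_unresolvable_selector_named(self, atoms):
        with pytest.raises(ValueError, match="B/9/NZ"):
            crosslink_distances(atoms, [(("A", 1, "NZ"), ("B", 9, "NZ"))])


class TestPDBReader:
    def test_round_trip_through_pdb_format(self, tmp_path):
        pdb = tmp_path / "toy.pdb"
        pdb.write_text(
            "ATOM      1  CA  LYS A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  NZ  LYS A   1       3.500   1.200  -2.000  1.00  0.00           N\n"
            "ATOM      3  CA  GLY A   2      10.000   0.000   5.000  1.00  0.00           C\n"
            "END\n"
        )
        atoms = read_pdb_atoms(pdb)
        assert len(atoms) == 3
        assert np.allclose(atoms.positions[1], [3.5, 1.2, -2.0])
        assert atoms.masses[1] == pytest.approx(14.007, rel=1e-3)
        assert list(atoms.labels["atom_name"]) == ["CA", "NZ", "CA"]


class TestLinkerExtension:
    @pytest.mark.parametrize("n,rise,expected", [(103, 3.6, 370.8), (0, 3.6, 0.0), (10, 3.6, 36.0)])
    def test_extension_arithmetic(self, n, rise, expected):
        assert max_linker_extension(n, rise) == pytest.approx(expected)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            max_linker_extension(-1)
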