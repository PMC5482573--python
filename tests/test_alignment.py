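"""Constrained correlation, pose search, averaging, symmetry, hygiene."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from tomocoat.core import DensityMap, WedgeSpec
from tomocoat.acquisition import apply_wedge_filter, wedge_mask
from tomocoat.alignment import (
    AlignmentSchedule,
    ScheduleStep,
    SymmetrySpec,
    _fourier_region,
    align_particle,
    apply_symmetry,
    average_particles,
    clean_by_cc,
    constrained_cc,
    expand_to_asymmetric_units,
    iterate_alignment,
    pose_recovery_errors,
    remove_duplicates,
)
from tomocoat.geometry import Pose, apply_pose, cone_rotations, rotation_angle_deg
from tomocoat.particles import pose_from_row
from tomocoat.synthetic_scene import simulate_leaf_stack


class TestConstrainedCC:
    def test_self_correlation_is_one(self, leaf):
        assert constrained_cc(leaf, leaf) == pytest.approx(1.0, abs=1e-6)

    def test_negation_gives_minus_one(self, leaf):
        assert constrained_cc(leaf, leaf.with_data(-leaf.data)) == pytest.approx(-1.0, abs=1e-6)

    def test_matches_real_space_oracle(self, rng, wedge60):
        # oracle: normalized dot product of the wedge-filtered volumes
        for _ in range(5):
            a = rng.normal(size=(8,) * 3)
            b = rng.normal(size=(8,) * 3)
            cc = constrained_cc(a, b, wedge_a=wedge60, wedge_b=wedge60, voxel_size=1.0)
            region = _fourier_region((8,) * 3, 1.0, wedge60, wedge60, None)
            fa = np.fft.ifftn(np.fft.fftn(a) * region).real.ravel()
            fb = np.fft.ifftn(np.fft.fftn(b) * region).real.ravel()
            oracle = fa @ fb / (np.linalg.norm(fa) * np.linalg.norm(fb))
            assert cc == pytest.approx(oracle, abs=1e-6)

    def test_symmetric_and_scale_invariant(self, rng, wedge60):
        a = rng.normal(size=(8,) * 3)
        b = rng.normal(size=(8,) * 3)
        cc_ab = constrained_cc(a, b, wedge_a=wedge60, voxel_size=1.0)
        cc_ba = constrained_cc(b, a, wedge_b=wedge60, voxel_size=1.0)
        cc_scaled = constrained_cc(3.7 * a, b, wedge_a=wedge60, voxel_size=1.0)
        assert cc_ab == pytest.approx(cc_ba, abs=1e-9)
        assert cc_ab == pytest.approx(cc_scaled, abs=1e-9)

    def test_empty_intersection_errors(self, rng):
        a = rng.normal(size=(8,) * 3)
        with pytest.raises(ValueError, match="intersection"):
            constrained_cc(a, a, bandpass=np.zeros((8,) * 3), voxel_size=1.0)


class TestAlignParticle:
    def test_on_grid_rotation_recovered_exactly(self, leaf):
        true = Pose(euler=(0.0, 0.0, 15.0))
        sub = DensityMap(apply_pose(leaf.data, true), leaf.voxel_size)
        step = ScheduleStep(cone_deg=0.0, inplane_range_deg=30.0, inplane_step_deg=7.5,
                            shift_limit=2.0, lowpass=None)
        pose, cc = align_particle(sub, leaf, WedgeSpec(-90, 90), step)
        assert pose.angular_distance(true) < 1e-6
        assert cc > 0.99

    def test_integer_shift_recovered_exactly(self, leaf):
        true = Pose(shift=(2.0, -1.0, 3.0))
        sub = DensityMap(apply_pose(leaf.data, true), leaf.voxel_size)
        step = ScheduleStep(cone_deg=0.0, inplane_range_deg=0.0, shift_limit=4.0, lowpass=None)
        pose, _ = align_particle(sub, leaf, WedgeSpec(-90, 90), step)
        assert np.allclose(pose.shift_vector, [2.0, -1.0, 3.0], atol=1e-6)

    def test_matches_exhaustive_bruteforce_with_wedge_and_noise(self, wedge60):
        # same coarse grid, wedge-filtered noisy particle: the FFT-accelerated
        # search must pick the same rotation and integer shift as explicit
        # enumeration of (rotation x shift) scored by constrained CC
        from tomocoat.synthetic_scene import PhantomSpec, build_leaf_phantom

        small = build_leaf_phantom(
            PhantomSpec(
                leaf_blob_centers=((0.0, 0.0, 0.0), (3.0, 1.0, 1.0), (-2.0, 2.0, -1.0)),
                leaf_blob_sigmas=(2.0, 1.4, 1.2),
                leaf_blob_weights=(1.0, 0.7, 0.5),
                box_size=16, voxel_size=1.0,
            )
        )
        rng = np.random.default_rng(4)
        true = Pose(euler=(10.0, 8.0, -12.0), shift=(1.0, 0.0, -2.0))
        signal = apply_wedge_filter(apply_pose(small.data, true), wedge60)
        noisy = signal + rng.normal(scale=np.std(signal) / np.sqrt(0.5), size=signal.shape)
        sub = DensityMap(noisy, 1.0)
        step = ScheduleStep(cone_deg=12.0, cone_step_deg=6.0, inplane_range_deg=12.0,
                            inplane_step_deg=6.0, shift_limit=2.0, lowpass=None)
        pose, cc = align_particle(sub, small, wedge60, step)

        from tomocoat.alignment import _refine_peak
        from tomocoat.geometry import transform_volume

        deltas = cone_rotations(step.cone_deg, step.cone_step_deg,
                                step.inplane_range_deg, step.inplane_step_deg)
        best = (-np.inf, None, None)
        for delta in deltas:
            rotated = transform_volume(small.data, delta)
            # explicit enumeration of every integer shift in the search range
            win = np.zeros((5, 5, 5))
            for iz, sz in enumerate(range(-2, 3)):
                for iy, sy in enumerate(range(-2, 3)):
                    for ix, sx in enumerate(range(-2, 3)):
                        shifted = np.roll(rotated, (sz, sy, sx), axis=(0, 1, 2))
                        win[iz, iy, ix] = constrained_cc(
                            noisy, shifted, wedge_a=wedge60, voxel_size=1.0
                        )
            peak = np.unravel_index(np.argmax(win), win.shape)
            offs, score = _refine_peak(win, peak)
            if score > best[0]:
                shift = (peak[2] - 2 + offs[2], peak[1] - 2 + offs[1], peak[0] - 2 + offs[0])
                best = (score, delta, shift)
        assert rotation_angle_deg(pose.rotation * best[1].inv()) < 1e-6
        assert np.allclose(pose.shift_vector, best[2], atol=1e-5)
        assert cc == pytest.approx(best[0], abs=1e-6)


class TestAveraging:
    def test_identity_pose_average_equals_particle_in_wedge(self, leaf, wedge60):
        sub = DensityMap(apply_wedge_filter(leaf.data, wedge60), leaf.voxel_size)
        avg = average_particles([sub], [Pose()], [wedge60])
        mask = wedge_mask(leaf.shape[0], wedge60)
        fa = np.fft.fftn(avg.data) * (mask == 1)
        fs = np.fft.fftn(sub.data) * (mask == 1)
        assert np.abs(fa - fs).max() < 1e-3 * np.abs(fs).max()

    def test_complementary_wedges_union_coverage(self, leaf):
        w1 = WedgeSpec(-90.0, 0.0)
        w2 = WedgeSpec(0.0, 90.0)
        m1 = wedge_mask(leaf.shape[0], w1)
        m2 = wedge_mask(leaf.shape[0], w2)
        total = m1 + m2  # the per-frequency weight the average divides by
        assert total.max() <= 2.0 + 1e-9
        covered = (total > 0).mean()
        assert covered > 0.99

    def test_average_beats_single_particle(self, leaf, wedge60):
        subs, wedges, truth = simulate_leaf_stack(leaf, 50, wedge60, snr=0.5, seed=11)
        poses = [pose_from_row(r) for _, r in truth.iterrows()]
        avg = average_particles(subs, poses, wedges)
        cc_avg = constrained_cc(avg, leaf)
        cc_singles = [
            constrained_cc(sub, DensityMap(apply_pose(leaf.data, p), leaf.voxel_size))
            for sub, p in zip(subs[:10], poses[:10])
        ]
        assert cc_avg > max(cc_singles)


class TestSymmetry:
    def test_c1_is_identity(self, leaf):
        assert apply_symmetry(leaf, SymmetrySpec(1)) is leaf

    def test_c3_invariant_under_rotation(self, leaf):
        from tomocoat.geometry import rotation_about_axis, transform_volume

        s = apply_symmetry(leaf, SymmetrySpec(3), order=3)
        rot = transform_volume(s.data, rotation_about_axis([0, 0, 1], 120.0), order=3)
        assert np.abs(rot - s.data).max() < 1e-3 * np.abs(s.data).max()

    def test_mean_intensity_preserved(self, leaf):
        s = apply_symmetry(leaf, SymmetrySpec(3), order=3)
        assert s.data.mean() == pytest.approx(leaf.data.mean(), rel=1e-6)


class TestExpansion:
    @pytest.fixture
    def triads(self):
        rng = np.random.default_rng(5)
        rots = Rotation.random(10, random_state=np.random.RandomState(5))
        rows = []
        for i, r in enumerate(rots):
            p = Pose.from_rotation(r)
            rows.append({"particle_id": i + 1, "vesicle_id": 1 + i % 2,
                         "x": 10.0 * i, "y": 5.0, "z": 3.0,
                         "rot": p.euler[0], "tilt": p.euler[1], "psi": p.euler[2]})
        return pd.DataFrame(rows)

    def test_counts_conserved(self, triads):
        leaves = expand_to_asymmetric_units(triads, SymmetrySpec(3))
        assert len(leaves) == 30

    def test_leaf_poses_differ_by_120_about_triad_axis(self, triads):
        leaves = expand_to_asymmetric_units(triads, SymmetrySpec(3))
        for tid, g in leaves.groupby("triad_id"):
            mats = [pose_from_row(r).matrix for _, r in g.iterrows()]
            axis = mats[0] @ np.array([0.0, 0.0, 1.0])  # triad axis in particle frame
            rel = Rotation.from_matrix(mats[1] @ mats[0].T)
            ang = rotation_angle_deg(rel)
            assert ang == pytest.approx(120.0, abs=1e-6)
            rv = rel.as_rotvec()
            assert np.allclose(np.abs(rv / np.linalg.norm(rv)), np.abs(axis), atol=1e-6)


class TestIterativeAlignment:
    def _stack(self, leaf, wedge, n, seed, snr=np.inf):
        subs, wedges, truth = simulate_leaf_stack(leaf, n, wedge, snr=snr, seed=seed,
                                                  shift_limit=1.5)
        return subs, wedges, truth

    def test_small_perturbation_converges_fast(self, leaf, wedge60):
        subs, wedges, truth = self._stack(leaf, wedge60, 10, seed=21)
        rng = np.random.default_rng(1)
        start = truth.copy()
        start["rot"] += rng.uniform(-2, 2, len(start))
        start["psi"] += rng.uniform(-2, 2, len(start))
        start[["shift_x", "shift_y", "shift_z"]] = 0.0
        step = ScheduleStep(cone_deg=8.0, cone_step_deg=4.0, inplane_range_deg=8.0,
                            inplane_step_deg=4.0, shift_limit=3.0, lowpass=None)
        schedule = AlignmentSchedule(steps=[step], max_iterations=3)
        aligned, history, log = iterate_alignment(subs, wedges, start, leaf, schedule)
        est = [pose_from_row(a) for _, a in aligned.iterrows()]
        true = [pose_from_row(t) for _, t in truth.iterrows()]
        ang_err, shift_err = pose_recovery_errors(est, true)
        assert len(log) <= 3
        assert np.median(ang_err) <= 4.0  # within the finest angular step
        assert np.median(shift_err) <= 1.0

    def test_mean_cc_nondecreasing_noise_free(self, leaf, wedge60):
        # realistic protocol: the starting reference is the average at the
        # (perturbed) starting poses, and improves as the poses do
        subs, wedges, truth = self._stack(leaf, wedge60, 8, seed=22)
        start = truth.copy()
        start["psi"] += 5.0
        start[["shift_x", "shift_y", "shift_z"]] = 0.0
        poses0 = [pose_from_row(r) for _, r in start.iterrows()]
        initial_ref = average_particles(subs, poses0, wedges)
        step = ScheduleStep(cone_deg=6.0, cone_step_deg=3.0, inplane_range_deg=6.0,
                            inplane_step_deg=3.0, shift_limit=2.0, lowpass=None)
        _, _, log = iterate_alignment(subs, wedges, start, initial_ref,
                                      AlignmentSchedule([step], max_iterations=3))
        ccs = [entry["mean_cc"] for entry in log]
        assert all(b >= a - 1e-3 for a, b in zip(ccs, ccs[1:]))


class TestCleaning:
    def test_absolute_threshold(self):
        t = _score_table([0.9, 0.5, 0.1])
        kept = clean_by_cc(t, ("absolute", 0.4))
        assert sorted(kept["cc"]) == [0.5, 0.9]

    def test_threshold_below_min_keeps_all(self):
        t = _score_table([0.9, 0.5, 0.1])
        assert len(clean_by_cc(t, ("absolute", 0.0))) == 3

    def test_sigma_rule_removes_expected_tail(self, rng):
        scores = rng.normal(0.5, 0.1, size=20000)
        t = _score_table(scores)
        kept = clean_by_cc(t, ("sigma", 1.0))
        removed = 1.0 - len(kept) / len(t)
        assert removed == pytest.approx(0.1587, abs=0.02)

    def test_empty_result_errors(self):
        t = _score_table([0.1, 0.2])
        with pytest.raises(ValueError, match="review"):
            clean_by_cc(t, ("absolute", 0.9))


def _score_table(scores):
    n = len(scores)
    return pd.DataFrame(
        {"particle_id": np.arange(n), "vesicle_id": 1, "x": np.arange(n, dtype=float),
         "y": 0.0, "z": 0.0, "rot": 0.0, "tilt": 0.0, "psi": 0.0, "cc": scores}
    )


class TestDeduplication:
    def test_closer_pair_keeps_higher_cc(self):
        t = _score_table([0.9, 0.8])
        t["x"] = [0.0, 5.0]
        kept = remove_duplicates(t, 10.0)
        assert list(kept["cc"]) == [0.9]

    def test_pair_exactly_at_threshold_both_kept(self):
        t = _score_table([0.9, 0.8])
        t["x"] = [0.0, 10.0]
        assert len(remove_duplicates(t, 10.0)) == 2

    def test_matches_bruteforce_oracle_and_idempotent(self, rng):
        for trial in range(5):
            n = 40
            t = _score_table(rng.uniform(0, 1, n))
            t["x"] = rng.uniform(0, 30, n)
            t["y"] = rng.uniform(0, 30, n)
            t["z"] = rng.uniform(0, 30, n)
            kept = remove_duplicates(t, 6.0)
            # independent O(n^2) greedy oracle
            order = sorted(range(n), key=lambda i: (-t["cc"].iloc[i], t["particle_id"].iloc[i]))
            pos = t[["x", "y", "z"]].to_numpy()
            oracle = []
            for i in order:
                if all(np.linalg.norm(pos[i] - pos[j]) >= 6.0 for j in oracle):
                    oracle.append(i)
            assert sorted(kept["particle_id"]) == sorted(t["particle_id"].iloc[oracle])
            again = remove_duplicates(kept, 6.0)
            pd.testing.assert_frame_equal(kept, again)
            assert len(kept) <= n
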