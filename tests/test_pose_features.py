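import numpy as np
import pytest
from hypothesis import given, strategies as st

from podscape.pose_features import (
    DEFAULT_FEATURES,
    PMFCurve,
    REDUCED_FEATURES,
    compute_pose_features,
    eigenvalue_vector,
    ks_resample_test,
    ks_statistic,
    pmf,
    sample_from_pmf,
    summarize_pmf,
)
from podscape.skeleton_io import SkeletonTrajectory
from podscape.synthetic_data import generate_skeleton, hyper_profile, hypo_profile
from podscape.skeleton_io import open_field_arena
from conftest import make_frames


def feature_map(traj, names=DEFAULT_FEATURES):
    return {s.feature_name: s for s in compute_pose_features(traj, names)}


class TestFeatureDefinitions:
    def test_static_trajectory_has_zero_speeds(self, static_trajectory):
        feats = feature_map(static_trajectory)
        for name in ("back_speed", "nose_speed", "left_front_claw_speed",
                     "right_front_claw_speed", "body_speed", "acceleration",
                     "angular_velocity"):
            np.testing.assert_allclose(feats[name].values, 0.0, atol=1e-12)

    def test_length_is_nose_tail_distance(self):
        frames = make_frames(5, {"nose": (40, 0, 0), "root_tail": (0, 0, 0)})
        feats = feature_map(SkeletonTrajectory(frames=frames), ["length"])
        np.testing.assert_allclose(feats["length"].values, 40.0)

    def test_widths(self):
        frames = make_frames(3, {
            "left_front_limb": (0, 6, 0), "right_front_limb": (0, -6, 0),
            "left_hind_limb": (0, 0, 5), "right_hind_limb": (0, 0, -5),
        })
        feats = feature_map(
            SkeletonTrajectory(frames=frames), ["front_width", "hind_width"]
        )
        np.testing.assert_allclose(feats["front_width"].values, 12.0)
        np.testing.assert_allclose(feats["hind_width"].values, 10.0)

    def test_spine_angle_straight_and_right_angle(self):
        straight = make_frames(3, {
            "neck": (10, 0, 0), "back": (0, 0, 0), "root_tail": (-10, 0, 0)
        })
        bent = make_frames(3, {
            "neck": (10, 0, 0), "back": (0, 0, 0), "root_tail": (0, -10, 0)
        })
        s = feature_map(SkeletonTrajectory(frames=straight), ["spine_angle"])
        b = feature_map(SkeletonTrajectory(frames=bent), ["spine_angle"])
        np.testing.assert_allclose(s["spine_angle"].values, np.pi, atol=1e-12)
        np.testing.assert_allclose(b["spine_angle"].values, np.pi / 2, atol=1e-12)

    def test_heights_are_z(self):
        frames = make_frames(3, {"neck": (0, 0, 33.0), "back": (1, 0, 21.0)})
        feats = feature_map(
            SkeletonTrajectory(frames=frames), ["neck_height", "back_height"]
        )
        np.testing.assert_allclose(feats["neck_height"].values, 33.0)
        np.testing.assert_allclose(feats["back_height"].values, 21.0)

    def test_unknown_feature_rejected(self, static_trajectory):
        with pytest.raises(ValueError, match="unknown pose feature"):
            compute_pose_features(static_trajectory, ["tail_speed"])

    def test_rigid_motion_invariance(self, random_trajectory):
        """Distances, speeds and angles are invariant to rotation about z
        plus translation; heights to x,y translation only."""
        theta = 0.7
        R = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        moved = SkeletonTrajectory(
            frames=random_trajectory.frames @ R.T + np.array([120.0, -50.0, 0.0])
        )
        base = feature_map(random_trajectory)
        after = feature_map(moved)
        for name in DEFAULT_FEATURES:
            np.testing.assert_allclose(
                after[name].values, base[name].values, atol=1e-8,
                err_msg=name,
            )
        # heights change under z translation, distances do not
        lifted = SkeletonTrajectory(
            frames=random_trajectory.frames + np.array([0.0, 0.0, 30.0])
        )
        lifted_feats = feature_map(lifted)
        np.testing.assert_allclose(
            lifted_feats["back_height"].values,
            base["back_height"].values + 30.0,
        )
        np.testing.assert_allclose(
            lifted_feats["length"].values, base["length"].values, atol=1e-8
        )


class TestPMF:
    def test_uniform_values(self):
        values = np.arange(100) / 100.0
        curve = pmf(values, bins=50)
        assert curve.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(curve.probabilities, 0.02)

    def test_constant_series_single_occupied_bin(self):
        curve = pmf(np.full(20, 3.7))
        assert (curve.probabilities > 0).sum() == 1
        assert curve.probabilities.max() == pytest.approx(1.0)

    def test_two_point_masses(self):
        values = np.concatenate([np.zeros(30), np.ones(70)])
        curve = pmf(values, bins=50)
        occupied = curve.probabilities[curve.probabilities > 0]
        np.testing.assert_allclose(sorted(occupied), [0.3, 0.7])


class TestSummarize:
    def test_uniform_curve(self):
        curve = pmf(np.arange(100) / 100.0, bins=50)
        mean, median, sd, q25, q75, lo, hi = summarize_pmf(curve)
        assert mean == median == lo == hi == pytest.approx(0.02)
        assert sd == pytest.approx(0.0)

    def test_one_hot_curve(self):
        curve = pmf(np.full(20, 5.0), bins=50)
        stats = summarize_pmf(curve)
        assert stats[6] == pytest.approx(1.0)  # max
        assert stats[5] == pytest.approx(0.0)  # min
        assert stats[0] == pytest.approx(0.02)  # mean = 1/50

    @given(st.integers(0, 10_000))
    def test_order_statistics_ordered(self, seed):
        rng = np.random.default_rng(seed)
        curve = pmf(rng.normal(size=200), bins=50)
        _, median, _, q25, q75, lo, hi = summarize_pmf(curve)
        assert lo <= q25 <= median <= q75 <= hi

    def test_value_level_statistics_describe_distribution(self):
        rng = np.random.default_rng(0)
        values = rng.normal(10.0, 2.0, size=200_000)
        stats = summarize_pmf(pmf(values), on="values")
        assert stats[0] == pytest.approx(10.0, abs=0.1)  # mean
        assert stats[2] == pytest.approx(2.0, abs=0.1)  # sd


class TestEigenvalueVector:
    def test_dimensionality_91_77_7(self, random_trajectory):
        assert len(eigenvalue_vector(random_trajectory, DEFAULT_FEATURES)) == 91
        assert len(eigenvalue_vector(random_trajectory, REDUCED_FEATURES)) == 77
        assert len(eigenvalue_vector(random_trajectory, ["length"])) == 7

    def test_deterministic(self, random_trajectory):
        a = eigenvalue_vector(random_trajectory)
        b = eigenvalue_vector(random_trajectory)
        np.testing.assert_array_equal(a.values, b.values)


def brute_force_ks(x, y):
    pooled = np.concatenate([x, y])
    best = 0.0
    for p in pooled:
        best = max(best, abs((x <= p).mean() - (y <= p).mean()))
    return best


class TestKSTest:
    def test_identical_curves_same_seed_gives_zero(self):
        curve = pmf(np.random.default_rng(0).normal(size=500))
        result = ks_resample_test(curve, curve, seed=7)
        assert result.D == 0.0 and not result.reject

    def test_disjoint_supports(self):
        a = pmf(np.random.default_rng(0).uniform(0, 1, 300))
        b = pmf(np.random.default_rng(1).uniform(10, 11, 300))
        result = ks_resample_test(a, b, seed=0, seed_b=1)
        assert result.D == 1.0 and result.reject

    def test_statistic_matches_brute_force(self):
        for i in range(20):
            rng = np.random.default_rng(i)
            x = rng.normal(size=50)
            y = rng.normal(0.4, 1.3, size=50)
            assert ks_statistic(x, y) == pytest.approx(brute_force_ks(x, y), abs=1e-12)

    def test_deterministic_under_seed(self):
        a = pmf(np.random.default_rng(0).normal(size=500))
        b = pmf(np.random.default_rng(1).normal(0.5, size=500))
        r1 = ks_resample_test(a, b, seed=3, seed_b=4)
        r2 = ks_resample_test(a, b, seed=3, seed_b=4)
        assert r1.D == r2.D and r1.reject == r2.reject

    def test_type_one_error_calibrated(self):
        curve = pmf(np.random.default_rng(0).normal(size=5000))
        rejections = sum(
            ks_resample_test(curve, curve, seed=2 * i, seed_b=2 * i + 1).reject
            for i in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_power_on_speed_scale_ratio_two(self):
        arena = open_field_arena()
        fast = generate_skeleton(hyper_profile(), arena, 10_000, seed=0)
        slow = generate_skeleton(hypo_profile(), arena, 10_000, seed=1)

        def back_speed_curve(traj):
            series = [s for s in compute_pose_features(traj, ["back_speed"])][0]
            return pmf(series)

        a, b = back_speed_curve(fast), back_speed_curve(slow)
        rejections = sum(
            ks_resample_test(a, b, seed=2 * i, seed_b=2 * i + 1).reject
            for i in range(200)
        )
        assert rejections / 200 >= 0.95

    def test_small_resample_rejected(self):
        curve = pmf(np.random.default_rng(0).normal(size=100))
        with pytest.raises(ValueError):
            ks_resample_test(curve, curve, n_resample=1)

    def test_samples_respect_pmf_support(self):
        curve = pmf(np.random.default_rng(0).uniform(5, 6, 500))
        draws = sample_from_pmf(curve, 1000, np.random.default_rng(1))
        assert draws.min() >= curve.bin_edges[0]
        assert draws.max() <= curve.bin_edges[-1]
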