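import numpy as np
import pytest
from hypothesis import given, strategies as st

from podscape.behavior_metrics import (
    CENTRE_RADIUS_OFT_MM,
    CompositeZInputs,
    centre_time,
    composite_z,
    movement_fractions,
    novel_time_ratio,
    recognition_index,
    select_significant_movements,
)
from podscape.skeleton_io import (
    MovementLabelStream,
    SkeletonTrajectory,
    SkeletonValidationError,
    open_field_arena,
)
from podscape.synthetic_data import (
    DISCRIMINATIVE_CLASSES,
    control_profile,
    generate_labels,
    nonpod_profile,
    pod_profile,
)
from conftest import make_frames


class TestMovementFractions:
    def test_point_mass(self):
        fv = movement_fractions(MovementLabelStream(labels=np.ones(50, dtype=int)))
        assert fv.fractions[0] == 1.0 and fv.fractions[1:].sum() == 0.0

    def test_counting(self):
        labels = np.concatenate([np.full(25, 2), np.full(75, 3)])
        fv = movement_fractions(MovementLabelStream(labels=labels))
        assert fv.fractions[1] == pytest.approx(0.25)
        assert fv.fractions[2] == pytest.approx(0.75)

    @given(st.integers(0, 10_000))
    def test_conservation_and_relabelling(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(1, 41, size=200)
        fv = movement_fractions(MovementLabelStream(labels=labels))
        assert fv.fractions.sum() == pytest.approx(1.0, abs=1e-12)
        # permuting the class alphabet permutes fractions identically
        perm = rng.permutation(40)
        relabelled = perm[labels - 1] + 1
        fv2 = movement_fractions(MovementLabelStream(labels=relabelled))
        np.testing.assert_allclose(fv2.fractions[perm], fv.fractions)


class TestSelectSignificantMovements:
    def test_identical_groups_select_nothing(self):
        fv = movement_fractions(
            MovementLabelStream(labels=np.tile(np.arange(1, 41), 10))
        )
        comparison = select_significant_movements([fv] * 5, [fv] * 5)
        assert comparison.selected == ()

    def test_alpha_zero_selects_nothing(self):
        rng = np.random.default_rng(0)
        groups = [
            [movement_fractions(MovementLabelStream(labels=rng.integers(1, 41, 500)))
             for _ in range(5)]
            for _ in range(2)
        ]
        comparison = select_significant_movements(groups[0], groups[1], alpha=0.0)
        assert comparison.selected == ()

    def test_small_groups_rejected(self):
        fv = movement_fractions(MovementLabelStream(labels=np.ones(40, dtype=int)))
        with pytest.raises(ValueError):
            select_significant_movements([fv], [fv, fv])

    def test_recovers_designated_classes(self):
        """POD-shifted classes are recovered in >= 90% of seeded runs."""
        hits = 0
        runs = 50
        for run in range(runs):
            pod = [
                movement_fractions(generate_labels(pod_profile(), 18_000,
                                                   seed=run * 100 + i))
                for i in range(15)
            ]
            non = [
                movement_fractions(generate_labels(nonpod_profile(), 18_000,
                                                   seed=run * 100 + 50 + i))
                for i in range(15)
            ]
            comparison = select_significant_movements(pod, non)
            hits += set(DISCRIMINATIVE_CLASSES) <= set(comparison.selected)
        assert hits / runs >= 0.9

    def test_familywise_error_controlled(self):
        """Under identical distributions any selection is rare (~5% of runs)."""
        false_runs = 0
        runs = 200
        for run in range(runs):
            a = [
                movement_fractions(generate_labels(control_profile(), 9000,
                                                   seed=run * 1000 + i))
                for i in range(10)
            ]
            b = [
                movement_fractions(generate_labels(control_profile(), 9000,
                                                   seed=run * 1000 + 500 + i))
                for i in range(10)
            ]
            false_runs += bool(select_significant_movements(a, b).selected)
        assert false_runs / runs <= 0.09


class TestCentreTime:
    arena = open_field_arena()

    def test_pinned_at_centre(self):
        frames = make_frames(300, {"back": (0.0, 0.0, 20.0)})
        traj = SkeletonTrajectory(frames=frames, frame_rate=30.0)
        assert centre_time(traj, self.arena) == pytest.approx(10.0)

    def test_pinned_at_wall(self):
        frames = make_frames(300, {"back": (240.0, 0.0, 20.0)})
        traj = SkeletonTrajectory(frames=frames, frame_rate=30.0)
        assert centre_time(traj, self.arena) == 0.0

    def test_mixed_path_matches_per_frame_count(self):
        rng = np.random.default_rng(5)
        frames = make_frames(400)
        path = rng.uniform(-150, 150, size=(400, 2))
        frames[:, :, 0] += path[:, [0]]
        frames[:, :, 1] += path[:, [1]]
        traj = SkeletonTrajectory(frames=frames, frame_rate=30.0)
        back = traj.keypoint("back")[:, :2]
        expected = (np.hypot(back[:, 0], back[:, 1]) < CENTRE_RADIUS_OFT_MM).sum() / 30.0
        assert centre_time(traj, self.arena) == pytest.approx(expected)

    def test_square_arena_rejected(self):
        from podscape.skeleton_io import novel_object_arena
        frames = make_frames(10)
        with pytest.raises(ValueError):
            centre_time(SkeletonTrajectory(frames=frames), novel_object_arena())


class TestRecognitionIndex:
    def test_symmetry_extremes_and_value(self):
        assert recognition_index(5.0, 5.0) == 0.0
        assert recognition_index(3.0, 0.0) == 1.0
        assert recognition_index(6.0, 4.0) == pytest.approx(0.2)
        assert novel_time_ratio(6.0, 4.0) == pytest.approx(0.6)

    def test_undefined_when_no_exploration(self):
        with pytest.raises(ValueError):
            recognition_index(0.0, 0.0)


class TestCompositeZ:
    control = dict(control_mean=(10.0, 60.0, 0.2), control_sd=(2.0, 10.0, 0.1))

    def test_zero_at_control_mean(self):
        inputs = CompositeZInputs(
            centre_time=10.0, total_exploration_time=60.0,
            recognition_index=0.2, **self.control,
        )
        assert composite_z(inputs) == pytest.approx(0.0)

    def test_one_sd_above_on_each_metric_gives_three(self):
        inputs = CompositeZInputs(
            centre_time=12.0, total_exploration_time=70.0,
            recognition_index=0.3, **self.control,
        )
        assert composite_z(inputs) == pytest.approx(3.0)

    def test_linearity_in_deviations(self):
        one = CompositeZInputs(
            centre_time=11.0, total_exploration_time=65.0,
            recognition_index=0.25, **self.control,
        )
        two = CompositeZInputs(
            centre_time=12.0, total_exploration_time=70.0,
            recognition_index=0.3, **self.control,
        )
        assert composite_z(two) == pytest.approx(2 * composite_z(one))

    def test_degenerate_control_sd_rejected(self):
        with pytest.raises(SkeletonValidationError):
            CompositeZInputs(
                centre_time=10.0, total_exploration_time=60.0,
                recognition_index=0.2,
                control_mean=(10.0, 60.0, 0.2), control_sd=(0.0, 10.0, 0.1),
            )
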