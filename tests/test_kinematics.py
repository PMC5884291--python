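"""Joint angles, angle series and trajectory summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from motionval import (
    ArmModel,
    DegenerateSegmentError,
    NoiseConfig,
    angle_series,
    joint_angle,
    static_pose,
    trajectory_summary,
)
from motionval.synthetic import constant, ramp, simulate_movement

QUIET = NoiseConfig(position_sd=0.0)


class TestJointAngle:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            ((1, 0, 0), (2, 0, 0), 0.0),
            ((1, 0, 0), (0, 1, 0), 90.0),
            ((1, 0, 0), (1, 1, 0), 45.0),
            ((1, 0, 0), (-3, 0, 0), 180.0),
            ((1, 1), (0, 2), 45.0),  # 2-vector (projected) form
        ],
    )
    def test_closed_forms(self, p1, p2, expected):
        assert joint_angle(p1, p2) == pytest.approx(expected, abs=1e-12)

    vectors = st.lists(
        st.floats(min_value=-100, max_value=100, allow_nan=False),
        min_size=3, max_size=3,
    ).map(np.asarray).filter(lambda v: np.linalg.norm(v) > 1e-6)

    @given(vectors, vectors, st.floats(min_value=0.01, max_value=100),
           st.floats(min_value=0.01, max_value=100))
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_scale_invariant(self, a, b, s, t):
        # arccos loses ~sqrt(eps) precision near 0/180 deg, hence 1e-5
        assert joint_angle(a, b) == pytest.approx(joint_angle(b, a), abs=1e-9)
        assert joint_angle(s * a, t * b) == pytest.approx(joint_angle(a, b), abs=1e-5)
        assert 0.0 <= joint_angle(a, b) <= 180.0

    def test_degenerate_vector_error_identifies_argument(self):
        with pytest.raises(DegenerateSegmentError, match="first"):
            joint_angle((0, 0, 0), (1, 0, 0))
        with pytest.raises(DegenerateSegmentError, match="second"):
            joint_angle((1, 0, 0), (1e-12, 0, 0))

    def test_floating_point_overshoot_is_clamped(self):
        # nearly parallel vectors whose normalised dot can exceed 1 in floats
        a = np.array([0.1, 0.2, 0.3])
        for scale in (1e-8, 1e8, 3.0):
            assert joint_angle(a, scale * a) == pytest.approx(0.0, abs=1e-5)
        assert np.isfinite(joint_angle(a, -a))


class TestAngleSeries:
    def test_noiseless_ramp_recovered(self):
        seq = simulate_movement(
            ramp(0, 180, 6.0), "coronal", noise=QUIET, duration=6.0
        )
        series = angle_series(seq, "shoulder_abduction", "right", plane="coronal")
        expected = ramp(0, 180, 6.0)(seq.t)
        assert series.n == seq.n_frames
        assert np.max(np.abs(series.theta - expected)) < 1e-6

    def test_sagittal_flexion_ramp_recovered(self):
        seq = simulate_movement(
            ramp(0, 120, 4.0), "sagittal", noise=QUIET, duration=4.0
        )
        series = angle_series(seq, "shoulder_flexion", "right", plane="sagittal")
        assert np.max(np.abs(series.theta - ramp(0, 120, 4.0)(seq.t))) < 1e-6

    def test_axial_ramp_recovered_via_shoulder_horizontal(self):
        seq = simulate_movement(
            ramp(0, 90, 3.0), "axial", noise=QUIET, duration=3.0
        )
        series = angle_series(seq, "shoulder_horizontal", "right", plane="axial")
        assert np.max(np.abs(series.theta - ramp(0, 90, 3.0)(seq.t))) < 1e-6

    def test_static_pose_gives_constant_series(self):
        seq = static_pose(60.0, "coronal", noise=QUIET, n_frames=30)
        series = angle_series(seq, "shoulder_abduction", "right", plane="coronal")
        assert np.allclose(series.theta, 60.0, atol=1e-9)

    def test_degenerate_frame_marked_missing_not_interpolated(self):
        seq = static_pose(90.0, "coronal", noise=QUIET, n_frames=10)
        positions = {j: p.copy() for j, p in seq.positions.items()}
        positions["elbow_right"][4] = positions["shoulder_right"][4]  # zero arm vector
        broken = seq.with_positions(positions)
        series = angle_series(broken, "shoulder_abduction", "right", plane="coronal")
        assert np.isnan(series.theta[4])
        mask = np.ones(10, bool)
        mask[4] = False
        assert np.allclose(series.theta[mask], 90.0, atol=1e-9)

    def test_rotation_invariance_of_3d_angles(self, rng):
        seq = simulate_movement(ramp(10, 170, 2.0), "coronal", noise=QUIET, duration=2.0)
        rot = Rotation.random(random_state=7).as_matrix()
        rotated = seq.with_positions(
            {j: p @ rot.T for j, p in seq.positions.items()}
        )
        # the straight elbow sits at 180 deg where arccos conditioning
        # limits agreement to ~1e-6 deg; the shoulder angle is well away
        # from the ends and must match to 1e-9 deg
        for joint, atol in (("shoulder_abduction", 1e-9), ("elbow", 1e-5)):
            a = angle_series(seq, joint, "right", plane=None).theta
            b = angle_series(rotated, joint, "right", plane=None).theta
            assert np.allclose(a, b, atol=atol)

    def test_unknown_articulation_rejected(self):
        seq = static_pose(10.0, "coronal", noise=QUIET)
        with pytest.raises(ValueError, match="unknown articulation"):
            angle_series(seq, "knee", "right")


class TestTrajectorySummary:
    ARC_ARM = ArmModel(upper_arm=0.1, forearm=0.1, hand=0.1)  # wrist radius 0.2

    def test_quarter_circle_path_length(self):
        # hand traces a radius-0.3 arc about the shoulder pivot
        seq = simulate_movement(
            ramp(0, 90, 3.0), "coronal", arm=self.ARC_ARM, noise=QUIET, duration=3.0
        )
        ts = trajectory_summary(seq, "hand_right", plane="coronal")
        assert ts.path_length == pytest.approx(np.pi * 0.3 / 2, rel=0.02)
        assert ts.rom == pytest.approx(89.0, abs=1.5)  # last sample short of 90

    def test_semicircle_hull_area(self):
        seq = simulate_movement(
            ramp(0, 180, 6.0), "coronal", arm=self.ARC_ARM, noise=QUIET, duration=6.0
        )
        ts = trajectory_summary(seq, "hand_right", plane="coronal")
        assert ts.area == pytest.approx(np.pi * 0.3**2 / 2, rel=0.02)

    def test_static_pose_degenerates_to_zero(self):
        seq = static_pose(45.0, "coronal", noise=QUIET, n_frames=10)
        with pytest.warns(UserWarning, match="covered area"):
            ts = trajectory_summary(seq, "hand_right", plane="coronal")
        assert ts.rom == pytest.approx(0.0, abs=1e-9)
        assert ts.area == 0.0
        assert ts.path_length == pytest.approx(0.0, abs=1e-12)

    def test_collinear_path_warns_and_zeroes_area(self):
        seq = simulate_movement(
            constant(90.0), "coronal", noise=QUIET, duration=1.0
        )
        positions = {j: p.copy() for j, p in seq.positions.items()}
        positions["hand_right"][:, 0] += np.linspace(0, 0.1, seq.n_frames)
        moved = seq.with_positions(positions)
        with pytest.warns(UserWarning, match="collinear"):
            ts = trajectory_summary(moved, "hand_right", plane="coronal")
        assert ts.area == 0.0
        assert ts.path_length == pytest.approx(0.1, rel=1e-6)

    def test_summary_report_keys(self):
        seq = simulate_movement(
            ramp(0, 90, 3.0), "coronal", arm=self.ARC_ARM, noise=QUIET, duration=3.0
        )
        rep = trajectory_summary(seq, "hand_right", plane="coronal").to_report()
        assert set(rep) == {"rom_deg", "area_m2", "path_length_m", "n_frames"}
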