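"""Per-frame kinematics: classification boundaries, angles, oracle equivalence."""

import math

import numpy as np
import pandas as pd
import pytest

from zlap.errors import InputError
from zlap.kinematics import (FEATURE_COLUMNS, body_axis_angle, build_feature_table,
                             classify_step, compute_feature_arrays,
                             displacement_series, frame_validity,
                             orientation_flags, spatial_flags, turn_series,
                             wrap_angle)
from zlap.pose_io import POSE_COLUMNS, PoseFrame
from zlap.well_grid import WellCircle

WELL = WellCircle(cx=100.0, cy=100.0, radius=75.0, row=0, col=0, well_id="A1")


def pose(x_yolk, y_yolk, eyes_mid=None, p=(0.9, 0.9, 0.9), frame=0):
    """PoseFrame with the eye pair symmetric about ``eyes_mid`` (image coords)."""
    if eyes_mid is None:
        eyes_mid = (x_yolk + 9.0, y_yolk)
    mx, my = eyes_mid
    return PoseFrame(frame, x_yolk, y_yolk, p[0],
                     mx, my - 3.0, p[1], mx, my + 3.0, p[2])


class TestValidity:
    @pytest.mark.parametrize("probs, expected", [
        ((0.9, 0.9, 0.9), True),
        ((0.9, 0.49, 0.9), False),   # any part below 0.5 invalidates
        ((0.5, 0.5, 0.5), True),     # the exclusion is strict '< 0.5'
        ((0.0, 1.0, 1.0), False),
    ])
    def test_threshold_boundary(self, probs, expected):
        assert frame_validity(pose(50, 50, p=probs)) is expected


class TestDisplacement:
    def test_three_four_five(self):
        d = displacement_series([(0, 0), (3, 4)], [True, True])
        assert d == [None, 5.0]

    def test_stationary(self):
        d = displacement_series([(7, 7)] * 4, [True] * 4)
        assert d == [None, 0.0, 0.0, 0.0]

    def test_invalid_frame_nulls_both_neighbors(self):
        d = displacement_series([(0, 0), (1, 0), (2, 0), (3, 0)],
                                [True, False, True, True])
        assert d == [None, None, None, 1.0]


class TestStepClass:
    @pytest.mark.parametrize("d, expected", [
        (10.0, "scoot"), (25.0, "burst"),
        (3.0, "none"),    # moved requires strictly > 3 px
        (20.0, "scoot"),  # burst requires strictly > 20 px
        (None, None),
    ])
    def test_boundaries(self, d, expected):
        assert classify_step(d) == expected


class TestSpatialFlags:
    def test_above_center(self):
        up, radial, edge = spatial_flags((100, 70), WELL)  # 30 px above (image y-down)
        assert (up, radial, edge) == (True, 30.0, False)

    def test_midline_counts_as_lower_half(self):
        up, radial, edge = spatial_flags((140, 100), WELL)  # 40 px right of center
        assert up is False
        assert edge is True  # 40 > 0.5 * 75

    def test_center(self):
        assert spatial_flags((100, 100), WELL) == (False, 0.0, False)


class TestBodyAxisAngle:
    def test_heading_east_is_zero(self):
        p = PoseFrame(0, 0, 0, 1, 9, 3, 1, 9, -3, 1)
        assert body_axis_angle(p) == pytest.approx(0.0)

    def test_heading_up_is_plus_ninety(self):
        assert body_axis_angle(pose(50, 50, eyes_mid=(50, 41))) == pytest.approx(90.0)

    def test_heading_west_is_plus_180(self):
        assert body_axis_angle(pose(50, 50, eyes_mid=(41, 50))) == pytest.approx(180.0)

    def test_degenerate_pose_is_null(self):
        assert body_axis_angle(pose(50, 50, eyes_mid=(50, 50))) is None


class TestOrientationFlags:
    def test_east_of_center_heading_south_is_clockwise(self):
        p = pose(150, 100, eyes_mid=(150, 109))  # heading due south (image y-down)
        cw, upward = orientation_flags(p, WELL)
        assert (cw, upward) == (True, False)

    def test_east_of_center_heading_north_is_counterclockwise(self):
        p = pose(150, 100, eyes_mid=(150, 91))
        cw, upward = orientation_flags(p, WELL)
        assert (cw, upward) == (False, True)

    def test_clockwise_null_near_center(self):
        p = pose(102, 100, eyes_mid=(111, 100))
        cw, _ = orientation_flags(p, WELL)
        assert cw is None

    @pytest.mark.parametrize("angle, expected", [(30.0, True), (-30.0, False)])
    def test_upward_from_heading_angle(self, angle, expected):
        rad = math.radians(angle)
        mid = (50 + 9 * math.cos(rad), 50 - 9 * math.sin(rad))  # image y-down
        _, upward = orientation_flags(pose(50, 50, eyes_mid=mid), WELL)
        assert upward is expected


class TestTurns:
    def test_wrap_across_branch_cut(self):
        [_, t] = turn_series([170.0, -170.0])
        assert t == (pytest.approx(20.0), pytest.approx(20.0))

    def test_constant_angle_zero_turns(self):
        out = turn_series([45.0] * 5)
        assert all(t == (0.0, 0.0) for t in out[1:])

    def test_closed_loop_sums_to_multiple_of_360(self, rng):
        """Sum of wrapped turns around any closed angle path is 0 mod 360."""
        angles = list(rng.uniform(-180, 180, 50))
        angles.append(angles[0])
        total = sum(t[0] for t in turn_series(angles)[1:])
        assert total % 360.0 == pytest.approx(0.0, abs=1e-9) or \
            360 - (total % 360.0) < 1e-9


def random_pose_arrays(rng, n_wells=4, n_frames=250):
    shape = (n_wells, n_frames)
    arr = {}
    for part in ("yolk", "left", "right"):
        arr[f"x_{part}"] = rng.uniform(40, 160, shape)
        arr[f"y_{part}"] = rng.uniform(40, 160, shape)
        arr[f"p_{part}"] = rng.uniform(0, 1, shape)
    return arr


class TestOracleEquivalence:
    """The vectorized table equals a brute-force recomputation from raw coordinates."""

    def test_thousand_random_poses(self, rng):
        arrays = random_pose_arrays(rng, 4, 250)  # 1,000 poses
        wells = [WellCircle(cx=100, cy=100, radius=75, row=0, col=i, well_id=f"A{i+1}")
                 for i in range(4)]
        feats = compute_feature_arrays(arrays, wells)
        for w in range(4):
            poses = [
                PoseFrame(t, *[arrays[k][w, t] for k in POSE_COLUMNS[1:]])
                for t in range(250)
            ]
            valid = [frame_validity(p) for p in poses]
            disp = displacement_series([(p.x_yolk, p.y_yolk) for p in poses], valid)
            angles = [body_axis_angle(p) if valid[t] else None
                      for t, p in enumerate(poses)]
            turns = turn_series(angles)
            for t, p in enumerate(poses):
                assert feats["valid"][w, t] == float(valid[t])
                if disp[t] is None:
                    assert np.isnan(feats["displacement"][w, t])
                    assert np.isnan(feats["moved"][w, t])
                else:
                    assert feats["displacement"][w, t] == pytest.approx(disp[t])
                    cls = classify_step(disp[t])
                    assert feats["moved"][w, t] == float(cls != "none")
                    assert feats["scoot"][w, t] == float(cls == "scoot")
                    assert feats["burst"][w, t] == float(cls == "burst")
                if valid[t]:
                    up, radial, edge = spatial_flags((p.x_yolk, p.y_yolk), wells[w])
                    assert feats["up"][w, t] == float(up)
                    assert feats["radial_dist"][w, t] == pytest.approx(radial)
                    assert feats["edge"][w, t] == float(edge)
                    cw, upward = orientation_flags(p, wells[w])
                    if angles[t] is None:
                        assert np.isnan(feats["angle"][w, t])
                    else:
                        assert feats["angle"][w, t] == pytest.approx(angles[t])
                        assert feats["upward"][w, t] == float(upward)
                        if cw is None:
                            assert np.isnan(feats["clockwise"][w, t])
                        else:
                            assert feats["clockwise"][w, t] == float(cw)
                else:
                    for key in ("up", "radial_dist", "edge", "angle", "upward",
                                "clockwise"):
                        assert np.isnan(feats[key][w, t])
                if turns[t] is None:
                    assert np.isnan(feats["turn"][w, t])
                else:
                    assert feats["turn"][w, t] == pytest.approx(turns[t][0])
                    assert feats["turn_abs"][w, t] == pytest.approx(turns[t][1])


class TestRotationConsistency:
    def test_rotation_about_well_center(self, rng):
        """Rotating all coordinates by theta shifts angles by theta and preserves
        displacement, radial distance, edge and movement classes."""
        theta = 37.0
        arrays = random_pose_arrays(rng, 2, 150)
        well = WellCircle(cx=100, cy=100, radius=75, row=0, col=0, well_id="A1")
        wells = [well, well]
        rad = math.radians(theta)
        rot = {}
        for part in ("yolk", "left", "right"):
            x = arrays[f"x_{part}"] - well.cx
            y = well.cy - arrays[f"y_{part}"]  # to y-up
            xr = x * math.cos(rad) - y * math.sin(rad)
            yr = x * math.sin(rad) + y * math.cos(rad)
            rot[f"x_{part}"] = well.cx + xr
            rot[f"y_{part}"] = well.cy - yr
            rot[f"p_{part}"] = arrays[f"p_{part}"]
        base = compute_feature_arrays(arrays, wells)
        turned = compute_feature_arrays(rot, wells)
        for key in ("displacement", "radial_dist", "edge", "scoot", "burst",
                    "moved", "turn", "turn_abs"):
            np.testing.assert_allclose(turned[key], base[key], atol=1e-8,
                                       equal_nan=True, err_msg=key)
        defined = ~np.isnan(base["angle"])
        shift = (turned["angle"] - base["angle"])[defined] % 360.0
        shift = np.minimum(shift, 360.0 - shift)
        np.testing.assert_allclose(shift, theta, atol=1e-8)


class TestFeatureTable:
    def test_shape_and_periods(self, control_features):
        assert control_features.shape == (1800, 33)
        assert list(control_features.columns) == FEATURE_COLUMNS
        assert control_features.loc[0, "period"] == 1
        assert control_features.loc[1799, "period"] == 18
        assert (control_features.groupby("period").size() == 100).all()
        assert control_features.loc[10, "time_s"] == 60.0

    def test_all_invalid_stream_keeps_rows_with_nulls(self, schedule, well):
        n = 200
        df = pd.DataFrame({"frame": range(n)})
        for part in ("yolk", "left", "right"):
            df[f"x_{part}"] = 100.0
            df[f"y_{part}"] = 100.0
            df[f"p_{part}"] = 0.1
        df = df[POSE_COLUMNS]
        table = build_feature_table({"A1": df}, [well], schedule)
        assert len(table) == n
        assert (table["valid"] == 0).all()
        assert table["moved"].isna().all()
        assert table["angle"].isna().all()

    def test_stream_length_mismatch_rejected(self, schedule, well):
        import dataclasses

        df1 = pd.DataFrame(0.6, index=range(10), columns=POSE_COLUMNS)
        df1["frame"] = range(10)
        df2 = df1.iloc[:5].copy()
        other = dataclasses.replace(well, well_id="A2")
        with pytest.raises(InputError):
            build_feature_table({"A1": df1, "A2": df2}, [well, other], schedule)

    def test_well_times_frames_rows(self, schedule):
        wells = [WellCircle(cx=100 + 160 * i, cy=100, radius=75, row=0, col=i,
                            well_id=f"A{i+1}") for i in range(3)]
        df = pd.DataFrame(0.8, index=range(40), columns=POSE_COLUMNS)
        df["frame"] = range(40)
        table = build_feature_table({w.well_id: df for w in wells}, wells, schedule)
        assert len(table) == 3 * 40
        assert table.shape[1] == 33


def test_wrap_angle_conventions():
    assert wrap_angle(-180.0) == 180.0
    assert wrap_angle(540.0) == 180.0
    assert wrap_angle(-20.0) == -20.0
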