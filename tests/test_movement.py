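"""Posture grid, leg inverse kinematics, trajectories and adoption filters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sitstand import StudyConfig, build_body_model
from sitstand.movement import (
    STSMovement,
    SeatOffPosture,
    apply_adoption_filters,
    classify_normal,
    compute_joint_angles,
    cosine_weight,
    generate_posture_grid,
    generate_trajectory,
    solve_leg_configuration,
    whole_body_com_x,
)


class TestPostureGrid:
    def test_grid_cardinality(self, study):
        movements, _ = study
        assert len(movements) == 2911  # 41 x 71

    def test_hip_x_spacing_is_one_centimetre(self, body, cfg):
        postures = generate_posture_grid(body, cfg)
        xs = sorted({p.hip_xy[0] for p in postures})
        assert len(xs) == 41
        assert np.allclose(np.diff(xs), 0.01)

    def test_zero_trunk_angle_means_vertical_trunk(self, body, cfg):
        postures = [p for p in generate_posture_grid(body, cfg) if p.trunk_angle == 0]
        assert len(postures) == 41
        # a vertical trunk contributes nothing beyond the thigh depression to
        # hip flexion: hip angle equals the thigh's forward angle
        p = next(p for p in postures if p.valid)
        trunk_down = (0.0, -1.0)
        v = (p.knee_xy[0] - p.hip_xy[0], p.knee_xy[1] - p.hip_xy[1])
        expected = math.degrees(
            math.atan2(trunk_down[0] * v[1] - trunk_down[1] * v[0],
                       trunk_down[0] * v[0] + trunk_down[1] * v[1])
        )
        assert p.hip_angle == pytest.approx(expected, abs=1e-9)


class TestLegConfiguration:
    def test_fully_extended_limit_is_collinear(self):
        knee = solve_leg_configuration((0.0, 0.9), (0.0, 0.0), 0.45, 0.45)
        assert knee == pytest.approx((0.0, 0.45), abs=1e-9)

    def test_unreachable_returns_none(self):
        assert solve_leg_configuration((0.0, 2.0), (0.0, 0.0), 0.45, 0.45) is None
        assert solve_leg_configuration((0.0, 0.01), (0.0, 0.0), 0.45, 0.10) is None

    @given(
        hx=st.floats(-0.4, 0.0),
        hy=st.floats(0.45, 0.6),
        lt=st.floats(0.3, 0.5),
        ls=st.floats(0.3, 0.5),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_solution_satisfies_both_distance_constraints(self, hx, hy, lt, ls):
        knee = solve_leg_configuration((hx, hy), (0.0, 0.0), lt, ls)
        if knee is None:
            d = math.hypot(hx, hy)
            assert d > lt + ls or d < abs(lt - ls)
        else:
            assert math.hypot(knee[0] - hx, knee[1] - hy) == pytest.approx(lt, abs=1e-9)
            assert math.hypot(*knee) == pytest.approx(ls, abs=1e-9)

    def test_anterior_solution_against_hand_circle_intersection(self):
        # hand solution: circles centred at hip (r=thigh) and ankle (r=shank)
        hip, ankle, lt, ls = (-0.2, 0.513), (0.0, 0.0679), 0.4263, 0.42804
        d = math.hypot(hip[0] - ankle[0], hip[1] - ankle[1])
        a = (lt**2 - ls**2 + d**2) / (2 * d)
        h = math.sqrt(lt**2 - a**2)
        ux, uy = (ankle[0] - hip[0]) / d, (ankle[1] - hip[1]) / d
        candidates = [
            (hip[0] + a * ux + h * uy, hip[1] + a * uy - h * ux),
            (hip[0] + a * ux - h * uy, hip[1] + a * uy + h * ux),
        ]
        expected = max(candidates, key=lambda c: c[0])
        knee = solve_leg_configuration(hip, ankle, lt, ls)
        assert knee == pytest.approx(expected, abs=1e-12)


class TestJointAngles:
    def test_standing_posture_is_all_zero(self):
        posture = SeatOffPosture(
            hip_xy=(0.0, 0.9), trunk_angle=0.0, ankle_xy=(0.0, 0.0),
            knee_xy=(0.0, 0.45),
        )
        assert compute_joint_angles(posture) == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)

    def test_angles_against_independent_vector_arithmetic(self, body, cfg):
        p = next(
            p for p in generate_posture_grid(body, cfg)
            if p.valid and p.trunk_angle == 30 and abs(p.hip_xy[0] + 0.2) < 1e-9
        )
        # dot-product recomputation with explicit segment vectors
        thigh = np.subtract(p.knee_xy, p.hip_xy)
        shank = np.subtract(p.ankle_xy, p.knee_xy)
        knee_hand = math.degrees(
            math.acos(np.dot(thigh, shank) / np.linalg.norm(thigh) / np.linalg.norm(shank))
        )
        ankle_hand = 90.0 - math.degrees(
            math.atan2(p.knee_xy[1] - p.ankle_xy[1], p.knee_xy[0] - p.ankle_xy[0])
        )
        trunk = np.array([math.sin(math.radians(30)), math.cos(math.radians(30))])
        hip_hand = math.degrees(
            math.acos(np.dot(-trunk, thigh) / np.linalg.norm(thigh))
        )
        assert p.knee_angle == pytest.approx(knee_hand, abs=1e-9)
        assert p.ankle_angle == pytest.approx(ankle_hand, abs=1e-9)
        assert p.hip_angle == pytest.approx(hip_hand, abs=1e-9)

    def test_invalid_posture_raises(self):
        posture = SeatOffPosture(
            hip_xy=(0.0, 2.0), trunk_angle=0.0, ankle_xy=(0.0, 0.0), valid=False
        )
        with pytest.raises(ValueError):
            compute_joint_angles(posture)

    def test_grid_angles_round_trip_to_positions(self, body, cfg):
        """Joint positions reconstructed from the joint angles must match the
        grid geometry (spec round-trip invariant)."""
        from sitstand.movement import joint_and_com_positions

        postures = [p for p in generate_posture_grid(body, cfg) if p.valid]
        for p in postures[:: 97]:
            pos = joint_and_com_positions(
                math.radians(p.hip_angle), math.radians(p.knee_angle),
                math.radians(p.ankle_angle), body,
            )
            assert pos["hip"][..., 0] == pytest.approx(p.hip_xy[0], abs=1e-6)
            assert pos["hip"][..., 1] == pytest.approx(p.hip_xy[1], abs=1e-6)
            assert pos["knee"][..., 0] == pytest.approx(p.knee_xy[0], abs=1e-6)


class TestTrajectory:
    def test_cosine_weight_endpoints_and_midpoint(self):
        assert cosine_weight(0.0, 1.55) == pytest.approx(1.0)
        assert cosine_weight(1.55, 1.55) == pytest.approx(0.0, abs=1e-15)
        assert cosine_weight(0.775, 1.55) == pytest.approx(0.5)

    def test_series_scale_from_seatoff_to_zero(self):
        posture = SeatOffPosture(
            hip_xy=(0.0, 0.513), trunk_angle=20.0, ankle_xy=(0.0, 0.0),
            knee_xy=(0.3, 0.3), hip_angle=100.0, knee_angle=110.0, ankle_angle=30.0,
        )
        mv = generate_trajectory(posture, duration=1.55, n_frames=101)
        assert mv.hip_series[0] == pytest.approx(100.0)
        assert mv.hip_series[-1] == pytest.approx(0.0, abs=1e-12)
        assert mv.hip_series[50] == pytest.approx(50.0)
        for series in (mv.hip_series, mv.knee_series, mv.ankle_series):
            assert np.all(np.diff(series) <= 1e-12)
            assert np.all(series >= -1e-12)

    def test_too_few_frames_rejected(self):
        posture = SeatOffPosture(
            hip_xy=(0.0, 0.513), trunk_angle=0.0, ankle_xy=(0.0, 0.0),
            knee_xy=(0.3, 0.3), hip_angle=90.0, knee_angle=100.0, ankle_angle=20.0,
        )
        with pytest.raises(ValueError):
            generate_trajectory(posture, 1.55, 2)


class TestWholeBodyCom:
    def test_mid_movement_frame_matches_hand_summation(self, body, adopted):
        from sitstand.movement import joint_and_com_positions

        mv = adopted[0]
        frame = mv.n_frames // 2
        pos = joint_and_com_positions(
            math.radians(mv.hip_series[frame]),
            math.radians(mv.knee_series[frame]),
            math.radians(mv.ankle_series[frame]),
            body,
        )
        hand = (
            body.hat.mass * pos["hat_com"][..., 0]
            + 2 * body.thigh.mass * pos["thigh_com"][..., 0]
            + 2 * body.shank.mass * pos["shank_com"][..., 0]
            + 2 * body.foot.mass * pos["foot_com"][..., 0]
        ) / body.mass
        assert whole_body_com_x(mv, body, frame) == pytest.approx(float(hand), abs=1e-12)

    def test_hat_only_body_reduces_to_hat_com(self, cfg):
        import pandas as pd

        from sitstand.body import load_fraction_table
        from sitstand.movement import com_x_series, joint_and_com_positions

        table = load_fraction_table().copy()
        table.loc[["thigh", "shank", "foot"], "mass_fraction"] = 0.0
        table.loc["hat", "mass_fraction"] = 1.0
        single = build_body_model(1.74, 73.8, table, config=cfg)
        com = com_x_series(100.0, 105.0, 30.0, single)
        pos = joint_and_com_positions(
            math.radians(100.0), math.radians(105.0), math.radians(30.0), single
        )
        assert com == pytest.approx(pos["hat_com"][..., 0], abs=1e-12)

    def test_frame_index_bounds(self, body, adopted):
        with pytest.raises(IndexError):
            whole_body_com_x(adopted[0], body, adopted[0].n_frames)

    def test_standing_com_inside_foot_base(self, body):
        from sitstand.movement import com_x_series

        com = float(com_x_series(0.0, 0.0, 0.0, body))
        assert body.heel_x <= com <= body.toe_x


class TestAdoptionFilters:
    def _movement(self, hip, knee, ankle, body):
        posture = SeatOffPosture(
            hip_xy=(-0.1, 0.513), trunk_angle=20.0, ankle_xy=(0.0, body.ankle_height),
            knee_xy=(0.3, 0.4), hip_angle=hip, knee_angle=knee, ankle_angle=ankle,
        )
        return generate_trajectory(posture, 1.55, 51)

    def test_angle_range_boundary_is_closed(self, body, cfg):
        inside = self._movement(85.0, 105.0, 35.0, body)
        outside = self._movement(84.9, 105.0, 35.0, body)
        adopted = apply_adoption_filters([inside, outside], body, cfg)
        assert inside in adopted
        assert outside not in adopted
        assert outside.exclusion_reason == "seat-off angles outside range"

    def test_adopted_is_subset_and_normal_is_subset(self, study):
        movements, adopted = study
        assert all(m.adopted for m in adopted)
        assert set(id(m) for m in adopted) <= set(id(m) for m in movements)
        assert all(m.adopted for m in movements if m.normal)

    def test_adoption_monotone_in_foot_length(self, study, cfg):
        """Relaxing the COM filter by lengthening the foot only admits
        movements (the angle filters are unchanged)."""
        import dataclasses

        movements, adopted = study
        base_body = build_body_model(1.74, 73.8, config=cfg)
        long_body = dataclasses.replace(base_body, foot_length=base_body.foot_length + 0.10)
        fresh = [
            generate_trajectory(m.posture, m.duration, m.n_frames) for m in movements
            if m.posture.valid
        ]
        more = apply_adoption_filters(fresh, long_body, cfg)
        assert len(more) >= len(adopted)

    def test_normal_band_classification(self, cfg, body):
        center = self._movement(93.0, 100.0, 30.0, body)
        above = self._movement(101.5, 100.0, 30.0, body)
        edge = self._movement(101.0, 100.0, 30.0, body)
        assert classify_normal(center, cfg)
        assert classify_normal(edge, cfg)
        assert not classify_normal(above, cfg)
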