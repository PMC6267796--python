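"""Sit-to-stand movement generation.

A seat-off posture is defined by the hip position (height fixed at the
seat-off hip height, X swept posterior to the ankle) and the trunk
inclination.  The knee follows from two-link inverse kinematics between hip
and ankle; joint angles follow from the segment vectors.  Each posture is
turned into a movement by driving every joint angle with a half-period cosine
from its seat-off value to zero (the standing reference) over a fixed
duration.

A movement is *adopted* when its seat-off angles fall inside the hip/knee/
ankle ranges and its whole-body centre of mass stays horizontally inside the
foot support base at every frame; adopted movements whose seat-off hip
flexion lies in the normal band are flagged *normal*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .body import BodyModel
from .config import StudyConfig

__all__ = [
    "SeatOffPosture",
    "STSMovement",
    "cosine_weight",
    "solve_leg_configuration",
    "compute_joint_angles",
    "generate_posture_grid",
    "generate_trajectory",
    "generate_movements",
    "whole_body_com_x",
    "com_x_series",
    "apply_adoption_filters",
    "classify_normal",
    "movements_table",
]


@dataclass
class SeatOffPosture:
    """A candidate seat-off configuration on the posture grid."""

    hip_xy: tuple[float, float]
    trunk_angle: float  # degrees clockwise from vertical (forward lean)
    ankle_xy: tuple[float, float]
    knee_xy: tuple[float, float] | None = None
    hip_angle: float = math.nan  # degrees flexion
    knee_angle: float = math.nan  # degrees flexion
    ankle_angle: float = math.nan  # degrees dorsiflexion
    valid: bool = True
    grid_index: tuple[int, int] = (-1, -1)  # (hip-X index, trunk index)


@dataclass
class STSMovement:
    """A seat-off posture plus cosine joint-angle time series."""

    posture: SeatOffPosture
    duration: float
    n_frames: int
    time: np.ndarray  # (F,)
    hip_series: np.ndarray  # degrees, (F,)
    knee_series: np.ndarray
    ankle_series: np.ndarray
    adopted: bool = False
    normal: bool = False
    exclusion_reason: str = ""


def cosine_weight(t: np.ndarray | float, duration: float) -> np.ndarray | float:
    """Normalised half-period cosine: w(0) = 1, w(duration) = 0."""
    return 0.5 * (1.0 + np.cos(np.pi * np.asarray(t, dtype=float) / duration))


def solve_leg_configuration(
    hip_xy: tuple[float, float],
    ankle_xy: tuple[float, float],
    thigh_length: float,
    shank_length: float,
) -> tuple[float, float] | None:
    """Two-link inverse kinematics for the knee position.

    Of the two circle intersections the anterior (larger X) solution is
    returned, because the knee flexes forward.  Returns ``None`` when the
    hip-ankle distance is outside the reachable annulus.
    """
    hx, hy = hip_xy
    ax, ay = ankle_xy
    dx, dy = ax - hx, ay - hy
    d = math.hypot(dx, dy)
    if d > thigh_length + shank_length or d < abs(thigh_length - shank_length) or d == 0.0:
        return None
    # intersection of circles centred at hip (r=thigh) and ankle (r=shank)
    a = (thigh_length**2 - shank_length**2 + d**2) / (2.0 * d)
    h2 = thigh_length**2 - a**2
    h = math.sqrt(max(h2, 0.0))
    mx, my = hx + a * dx / d, hy + a * dy / d
    k1 = (mx + h * dy / d, my - h * dx / d)
    k2 = (mx - h * dy / d, my + h * dx / d)
    return k1 if k1[0] >= k2[0] else k2


def _signed_angle(ref: tuple[float, float], vec: tuple[float, float]) -> float:
    """Angle (degrees) rotating ``ref`` onto ``vec``; sign from the 2-D cross."""
    cross = ref[0] * vec[1] - ref[1] * vec[0]
    dot = ref[0] * vec[0] + ref[1] * vec[1]
    return math.degrees(math.atan2(cross, dot))


def compute_joint_angles(posture: SeatOffPosture) -> tuple[float, float, float]:
    """Hip/knee flexion and ankle dorsiflexion (degrees) of a posture.

    Conventions: all angles are zero in quiet standing (segments stacked
    vertically, foot flat).  Hip flexion is the angle between the downward
    continuation of the trunk and the thigh; knee flexion the angle between
    the thigh continuation and the shank; ankle dorsiflexion the forward
    inclination of the shank relative to the flat-foot vertical.
    """
    if not posture.valid or posture.knee_xy is None:
        raise ValueError("cannot compute joint angles of an invalid posture")
    t = math.radians(posture.trunk_angle)
    hip, knee, ankle = posture.hip_xy, posture.knee_xy, posture.ankle_xy
    v_thigh = (knee[0] - hip[0], knee[1] - hip[1])
    v_shank = (ankle[0] - knee[0], ankle[1] - knee[1])
    trunk_down = (-math.sin(t), -math.cos(t))
    hip_deg = _signed_angle(trunk_down, v_thigh)
    knee_deg = -_signed_angle(v_thigh, v_shank)
    ankle_deg = math.degrees(math.atan2(knee[0] - ankle[0], knee[1] - ankle[1]))
    return hip_deg, knee_deg, ankle_deg


def generate_posture_grid(
    body: BodyModel, config: StudyConfig | None = None
) -> list[SeatOffPosture]:
    """All seat-off postures of the hip-X x trunk-angle grid (41 x 71 = 2911
    by default).  Geometrically unreachable postures are flagged invalid but
    retained so the grid cardinality is exact."""
    cfg = config or StudyConfig()
    n_hip = int(round((cfg.hip_x_max_m - cfg.hip_x_min_m) / cfg.hip_x_step_m)) + 1
    n_trunk = int(round((cfg.trunk_max_deg - cfg.trunk_min_deg) / cfg.trunk_step_deg)) + 1
    hip_xs = cfg.hip_x_max_m - cfg.hip_x_step_m * np.arange(n_hip)
    trunks = cfg.trunk_min_deg + cfg.trunk_step_deg * np.arange(n_trunk)
    ankle = (0.0, body.ankle_height)

    postures: list[SeatOffPosture] = []
    for i, hx in enumerate(hip_xs):
        hip = (float(hx), body.hip_height_seatoff)
        knee = solve_leg_configuration(hip, ankle, body.thigh.length, body.shank.length)
        for j, trunk in enumerate(trunks):
            p = SeatOffPosture(
                hip_xy=hip,
                trunk_angle=float(trunk),
                ankle_xy=ankle,
                knee_xy=knee,
                valid=knee is not None,
                grid_index=(i, j),
            )
            if p.valid:
                p.hip_angle, p.knee_angle, p.ankle_angle = compute_joint_angles(p)
            postures.append(p)
    return postures


def generate_trajectory(
    posture: SeatOffPosture, duration: float = 1.55, n_frames: int = 101
) -> STSMovement:
    """Cosine joint-angle series from the seat-off posture to standing."""
    if n_frames < 3:
        raise ValueError("n_frames must be at least 3")
    t = np.linspace(0.0, duration, n_frames)
    w = cosine_weight(t, duration)
    return STSMovement(
        posture=posture,
        duration=duration,
        n_frames=n_frames,
        time=t,
        hip_series=posture.hip_angle * w,
        knee_series=posture.knee_angle * w,
        ankle_series=posture.ankle_angle * w,
    )


# ---------------------------------------------------------------------------
# forward kinematics of the joint-angle state (shared with inverse dynamics)

def segment_orientation_angles(hip, knee, ankle):
    """Segment orientation angles (radians, anterior-positive from vertical)
    from joint angles: shank (ankle->knee), thigh (knee->hip), HAT (hip->top).
    """
    phi_shank = ankle
    phi_thigh = ankle - knee
    phi_hat = hip + ankle - knee
    return phi_shank, phi_thigh, phi_hat


def joint_and_com_positions(hip, knee, ankle, body: BodyModel):
    """Joint-centre and segment-COM positions for (broadcastable) joint-angle
    arrays in radians.  Returns a dict of (…, 2) arrays."""
    phi_s, phi_t, phi_h = segment_orientation_angles(hip, knee, ankle)

    def unit(phi):
        return np.stack([np.sin(phi), np.cos(phi)], axis=-1)

    ankle_pos = np.zeros(np.broadcast(hip, knee, ankle).shape + (2,))
    ankle_pos[..., 1] = body.ankle_height
    knee_pos = ankle_pos + body.shank.length * unit(phi_s)
    hip_pos = knee_pos + body.thigh.length * unit(phi_t)
    hat_com = hip_pos + body.hat.com_ratio * body.hat.length * unit(phi_h)
    thigh_com = hip_pos + body.thigh.com_ratio * (knee_pos - hip_pos)
    shank_com = knee_pos + body.shank.com_ratio * (ankle_pos - knee_pos)
    foot_com = np.zeros_like(ankle_pos)
    foot_com[..., 0] = body.heel_x + body.foot.com_ratio * body.foot_length
    return {
        "ankle": ankle_pos,
        "knee": knee_pos,
        "hip": hip_pos,
        "hat_com": hat_com,
        "thigh_com": thigh_com,
        "shank_com": shank_com,
        "foot_com": foot_com,
    }


def com_x_series(
    hip_deg: np.ndarray, knee_deg: np.ndarray, ankle_deg: np.ndarray, body: BodyModel
) -> np.ndarray:
    """Whole-body COM X for joint-angle arrays in degrees (bilateral legs
    counted twice)."""
    pos = joint_and_com_positions(
        np.radians(hip_deg), np.radians(knee_deg), np.radians(ankle_deg), body
    )
    m = body
    total = (
        m.hat.mass * pos["hat_com"][..., 0]
        + 2.0 * m.thigh.mass * pos["thigh_com"][..., 0]
        + 2.0 * m.shank.mass * pos["shank_com"][..., 0]
        + 2.0 * m.foot.mass * pos["foot_com"][..., 0]
    )
    return total / m.mass


def whole_body_com_x(movement: STSMovement, body: BodyModel, frame: int) -> float:
    """Whole-body COM X (m) at one frame of a movement."""
    if not 0 <= frame < movement.n_frames:
        raise IndexError(f"frame {frame} outside 0..{movement.n_frames - 1}")
    return float(
        com_x_series(
            movement.hip_series[frame],
            movement.knee_series[frame],
            movement.ankle_series[frame],
            body,
        )
    )


# ---------------------------------------------------------------------------
# filters

def _in_range(x: float, lo_hi: tuple[float, float]) -> bool:
    return lo_hi[0] <= x <= lo_hi[1]


def apply_adoption_filters(
    movements: list[STSMovement], body: BodyModel, config: StudyConfig | None = None
) -> list[STSMovement]:
    """Flag adopted movements; return the adopted subset.

    Adoption requires (a) seat-off hip/knee/ankle angles inside the closed
    configuration ranges and (b) the whole-body COM X inside the support base
    [heel, toe] at every frame.
    """
    cfg = config or StudyConfig()
    adopted: list[STSMovement] = []
    for mv in movements:
        p = mv.posture
        if not p.valid:
            mv.adopted, mv.exclusion_reason = False, "unreachable leg configuration"
            continue
        if not (
            _in_range(p.hip_angle, cfg.hip_range_deg)
            and _in_range(p.knee_angle, cfg.knee_range_deg)
            and _in_range(p.ankle_angle, cfg.ankle_range_deg)
        ):
            mv.adopted, mv.exclusion_reason = False, "seat-off angles outside range"
            continue
        com_x = com_x_series(mv.hip_series, mv.knee_series, mv.ankle_series, body)
        if com_x.min() < body.heel_x or com_x.max() > body.toe_x:
            mv.adopted, mv.exclusion_reason = False, "COM left the support base"
            continue
        mv.adopted, mv.exclusion_reason = True, ""
        mv.normal = classify_normal(mv, cfg)
        adopted.append(mv)
    return adopted


def classify_normal(movement: STSMovement, config: StudyConfig | None = None) -> bool:
    """True iff the seat-off hip flexion lies in the normal band (93 +/- 8 deg)."""
    cfg = config or StudyConfig()
    return _in_range(movement.posture.hip_angle, cfg.normal_hip_range_deg)


def generate_movements(
    body: BodyModel, config: StudyConfig | None = None
) -> tuple[list[STSMovement], list[STSMovement]]:
    """Grid -> trajectories -> filters.  Returns (all movements, adopted)."""
    cfg = config or StudyConfig()
    postures = generate_posture_grid(body, cfg)
    movements = [
        generate_trajectory(p, cfg.duration_s, cfg.n_frames) if p.valid
        else STSMovement(
            posture=p, duration=cfg.duration_s, n_frames=cfg.n_frames,
            time=np.linspace(0.0, cfg.duration_s, cfg.n_frames),
            hip_series=np.full(cfg.n_frames, np.nan),
            knee_series=np.full(cfg.n_frames, np.nan),
            ankle_series=np.full(cfg.n_frames, np.nan),
        )
        for p in postures
    ]
    adopted = apply_adoption_filters(movements, body, cfg)
    return movements, adopted


def movements_table(movements: list[STSMovement]) -> pd.DataFrame:
    """One row per movement: grid indices, seat-off angles, flags."""
    rows = []
    for mv in movements:
        p = mv.posture
        rows.append(
            {
                "hip_x_index": p.grid_index[0],
                "trunk_index": p.grid_index[1],
                "hip_x_m": p.hip_xy[0],
                "trunk_deg": p.trunk_angle,
                "hip_deg": p.hip_angle,
                "knee_deg": p.knee_angle,
                "ankle_deg": p.ankle_angle,
                "valid": p.valid,
                "adopted": mv.adopted,
                "normal": mv.normal,
                "exclusion_reason": mv.exclusion_reason,
            }
        )
    return pd.DataFrame(rows)
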