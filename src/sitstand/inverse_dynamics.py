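"""2-D link-segment inverse dynamics on the prescribed cosine kinematics.

The chain HAT - hip - thigh - knee - shank - ankle is resolved top-down with
Newton-Euler equations per leg.  The model is bilaterally symmetric: each leg
carries half of the HAT segment (mass and inertia), and joint moments and the
hip intersegmental force are reported per leg, normalised by the whole-body
mass (Nm/kg and N/kg).

Sign conventions: hip extension, knee extension and ankle plantarflexion
moments are positive; z-torques follow the right-handed X-anterior/Y-up
frame (counter-clockwise positive when viewed from the subject's right).
Velocities and accelerations come from analytic differentiation of the
closed-form cosine angle trajectories, not finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .body import BodyModel
from .movement import STSMovement, segment_orientation_angles

__all__ = [
    "KinematicsSeries",
    "JointKinetics",
    "differentiate_kinematics",
    "compute_joint_moments",
    "static_moment_component",
    "static_joint_moments",
    "hip_joint_force",
    "batch_joint_kinetics",
]


def _unit(phi: np.ndarray) -> np.ndarray:
    return np.stack([np.sin(phi), np.cos(phi)], axis=-1)


def _unit_d(phi: np.ndarray) -> np.ndarray:
    # derivative of _unit w.r.t. phi
    return np.stack([np.cos(phi), -np.sin(phi)], axis=-1)


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def _cosine_weight_derivatives(t: np.ndarray, duration: float):
    x = np.pi * t / duration
    w = 0.5 * (1.0 + np.cos(x))
    wd = -0.5 * np.pi / duration * np.sin(x)
    wdd = -0.5 * (np.pi / duration) ** 2 * np.cos(x)
    return w, wd, wdd


@dataclass
class KinematicsSeries:
    """Per-frame segment kinematics of one movement (leading axis = frame)."""

    time: np.ndarray
    #: joint angles (hip, knee, ankle) in radians, shape (F, 3)
    joint_angles: np.ndarray
    joint_velocities: np.ndarray
    joint_accelerations: np.ndarray
    #: segment orientation angles (shank, thigh, hat), anterior-positive from
    #: vertical, radians, shape (F, 3); velocities/accelerations likewise
    segment_angles: np.ndarray
    segment_velocities: np.ndarray
    segment_accelerations: np.ndarray
    #: point kinematics, each (F, 2): joints and segment COMs
    positions: dict
    velocities: dict
    accelerations: dict


def _chain_kinematics(h0, k0, a0, time: np.ndarray, duration: float, body: BodyModel):
    """Core closed-form kinematics for seat-off angle arrays (radians).

    ``h0, k0, a0`` broadcast against each other with shape S; returns arrays
    of shape S + (F,) / S + (F, 2).
    """
    w, wd, wdd = _cosine_weight_derivatives(time, duration)
    h0, k0, a0 = np.broadcast_arrays(
        np.atleast_1d(h0), np.atleast_1d(k0), np.atleast_1d(a0)
    )
    H, K, A = h0[..., None] * w, k0[..., None] * w, a0[..., None] * w
    Hd, Kd, Ad = h0[..., None] * wd, k0[..., None] * wd, a0[..., None] * wd
    Hdd, Kdd, Add = h0[..., None] * wdd, k0[..., None] * wdd, a0[..., None] * wdd

    phi = {}
    phi["shank"], phi["thigh"], phi["hat"] = segment_orientation_angles(H, K, A)
    phid = {"shank": Ad, "thigh": Ad - Kd, "hat": Hd + Ad - Kd}
    phidd = {"shank": Add, "thigh": Add - Kdd, "hat": Hdd + Add - Kdd}

    def point_chain(base_p, base_v, base_a, L, seg):
        u, c = _unit(phi[seg]), _unit_d(phi[seg])
        p = base_p + L * u
        v = base_v + L * phid[seg][..., None] * c
        a = base_a + L * (
            phidd[seg][..., None] * c - (phid[seg] ** 2)[..., None] * u
        )
        return p, v, a

    shape = H.shape
    zero = np.zeros(shape + (2,))
    ankle_p = zero.copy()
    ankle_p[..., 1] = body.ankle_height
    knee_p, knee_v, knee_a = point_chain(ankle_p, zero, zero, body.shank.length, "shank")
    hip_p, hip_v, hip_a = point_chain(knee_p, knee_v, knee_a, body.thigh.length, "thigh")
    hat_p, hat_v, hat_a = point_chain(
        hip_p, hip_v, hip_a, body.hat.com_ratio * body.hat.length, "hat"
    )

    rt = body.thigh.com_ratio
    rs = body.shank.com_ratio
    thigh_com = (hip_p + rt * (knee_p - hip_p), hip_v + rt * (knee_v - hip_v),
                 hip_a + rt * (knee_a - hip_a))
    shank_com = (knee_p + rs * (ankle_p - knee_p), (1.0 - rs) * knee_v,
                 (1.0 - rs) * knee_a)

    return {
        "joint_angles": (H, K, A),
        "joint_velocities": (Hd, Kd, Ad),
        "joint_accelerations": (Hdd, Kdd, Add),
        "phi": phi,
        "phid": phid,
        "phidd": phidd,
        "points": {
            "ankle": (ankle_p, zero, zero),
            "knee": (knee_p, knee_v, knee_a),
            "hip": (hip_p, hip_v, hip_a),
            "hat_com": (hat_p, hat_v, hat_a),
            "thigh_com": thigh_com,
            "shank_com": shank_com,
        },
    }


def differentiate_kinematics(movement: STSMovement, body: BodyModel) -> KinematicsSeries:
    """Closed-form position/velocity/acceleration series of one movement."""
    if movement.n_frames < 3:
        raise ValueError("movement needs at least 3 frames")
    p = movement.posture
    kin = _chain_kinematics(
        np.radians(p.hip_angle), np.radians(p.knee_angle), np.radians(p.ankle_angle),
        movement.time, movement.duration, body,
    )

    def stack3(tup):
        return np.stack([np.squeeze(x, axis=0) for x in tup], axis=-1)

    seg_order = ("shank", "thigh", "hat")
    return KinematicsSeries(
        time=movement.time,
        joint_angles=stack3(kin["joint_angles"]),
        joint_velocities=stack3(kin["joint_velocities"]),
        joint_accelerations=stack3(kin["joint_accelerations"]),
        segment_angles=stack3([kin["phi"][s] for s in seg_order]),
        segment_velocities=stack3([kin["phid"][s] for s in seg_order]),
        segment_accelerations=stack3([kin["phidd"][s] for s in seg_order]),
        positions={k: v[0][0] for k, v in kin["points"].items()},
        velocities={k: v[1][0] for k, v in kin["points"].items()},
        accelerations={k: v[2][0] for k, v in kin["points"].items()},
    )


@dataclass
class JointKinetics:
    """Per-frame joint moments (Nm/kg, per leg) and hip intersegmental force
    (N/kg, force on the femoral head from the pelvis side)."""

    time: np.ndarray
    hip_moment: np.ndarray  # extension positive
    knee_moment: np.ndarray  # extension positive
    ankle_moment: np.ndarray  # plantarflexion positive
    hip_joint_force: np.ndarray  # (F, 2)

    @property
    def moments(self) -> np.ndarray:
        return np.stack([self.hip_moment, self.knee_moment, self.ankle_moment], axis=-1)


def _newton_euler(kin: dict, body: BodyModel, static: bool):
    """Top-down per-leg Newton-Euler pass on `_chain_kinematics` output.

    Returns (moments S+(F,3) in Nm/kg, hip force S+(F,2) in N/kg).
    """
    g_vec = np.array([0.0, -body.gravity])
    pts = kin["points"]

    def acc(name):
        a = pts[name][2]
        return np.zeros_like(a) if static else a

    def ang_acc(seg):
        # CCW angular acceleration = -(anterior-from-vertical second derivative)
        a = -kin["phidd"][seg]
        return np.zeros_like(a) if static else a

    m_hat = body.hat.mass / 2.0
    i_hat = body.hat.moment_of_inertia / 2.0
    m_t, i_t = body.thigh.mass, body.thigh.moment_of_inertia
    m_s, i_s = body.shank.mass, body.shank.moment_of_inertia

    r_hip, r_knee, r_ankle = pts["hip"][0], pts["knee"][0], pts["ankle"][0]
    r_hc, r_tc, r_sc = pts["hat_com"][0], pts["thigh_com"][0], pts["shank_com"][0]

    f1 = m_hat * (acc("hat_com") - g_vec)
    m1 = i_hat * ang_acc("hat") - _cross(r_hip - r_hc, f1)

    f2 = m_t * (acc("thigh_com") - g_vec) + f1
    m2 = (
        i_t * ang_acc("thigh") + m1
        - _cross(r_knee - r_tc, f2) - _cross(r_hip - r_tc, -f1)
    )

    f3 = m_s * (acc("shank_com") - g_vec) + f2
    m3 = (
        i_s * ang_acc("shank") + m2
        - _cross(r_ankle - r_sc, f3) - _cross(r_knee - r_sc, -f2)
    )

    mass = body.mass
    moments = np.stack([m1, -m2, m3], axis=-1) / mass
    hip_force = -f1 / mass
    return moments, hip_force


def batch_joint_kinetics(
    hip0_deg, knee0_deg, ankle0_deg,
    body: BodyModel,
    duration: float = 1.55,
    n_frames: int = 101,
    static: bool = False,
):
    """Vectorised kinetics for arrays of seat-off angles (degrees).

    Returns (moments, hip_force) with shapes S + (F, 3) and S + (F, 2),
    where S broadcasts from the inputs.  ``static=True`` zeroes all
    velocities and accelerations (gravity-only moments).
    """
    time = np.linspace(0.0, duration, n_frames)
    kin = _chain_kinematics(
        np.radians(np.asarray(hip0_deg, dtype=float)),
        np.radians(np.asarray(knee0_deg, dtype=float)),
        np.radians(np.asarray(ankle0_deg, dtype=float)),
        time, duration, body,
    )
    return _newton_euler(kin, body, static)


def compute_joint_moments(movement: STSMovement, body: BodyModel) -> JointKinetics:
    """Hip/knee/ankle joint moments and hip intersegmental force of one
    movement (per leg, normalised by body mass)."""
    p = movement.posture
    kin = _chain_kinematics(
        np.radians(p.hip_angle), np.radians(p.knee_angle), np.radians(p.ankle_angle),
        movement.time, movement.duration, body,
    )
    moments, hip_force = _newton_euler(kin, body, static=False)
    return JointKinetics(
        time=movement.time,
        hip_moment=moments[0, :, 0],
        knee_moment=moments[0, :, 1],
        ankle_moment=moments[0, :, 2],
        hip_joint_force=hip_force[0],
    )


def static_joint_moments(movement: STSMovement, body: BodyModel) -> JointKinetics:
    """Gravity-only (static-component) moments along a movement."""
    p = movement.posture
    kin = _chain_kinematics(
        np.radians(p.hip_angle), np.radians(p.knee_angle), np.radians(p.ankle_angle),
        movement.time, movement.duration, body,
    )
    moments, hip_force = _newton_euler(kin, body, static=True)
    return JointKinetics(
        time=movement.time,
        hip_moment=moments[0, :, 0],
        knee_moment=moments[0, :, 1],
        ankle_moment=moments[0, :, 2],
        hip_joint_force=hip_force[0],
    )


def static_moment_component(
    hip_deg: float, knee_deg: float, ankle_deg: float, body: BodyModel
) -> tuple[float, float, float]:
    """Gravity-only hip/knee/ankle moments (Nm/kg) of a single posture."""
    moments, _ = batch_joint_kinetics(
        hip_deg, knee_deg, ankle_deg, body, n_frames=3, static=True
    )
    return tuple(float(x) for x in moments[0, 0])


def hip_joint_force(movement: STSMovement, body: BodyModel) -> np.ndarray:
    """Hip intersegmental force series, (F, 2) in N/kg per leg."""
    return compute_joint_moments(movement, body).hip_joint_force
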