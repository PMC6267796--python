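"""Hip joint contact force from intersegmental force and hip-muscle pull.

The bone-on-bone load at the hip is the norm of the intersegmental (skeletal)
force minus the vector sum of the four hip-spanning muscle forces along their
lines of action:

    HJCF = || v_HJF - sum_n F_n e_n ||,   n in {iliopsoas, gluteus maximus,
                                               rectus femoris, hamstrings}

where v_HJF is the force on the femoral head from the pelvis side and e_n is
the unit vector of muscle pull on the femur toward the pelvic attachment, so
extensor loading presses the joint surfaces together and increases the norm.
Attachment coordinates live in pelvis- and femur-fixed frames sharing the hip
centre as origin (``_fixtures/attachments.csv``, swappable).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .body import BodyModel

__all__ = [
    "HIP_MUSCLES",
    "MuscleLineOfAction",
    "ContactForceResult",
    "load_attachments",
    "muscle_line_unit_vector",
    "unit_vectors_series",
    "hip_contact_force",
    "gluteus_medius_adjustment",
]

#: the four muscles crossing the hip, in fixture order
HIP_MUSCLES = ("iliopsoas", "gluteus_maximus", "rectus_femoris", "hamstrings")


@dataclass(frozen=True)
class MuscleLineOfAction:
    """Sagittal attachment geometry of one hip-spanning muscle.

    ``pelvis_xy`` is the pelvic attachment (or effective via point) in the
    pelvis frame; ``femur_xy`` the femoral attachment or distal path point in
    the femur frame.  Both frames have the hip centre as origin, +x anterior;
    pelvis +y cranial along the trunk, femur +y proximal along the thigh.
    """

    muscle: str
    pelvis_xy: np.ndarray
    femur_xy: np.ndarray


def load_attachments(path: str | Path | None = None) -> dict[str, MuscleLineOfAction]:
    if path is None:
        ref = resources.files("sitstand") / "_fixtures" / "attachments.csv"
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, comment="#")
    else:
        table = pd.read_csv(path, comment="#")
    lines = {}
    for _, row in table.iterrows():
        lines[str(row["muscle"])] = MuscleLineOfAction(
            muscle=str(row["muscle"]),
            pelvis_xy=np.array([row["pelvis_x_m"], row["pelvis_y_m"]], dtype=float),
            femur_xy=np.array([row["femur_x_m"], row["femur_y_m"]], dtype=float),
        )
    missing = set(HIP_MUSCLES) - set(lines)
    if missing:
        raise ValueError(f"attachment fixture lacks muscles: {sorted(missing)}")
    return lines


def _frame_to_global(local_xy: np.ndarray, axis_dir: np.ndarray) -> np.ndarray:
    """Map local (x, y) to global for a frame whose local +y axis points along
    ``axis_dir`` (unit, (..., 2)); proper rotation, local +x maps to the
    clockwise perpendicular (anterior when the axis is vertical)."""
    x, y = local_xy
    perp = np.stack([axis_dir[..., 1], -axis_dir[..., 0]], axis=-1)
    return x * perp + y * axis_dir


def muscle_line_unit_vector(
    muscle: str,
    attachments: dict[str, MuscleLineOfAction],
    hat_angle_rad: np.ndarray | float,
    thigh_angle_rad: np.ndarray | float,
) -> np.ndarray:
    """Unit direction of muscle pull on the femur toward the pelvis, (..., 2).

    ``hat_angle_rad`` is the trunk (pelvis-frame) orientation and
    ``thigh_angle_rad`` the knee-to-hip thigh orientation, both
    anterior-positive from vertical.
    """
    if muscle not in HIP_MUSCLES:
        raise ValueError(f"{muscle!r} does not span the hip")
    line = attachments[muscle]
    hat = np.asarray(hat_angle_rad, dtype=float)
    thigh = np.asarray(thigh_angle_rad, dtype=float)
    pelvis_dir = np.stack([np.sin(hat), np.cos(hat)], axis=-1)
    femur_dir = np.stack([np.sin(thigh), np.cos(thigh)], axis=-1)
    p = _frame_to_global(line.pelvis_xy, pelvis_dir)
    f = _frame_to_global(line.femur_xy, femur_dir)
    d = p - f
    norm = np.linalg.norm(d, axis=-1, keepdims=True)
    return d / norm


def unit_vectors_series(
    attachments: dict[str, MuscleLineOfAction],
    hat_angle_rad: np.ndarray,
    thigh_angle_rad: np.ndarray,
) -> np.ndarray:
    """(F, 4, 2) unit vectors for the four hip muscles along a movement."""
    return np.stack(
        [
            muscle_line_unit_vector(m, attachments, hat_angle_rad, thigh_angle_rad)
            for m in HIP_MUSCLES
        ],
        axis=-2,
    )


@dataclass
class ContactForceResult:
    hjcf_series: np.ndarray  # (F,) N/kg; NaN on infeasible frames
    peak_hjcf: float  # N/kg, NaN-ignoring max
    muscle_forces: np.ndarray  # (F, 4) N/kg, fixture order HIP_MUSCLES


def hip_contact_force(
    v_hjf: np.ndarray,
    muscle_forces: np.ndarray,
    unit_vectors: np.ndarray,
) -> ContactForceResult:
    """Per-frame hip joint contact force magnitude.

    Parameters are per-frame series: ``v_hjf`` (F, 2) intersegmental force in
    N/kg, ``muscle_forces`` (F, 4) hip-muscle contractile forces in N/kg and
    ``unit_vectors`` (F, 4, 2) lines of action (femur toward pelvis).
    """
    v_hjf = np.asarray(v_hjf, dtype=float)
    muscle_forces = np.asarray(muscle_forces, dtype=float)
    unit_vectors = np.asarray(unit_vectors, dtype=float)
    if not (len(v_hjf) == len(muscle_forces) == len(unit_vectors)):
        raise ValueError("mismatched series lengths")
    if muscle_forces.shape[-1] != len(HIP_MUSCLES):
        raise ValueError(f"expected {len(HIP_MUSCLES)} hip-spanning muscle forces")
    pull = np.sum(muscle_forces[..., None] * unit_vectors, axis=-2)
    hjcf = np.linalg.norm(v_hjf - pull, axis=-1)
    peak = float(np.nanmax(hjcf)) if np.any(np.isfinite(hjcf)) else float("nan")
    return ContactForceResult(
        hjcf_series=hjcf, peak_hjcf=peak, muscle_forces=muscle_forces
    )


def gluteus_medius_adjustment(
    pcsa: float, activation_fraction: float, sigma: float, body_mass: float
) -> float:
    """Rough frontal-plane correction (N/kg) for the unmodelled gluteus
    medius: PCSA x activation x specific tension / body mass."""
    if min(pcsa, sigma, body_mass) <= 0 or activation_fraction < 0:
        raise ValueError("inputs must be positive (activation non-negative)")
    return pcsa * activation_fraction * sigma / body_mass
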