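"""Hill-type contractile-element model for the eight lower-limb muscles.

Each muscle carries a physiological cross-sectional area (PCSA), constant
sagittal moment arms with an anatomical action sign per spanned joint, and a
quadratic fiber-length-ratio model in the joint angles.  The maximum
contractile force per frame is

    F_MAX = k * f_ce(Lr) * f_v(Ldot) * PCSA * sigma,

with f_ce a Gaussian force-length curve (optimum at Lr = 1, support
(0.5, 1.5)), f_v a normalised Hill force-velocity curve (zero at maximum
shortening velocity, 1 isometric, eccentric plateau 1.5), sigma the specific
tension (60 N/cm^2) and k the force-length-ability scaling used by the
sensitivity analysis (1 = nominal).

Only the contractile element is modelled: series/parallel elastic elements
and pennation are intentionally absent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "JOINTS",
    "MuscleParams",
    "MuscleState",
    "load_muscles",
    "signed_moment_arms",
    "fiber_length_ratio",
    "fiber_velocity",
    "force_length",
    "force_velocity",
    "max_muscle_force",
    "muscle_states",
]

JOINTS = ("hip", "knee", "ankle")

#: Gaussian width of the force-length curve (dimensionless fiber-length units)
FL_WIDTH = 0.45
#: force-length support: f_ce = 0 outside this open interval
FL_SUPPORT = (0.5, 1.5)
#: Hill shape parameter a/F0 of the concentric branch
FV_SHAPE = 0.25
#: eccentric plateau of the force-velocity curve
FV_ECC_PLATEAU = 1.5
# eccentric shape constant chosen for slope continuity at zero velocity:
# concentric slope at 0 is 1 + 1/FV_SHAPE = 5, so (plateau-1)/a_e = 5
FV_ECC_SHAPE = (FV_ECC_PLATEAU - 1.0) / (1.0 + 1.0 / FV_SHAPE)


@dataclass(frozen=True)
class MuscleParams:
    """Parameters of one muscle (arms in m, PCSA in cm^2, sigma in N/cm^2)."""

    name: str
    pcsa_mean: float
    pcsa_sd: float
    moment_arm: np.ndarray  # (3,) magnitudes per joint, 0 = not spanned
    action_sign: np.ndarray  # (3,) +1 extensor/plantarflexor, -1 flexor, 0
    sigma: float
    lref: float  # normalising (optimal) fiber length, m
    vmax: float  # maximum shortening velocity, lref/s
    ref_angles_deg: np.ndarray  # (3,) reference posture where Lr = 1
    quad_c1: np.ndarray  # (3,) linear coefficients, 1/rad
    quad_c2: np.ndarray  # (3,) quadratic coefficients, 1/rad^2

    @property
    def pcsa(self) -> float:
        return self.pcsa_mean

    @property
    def signed_arms(self) -> np.ndarray:
        """Moment arms in the extension/plantarflexion-positive convention."""
        return self.action_sign * self.moment_arm

    def perturbed(self, pcsa=None, moment_arm=None) -> "MuscleParams":
        changes = {}
        if pcsa is not None:
            changes["pcsa_mean"] = float(pcsa)
        if moment_arm is not None:
            changes["moment_arm"] = np.asarray(moment_arm, dtype=float)
        return replace(self, **changes)


@dataclass
class MuscleState:
    """Per-frame contractile state of one muscle."""

    fiber_length_ratio: np.ndarray  # Lr, dimensionless
    fiber_velocity: np.ndarray  # Ldot, normalised by vmax (shortening < 0)
    f_ce: np.ndarray
    f_v: np.ndarray
    f_n_max: np.ndarray  # f_ce * f_v
    f_max: np.ndarray  # N


def load_muscles(
    path: str | Path | None = None, sigma: float = 60.0
) -> list[MuscleParams]:
    """Load the eight-muscle parameter table (default: shipped fixture)."""
    if path is None:
        ref = resources.files("sitstand") / "_fixtures" / "muscles.csv"
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, comment="#")
    else:
        table = pd.read_csv(path, comment="#")

    muscles = []
    for _, row in table.iterrows():
        arms = np.array([row[f"arm_{j}_m"] for j in JOINTS], dtype=float)
        signs = np.array([row[f"sign_{j}"] for j in JOINTS], dtype=float)
        if np.any((arms == 0) != (signs == 0)):
            raise ValueError(f"{row['name']}: zero arm must pair with zero sign")
        lref = float(row["lref_m"])
        c1 = signs * arms / lref
        c2 = -0.06 * c1
        muscles.append(
            MuscleParams(
                name=str(row["name"]),
                pcsa_mean=float(row["pcsa_mean_cm2"]),
                pcsa_sd=float(row["pcsa_sd_cm2"]),
                moment_arm=arms,
                action_sign=signs,
                sigma=sigma,
                lref=lref,
                vmax=float(row["vmax_lref_per_s"]),
                ref_angles_deg=np.array(
                    [row[f"ref_{j}_deg"] for j in JOINTS], dtype=float
                ),
                quad_c1=c1,
                quad_c2=c2,
            )
        )
    return muscles


def signed_moment_arms(muscles: list[MuscleParams]) -> np.ndarray:
    """Signed moment-arm matrix, (3 joints, n muscles), extension-positive."""
    return np.stack([m.signed_arms for m in muscles], axis=1)


def fiber_length_ratio(muscle: MuscleParams, joint_angles_deg: np.ndarray) -> np.ndarray:
    """Quadratic fiber-length ratio Lr at joint angles (..., 3) in degrees.

    Biarticular muscles sum the contributions of both spanned joints around
    the reference ratio 1.0; the linear terms are tied to the signed moment
    arms so extensors lengthen under flexion (dLr/dtheta = r_signed / lref).
    """
    d = np.radians(np.asarray(joint_angles_deg, dtype=float) - muscle.ref_angles_deg)
    return 1.0 + np.sum(muscle.quad_c1 * d + muscle.quad_c2 * d * d, axis=-1)


def fiber_velocity(
    muscle: MuscleParams,
    joint_angles_deg: np.ndarray,
    joint_velocities_deg_s: np.ndarray,
) -> np.ndarray:
    """Normalised fiber velocity (shortening negative) at (..., 3) angles and
    angular velocities, via the analytic chain rule through the quadratic."""
    d = np.radians(np.asarray(joint_angles_deg, dtype=float) - muscle.ref_angles_deg)
    dtheta = np.radians(np.asarray(joint_velocities_deg_s, dtype=float))
    dlr_dt = np.sum((muscle.quad_c1 + 2.0 * muscle.quad_c2 * d) * dtheta, axis=-1)
    return dlr_dt / muscle.vmax


def force_length(lr: np.ndarray) -> np.ndarray:
    """Bell-shaped normalised force-length curve; zero outside (0.5, 1.5)."""
    lr = np.asarray(lr, dtype=float)
    f = np.exp(-(((lr - 1.0) / FL_WIDTH) ** 2))
    return np.where((lr > FL_SUPPORT[0]) & (lr < FL_SUPPORT[1]), f, 0.0)


def force_velocity(v: np.ndarray) -> np.ndarray:
    """Normalised Hill force-velocity curve of the contractile element.

    Concentric branch (v in [-1, 0]): (1 + v) / (1 - v/FV_SHAPE); zero below
    -1.  Eccentric branch rises C1-continuously to the 1.5 plateau.
    """
    v = np.asarray(v, dtype=float)
    conc = np.clip((1.0 + v) / (1.0 - v / FV_SHAPE), 0.0, None)
    ecc = (FV_ECC_PLATEAU * v + FV_ECC_SHAPE) / (v + FV_ECC_SHAPE)
    return np.where(v < 0.0, conc, ecc)


def max_muscle_force(
    muscle: MuscleParams, f_n_max: np.ndarray, k: float = 1.0
) -> np.ndarray:
    """F_MAX = k * F_N_MAX * PCSA * sigma, clipped at >= 0 (cm^2 * N/cm^2 = N)."""
    if k <= 0:
        raise ValueError("force-length scaling k must be positive")
    return np.clip(k * np.asarray(f_n_max) * muscle.pcsa * muscle.sigma, 0.0, None)


def muscle_states(
    muscles: list[MuscleParams],
    joint_angles_deg: np.ndarray,
    joint_velocities_deg_s: np.ndarray,
    k: float | np.ndarray = 1.0,
) -> list[MuscleState]:
    """Contractile states for all muscles along an angle series (F, 3)."""
    ks = np.broadcast_to(np.asarray(k, dtype=float), (len(muscles),))
    states = []
    for m, km in zip(muscles, ks):
        lr = fiber_length_ratio(m, joint_angles_deg)
        v = fiber_velocity(m, joint_angles_deg, joint_velocities_deg_s)
        fce = force_length(lr)
        fv = force_velocity(v)
        fn = fce * fv
        states.append(
            MuscleState(
                fiber_length_ratio=lr,
                fiber_velocity=v,
                f_ce=fce,
                f_v=fv,
                f_n_max=fn,
                f_max=max_muscle_force(m, fn, float(km)),
            )
        )
    return states
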