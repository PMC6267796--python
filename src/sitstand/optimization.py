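"""Static optimization of the per-frame muscle-redundancy problem.

Each frame poses a convex quadratic program in the eight contractile forces

    minimize   J1 = sum_m (F_m / F_MAX_m)^2     (activation squared)
        or     J2 = sum_m (F_m / PCSA_m)^2      (stress squared)
    subject to R F = M        (hip, knee, ankle moment equality)
               0 <= F <= F_MAX,

with R the signed moment-arm matrix (extension/plantarflexion positive) and
M the inverse-dynamics joint moments de-normalised to Nm.  The solver is a
primal active-set method exploiting the diagonal Hessian (exact KKT solves on
the free set), with an SLSQP fallback and a phase-1 linear program to certify
infeasibility — a frame is infeasible when no force vector inside the bounds
reproduces the moments, which is how "non-optimal" movements are counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as sp_optimize

from .body import BodyModel
from .inverse_dynamics import JointKinetics
from .movement import STSMovement
from .muscle import MuscleParams, MuscleState, muscle_states, signed_moment_arms

__all__ = [
    "OBJECTIVES",
    "OptimizationProblem",
    "MuscleForceSolution",
    "MovementSolution",
    "SolverError",
    "build_problem",
    "solve_frame",
    "solve_movement",
]

OBJECTIVES = ("activation", "stress")

_RESIDUAL_TOL = 1e-6  # Nm
_BOUND_TOL = 1e-9


class SolverError(RuntimeError):
    """The QP solver failed on a problem that is not provably infeasible."""


@dataclass
class OptimizationProblem:
    objective_id: str  # "activation" (J1) or "stress" (J2)
    target_moments: np.ndarray  # (3,) Nm per leg
    moment_arm_matrix: np.ndarray  # (3, n) signed, m
    f_max: np.ndarray  # (n,) N
    pcsa: np.ndarray  # (n,) cm^2

    def __post_init__(self) -> None:
        if self.objective_id not in OBJECTIVES:
            raise ValueError(f"unknown objective {self.objective_id!r}")
        self.target_moments = np.asarray(self.target_moments, dtype=float)
        self.moment_arm_matrix = np.asarray(self.moment_arm_matrix, dtype=float)
        self.f_max = np.asarray(self.f_max, dtype=float)
        self.pcsa = np.asarray(self.pcsa, dtype=float)

    @property
    def weights(self) -> np.ndarray:
        """Diagonal objective weights w with J = sum w_m F_m^2."""
        if self.objective_id == "activation":
            with np.errstate(divide="ignore"):
                return np.where(self.f_max > 0.0, 1.0 / self.f_max**2, np.inf)
        return 1.0 / self.pcsa**2

    def objective_value(self, forces: np.ndarray) -> float:
        w = self.weights
        forces = np.asarray(forces, dtype=float)
        active = forces > 0.0
        return float(np.sum(w[active] * forces[active] ** 2))


@dataclass
class MuscleForceSolution:
    forces: np.ndarray  # (n,) N
    objective_value: float
    feasible: bool
    residuals: np.ndarray  # (3,) Nm


@dataclass
class MovementSolution:
    """Per-frame solutions for one movement under one objective."""

    solutions: list[MuscleForceSolution]
    objective_id: str
    infeasible_frame_count: int = 0

    @property
    def optimal(self) -> bool:
        """The paper's bookkeeping: a movement-run is optimal iff every frame
        admitted a solution within the force bounds."""
        return self.infeasible_frame_count == 0

    @property
    def force_matrix(self) -> np.ndarray:
        """(F, n) forces, NaN on infeasible frames."""
        return np.stack([s.forces for s in self.solutions])


def build_problem(
    moments_nm_kg: np.ndarray,
    body_mass: float,
    muscles: list[MuscleParams],
    f_max: np.ndarray,
    objective_id: str = "activation",
    moment_arm_matrix: np.ndarray | None = None,
) -> OptimizationProblem:
    """Assemble one frame's QP from normalised moments and muscle state."""
    R = signed_moment_arms(muscles) if moment_arm_matrix is None else moment_arm_matrix
    return OptimizationProblem(
        objective_id=objective_id,
        target_moments=np.asarray(moments_nm_kg, dtype=float) * body_mass,
        moment_arm_matrix=R,
        f_max=np.asarray(f_max, dtype=float),
        pcsa=np.array([m.pcsa for m in muscles], dtype=float),
    )


# ---------------------------------------------------------------------------
# active-set core

def _solve_free(A, w, b, free, upper, status):
    """KKT solve on the free set given bound-fixed variables.

    Returns (x, nu, eq_residual_norm).
    """
    n = A.shape[1]
    x = np.zeros(n)
    at_up = status == 2
    x[at_up] = upper[at_up]
    b_eff = b - A[:, at_up] @ upper[at_up]
    if not np.any(free):
        return x, np.zeros(A.shape[0]), float(np.linalg.norm(A @ x - b))
    Af = A[:, free]
    d = 0.5 / w[free]  # inverse Hessian diagonal / 2
    G = (Af * d) @ Af.T
    try:
        nu = np.linalg.solve(G, b_eff)
    except np.linalg.LinAlgError:
        nu = np.linalg.lstsq(G, b_eff, rcond=None)[0]
    x[free] = d * (Af.T @ nu)
    return x, nu, float(np.linalg.norm(A @ x - b))


def _active_set_qp(A, b, upper, w, max_iter=200):
    """Primal active-set method for min sum(w x^2) s.t. Ax=b, 0<=x<=upper.

    Returns (x, converged_flag).  Variables with upper == 0 are pinned.
    status: 0 free, 1 at lower bound, 2 at upper bound.
    """
    n = A.shape[1]
    status = np.zeros(n, dtype=np.int8)
    status[upper <= _BOUND_TOL] = 1
    seen: set[bytes] = set()

    for _ in range(max_iter):
        key = status.tobytes()
        if key in seen:
            return None, False  # cycling; defer to fallback
        seen.add(key)
        free = status == 0
        x, nu, res = _solve_free(A, w, b, free, upper, status)

        if res > _RESIDUAL_TOL:
            # equality unreachable on this active set: release the bounded
            # variable best aligned with the residual, if any remains
            r = b - A @ x
            candidates = np.flatnonzero((status != 0) & (upper > _BOUND_TOL))
            if candidates.size == 0:
                return None, False
            align = np.abs(A[:, candidates].T @ r)
            status[candidates[np.argmax(align)]] = 0
            continue

        lo_viol = free & (x < -_BOUND_TOL)
        up_viol = free & (x > upper + _BOUND_TOL)
        if np.any(lo_viol) or np.any(up_viol):
            # pin the worst violator at its nearest bound
            viol = np.where(lo_viol, -x, np.where(up_viol, x - upper, 0.0))
            i = int(np.argmax(viol))
            status[i] = 1 if lo_viol[i] else 2
            continue

        # primal feasible: check dual feasibility of the bounds
        g = 2.0 * w * np.where(np.isfinite(w), x, 0.0) - A.T @ nu
        g = np.where(np.isfinite(g), g, 0.0)
        release = None
        worst = _BOUND_TOL
        for i in range(n):
            if status[i] == 1 and upper[i] > _BOUND_TOL and -g[i] > worst:
                worst, release = -g[i], i
            elif status[i] == 2 and g[i] > worst:
                worst, release = g[i], i
        if release is None:
            return np.clip(x, 0.0, upper), True
        status[release] = 0
    return None, False


def _verify_and_polish(A, b, upper, w, x_approx):
    """Exact KKT re-solve on the active pattern of an approximate solution.

    Returns the polished optimum when the pattern is primal and dual
    feasible, else None.
    """
    n = A.shape[1]
    status = np.zeros(n, dtype=np.int8)
    status[x_approx <= 1e-6] = 1
    status[x_approx >= upper - 1e-6] = 2
    status[upper <= _BOUND_TOL] = 1
    free = status == 0
    x, nu, res = _solve_free(A, w, b, free, upper, status)
    if res > _RESIDUAL_TOL:
        return None
    if np.any(x < -_BOUND_TOL) or np.any(x > upper + _BOUND_TOL):
        return None
    g = 2.0 * w * x - A.T @ nu
    for i in range(n):
        if status[i] == 1 and upper[i] > _BOUND_TOL and -g[i] > 1e-7:
            return None
        if status[i] == 2 and g[i] > 1e-7:
            return None
    return np.clip(x, 0.0, upper)


def _slsqp_fallback(problem: OptimizationProblem, x0: np.ndarray | None):
    A, b = problem.moment_arm_matrix, problem.target_moments
    upper = problem.f_max
    w = problem.weights
    w_eff = np.where(np.isfinite(w), w, 0.0)
    if x0 is None:
        x0 = np.clip(np.full(A.shape[1], 1.0), 0.0, upper)
    res = sp_optimize.minimize(
        lambda x: float(np.sum(w_eff * x**2)),
        x0,
        jac=lambda x: 2.0 * w_eff * x,
        bounds=[(0.0, u) for u in upper],
        constraints=[{"type": "eq", "fun": lambda x: A @ x - b, "jac": lambda x: A}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    if np.all(np.isfinite(res.x)) and np.linalg.norm(A @ res.x - b) <= 1e-4:
        w_kkt = np.where(np.isfinite(w), w, 1.0)
        return _verify_and_polish(A, b, upper, w_kkt, np.clip(res.x, 0.0, upper))
    return None


def _enumerate_qp(A, b, upper, w):
    """Exhaustive active-set enumeration: exact global optimum or None.

    O(3^n) reduced KKT solves — used only as a last resort on frames where
    the iterative solvers stall (near-capacity problems with many bounds
    active at the optimum).
    """
    import itertools

    n = A.shape[1]
    best_obj, best_x = np.inf, None
    for combo in itertools.product((0, 1, 2), repeat=n):
        status = np.array(combo, dtype=np.int8)
        if np.any((status == 2) & (upper <= _BOUND_TOL)):
            continue
        free = status == 0
        x, _, res = _solve_free(A, w, b, free, upper, status)
        if res > _RESIDUAL_TOL:
            continue
        if np.any(x < -_BOUND_TOL) or np.any(x > upper + _BOUND_TOL):
            continue
        obj = float(np.sum(w * x**2))
        if obj < best_obj:
            best_obj, best_x = obj, np.clip(x, 0.0, upper)
    return best_x


def _lp_feasible(problem: OptimizationProblem):
    """Phase-1 LP: is {0 <= F <= F_MAX, R F = M} non-empty?  Returns a point
    or None."""
    A, b = problem.moment_arm_matrix, problem.target_moments
    res = sp_optimize.linprog(
        c=np.zeros(A.shape[1]),
        A_eq=A,
        b_eq=b,
        bounds=[(0.0, u) for u in problem.f_max],
        method="highs",
    )
    return res.x if res.status == 0 else None


def solve_frame(problem: OptimizationProblem) -> MuscleForceSolution:
    """Global optimum of one frame's convex QP, or an infeasibility record.

    Raises :class:`SolverError` when every solver fails on a frame that the
    phase-1 LP certifies as feasible (retriable, distinct from infeasibility).
    """
    A, b = problem.moment_arm_matrix, problem.target_moments
    upper = problem.f_max
    w = problem.weights
    # activation objective: muscles with F_MAX = 0 cannot produce force
    w_eff = np.where(np.isfinite(w), w, 1.0)

    x, ok = _active_set_qp(A, b, upper, w_eff)
    if not ok:
        feas_point = _lp_feasible(problem)
        if feas_point is None:
            return MuscleForceSolution(
                forces=np.full(A.shape[1], np.nan),
                objective_value=np.nan,
                feasible=False,
                residuals=np.full(A.shape[0], np.nan),
            )
        x = _slsqp_fallback(problem, feas_point)
        if x is None:
            x = _enumerate_qp(A, b, upper, w_eff)
        if x is None:
            raise SolverError("QP solvers failed on a feasible frame")
    residuals = A @ x - b
    return MuscleForceSolution(
        forces=x,
        objective_value=problem.objective_value(x),
        feasible=True,
        residuals=residuals,
    )


def solve_movement(
    movement: STSMovement,
    kinetics: JointKinetics,
    muscles: list[MuscleParams],
    body: BodyModel,
    objective_id: str = "activation",
    k: float | np.ndarray = 1.0,
    moment_arm_matrix: np.ndarray | None = None,
    states: list[MuscleState] | None = None,
) -> MovementSolution:
    """Independent static-optimization solves for every frame of a movement."""
    if states is None:
        angles = np.degrees(
            np.stack(
                [
                    np.radians(movement.hip_series),
                    np.radians(movement.knee_series),
                    np.radians(movement.ankle_series),
                ],
                axis=-1,
            )
        )
        # analytic angle velocities of the cosine trajectory (deg/s)
        tt = movement.time
        wd = -0.5 * np.pi / movement.duration * np.sin(np.pi * tt / movement.duration)
        vel = np.stack(
            [
                movement.posture.hip_angle * wd,
                movement.posture.knee_angle * wd,
                movement.posture.ankle_angle * wd,
            ],
            axis=-1,
        )
        states = muscle_states(muscles, angles, vel, k=k)
    f_max = np.stack([s.f_max for s in states], axis=-1)  # (F, n)
    moments = kinetics.moments  # (F, 3) Nm/kg

    solutions = []
    infeasible = 0
    for fidx in range(movement.n_frames):
        problem = build_problem(
            moments[fidx], body.mass, muscles, f_max[fidx],
            objective_id=objective_id, moment_arm_matrix=moment_arm_matrix,
        )
        sol = solve_frame(problem)
        if not sol.feasible:
            infeasible += 1
        solutions.append(sol)
    return MovementSolution(
        solutions=solutions, objective_id=objective_id,
        infeasible_frame_count=infeasible,
    )
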