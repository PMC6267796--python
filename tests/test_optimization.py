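"""Static optimization: QP correctness against independent oracles.

The brute-force oracle enumerates every active-set pattern (each variable
free, at zero, or at its upper bound), solves the reduced equality-
constrained problem in closed form, and keeps the best feasible candidate —
an exact, exhaustive method independent of the solver's iteration path.
"""

import itertools

import numpy as np
import pytest

from sitstand.muscle import muscle_states, signed_moment_arms
from sitstand.optimization import (
    MuscleForceSolution,
    OptimizationProblem,
    build_problem,
    solve_frame,
    solve_movement,
)


def enumeration_oracle(A, b, upper, w, tol=1e-7):
    """Exact global optimum by exhaustive active-set enumeration, or None if
    the constraint set is empty."""
    n = A.shape[1]
    best = None
    for combo in itertools.product((0, 1, 2), repeat=n):
        status = np.array(combo)
        x = np.zeros(n)
        x[status == 2] = upper[status == 2]
        free = status == 0
        b_eff = b - A[:, status == 2] @ upper[status == 2]
        if np.any(free):
            Af = A[:, free]
            d = 0.5 / w[free]
            G = (Af * d) @ Af.T
            nu = np.linalg.lstsq(G, b_eff, rcond=None)[0]
            x[free] = d * (Af.T @ nu)
        if np.linalg.norm(A @ x - b) > tol:
            continue
        if np.any(x < -1e-9) or np.any(x > upper + 1e-9):
            continue
        obj = float(np.sum(w * x**2))
        if best is None or obj < best[0]:
            best = (obj, x)
    return best


class TestProblemAssembly:
    def test_ankle_row_has_three_nonzeros(self, muscles):
        prob = build_problem(np.zeros(3), 73.8, muscles, np.full(8, 100.0))
        assert np.count_nonzero(prob.moment_arm_matrix[2]) == 3

    def test_hip_row_signs_follow_anatomy(self, muscles):
        prob = build_problem(np.zeros(3), 73.8, muscles, np.full(8, 100.0))
        names = [m.name for m in muscles]
        hip = prob.moment_arm_matrix[0]
        assert hip[names.index("gluteus_maximus")] > 0
        assert hip[names.index("hamstrings")] > 0
        assert hip[names.index("iliopsoas")] < 0
        assert hip[names.index("rectus_femoris")] < 0

    def test_moments_denormalised_by_body_mass(self, muscles):
        prob = build_problem(np.array([0.5, 1.0, -0.1]), 73.8, muscles, np.full(8, 100.0))
        assert np.allclose(prob.target_moments, [36.9, 73.8, -7.38])

    def test_unknown_objective_rejected(self, muscles):
        with pytest.raises(ValueError):
            build_problem(np.zeros(3), 73.8, muscles, np.full(8, 100.0), "minmax")


class TestSolveFrame:
    def test_zero_moments_give_zero_forces(self, muscles):
        prob = build_problem(np.zeros(3), 73.8, muscles, np.full(8, 1000.0))
        sol = solve_frame(prob)
        assert sol.feasible
        assert np.allclose(sol.forces, 0.0, atol=1e-12)
        assert sol.objective_value == 0.0

    def test_two_agonist_closed_form(self):
        """One joint, two agonists, bounds slack: the activation-squared
        optimum is F_i = M r_i w_i / sum_j r_j^2 w_j with w_i = F_MAX_i^2."""
        r = np.array([[0.027, 0.011]])
        fmax = np.array([2808.0, 4380.0])
        M = np.array([30.0])
        prob = OptimizationProblem("activation", M, r, fmax, pcsa=np.array([46.8, 73.0]))
        sol = solve_frame(prob)
        w = fmax**2
        expected = M[0] * r[0] * w / np.sum(r[0] ** 2 * w)
        assert sol.feasible
        assert np.allclose(sol.forces, expected, atol=1e-8)

    def test_matches_enumeration_oracle_on_random_battery(self, rng):
        """300 random 2-3 muscle problems, objective agreement to 1e-6."""
        checked = 0
        for _ in range(300):
            n = int(rng.integers(2, 4))
            m = int(rng.integers(1, 4))
            A = rng.normal(0.0, 0.03, (m, n))
            upper = rng.uniform(0.0, 3000.0, n)
            w = 1.0 / rng.uniform(100.0, 3000.0, n) ** 2
            b = rng.normal(0.0, 30.0, m)
            prob = OptimizationProblem("stress", b, A, upper, pcsa=1.0 / np.sqrt(w))
            sol = solve_frame(prob)
            oracle = enumeration_oracle(A, b, upper, w)
            if oracle is None:
                assert not sol.feasible
            else:
                assert sol.feasible
                assert sol.objective_value == pytest.approx(
                    oracle[0], abs=1e-6, rel=1e-6
                )
                checked += 1
        assert checked > 50  # the battery must exercise feasible cases

    def test_residuals_within_tolerance_and_objective_consistent(self, muscles, rng):
        for _ in range(50):
            fmax = rng.uniform(500.0, 9000.0, 8)
            b = np.array(
                [rng.uniform(0, 40), rng.uniform(0, 80), rng.uniform(-15, 30)]
            )
            prob = build_problem(b / 73.8, 73.8, muscles, fmax)
            sol = solve_frame(prob)
            if sol.feasible:
                assert np.all(np.abs(sol.residuals) <= 1e-6)
                assert np.all(sol.forces >= -1e-12)
                assert np.all(sol.forces <= fmax + 1e-9)
                assert sol.objective_value == pytest.approx(
                    prob.objective_value(sol.forces), abs=1e-9
                )

    def test_agrees_with_multistart_slsqp(self, muscles, rng):
        """Convexity: SLSQP from 5 random starting points reaches the same
        optimum as the active-set solver."""
        from scipy.optimize import minimize

        fmax = np.full(8, 3000.0)
        prob = build_problem(np.array([0.4, 1.2, 0.1]), 73.8, muscles, fmax)
        sol = solve_frame(prob)
        A, b = prob.moment_arm_matrix, prob.target_moments
        w = prob.weights
        for _ in range(5):
            x0 = rng.uniform(0.0, 3000.0, 8)
            res = minimize(
                lambda x: np.sum(w * x**2),
                x0,
                jac=lambda x: 2 * w * x,
                bounds=[(0.0, u) for u in fmax],
                constraints=[{"type": "eq", "fun": lambda x: A @ x - b, "jac": lambda x: A}],
                method="SLSQP",
                options={"maxiter": 500, "ftol": 1e-14},
            )
            assert res.success
            assert np.sum(w * res.x**2) == pytest.approx(sol.objective_value, abs=1e-6)

    def test_infeasible_when_demand_exceeds_capacity(self, muscles):
        prob = build_problem(np.array([50.0, 50.0, 50.0]), 73.8, muscles, np.full(8, 10.0))
        sol = solve_frame(prob)
        assert not sol.feasible
        assert np.all(np.isnan(sol.forces))

    def test_objectives_generally_differ(self, muscles):
        b = np.array([0.45, 1.3, 0.05])
        fmax = np.full(8, 4000.0)
        j1 = solve_frame(build_problem(b, 73.8, muscles, fmax, "activation"))
        j2 = solve_frame(build_problem(b, 73.8, muscles, fmax, "stress"))
        assert j1.feasible and j2.feasible
        assert not np.allclose(j1.forces, j2.forces, atol=1.0)


class TestSolveMovement:
    def test_frames_solved_independently(self, adopted, body, muscles):
        from sitstand.inverse_dynamics import compute_joint_moments

        mv = adopted[0]
        kin = compute_joint_moments(mv, body)
        sol = solve_movement(mv, kin, muscles, body)
        assert len(sol.solutions) == mv.n_frames
        # re-solving a single frame in isolation reproduces the same forces
        from sitstand.muscle import muscle_states as states_fn

        idx = mv.n_frames // 3
        angles = np.stack([mv.hip_series, mv.knee_series, mv.ankle_series], -1)
        tt = mv.time
        wd = -0.5 * np.pi / mv.duration * np.sin(np.pi * tt / mv.duration)
        vel = np.stack(
            [mv.posture.hip_angle * wd, mv.posture.knee_angle * wd,
             mv.posture.ankle_angle * wd], -1,
        )
        st = states_fn(muscles, angles, vel)
        fmax = np.stack([s.f_max for s in st], -1)[idx]
        prob = build_problem(kin.moments[idx], body.mass, muscles, fmax)
        single = solve_frame(prob)
        assert np.allclose(single.forces, sol.solutions[idx].forces, atol=1e-6)

    def test_huge_moments_flag_movement_non_optimal(self, adopted, body, muscles):
        from sitstand.inverse_dynamics import compute_joint_moments

        mv = adopted[0]
        kin = compute_joint_moments(mv, body)
        inflated = type(kin)(
            time=kin.time,
            hip_moment=kin.hip_moment * 100.0,
            knee_moment=kin.knee_moment * 100.0,
            ankle_moment=kin.ankle_moment * 100.0,
            hip_joint_force=kin.hip_joint_force,
        )
        sol = solve_movement(mv, inflated, muscles, body)
        assert not sol.optimal
        assert sol.infeasible_frame_count > 0
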