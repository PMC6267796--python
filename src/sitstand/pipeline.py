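"""Full-study orchestration: generate -> filter -> dynamics -> optimize ->
contact force -> summaries, with CSV artifacts and reproducible seeds.

The per-movement evaluation used here (and by the sensitivity sweep) couples
the modules end to end: inverse-dynamics moments feed the per-frame static
optimization, whose hip-spanning muscle forces combine with the hip
intersegmental force into the contact-force series.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pathlib import Path
from scipy import stats

from .body import BodyModel, build_body_model
from .config import StudyConfig
from .contact import (
    HIP_MUSCLES,
    hip_contact_force,
    load_attachments,
    unit_vectors_series,
)
from .inverse_dynamics import JointKinetics, batch_joint_kinetics
from .movement import (
    STSMovement,
    generate_movements,
    movements_table,
    segment_orientation_angles,
)
from .muscle import MuscleParams, load_muscles
from .optimization import solve_movement

__all__ = [
    "SummaryTables",
    "evaluate_movements",
    "summarize",
    "seat_height_scaling_note",
    "run_full_study",
]

#: Fig. 5-style relationships summarised by ``summarize``
_RELATIONSHIPS = (
    ("seatoff_hip_deg", "peak_hjcf_n_kg"),
    ("peak_hip_moment_nm_kg", "peak_hjcf_n_kg"),
    ("peak_hip_extensor_force_n_kg", "peak_hjcf_n_kg"),
    ("seatoff_hip_deg", "peak_hip_extensor_force_n_kg"),
)


def _movement_id(mv: STSMovement, n_trunk: int = 71) -> int:
    i, j = mv.posture.grid_index
    return i * n_trunk + j


def evaluate_movements(
    movements: list[STSMovement],
    body: BodyModel,
    muscles: list[MuscleParams],
    attachments: dict,
    objective: str = "activation",
    k: float | np.ndarray = 1.0,
    moment_arm_matrix: np.ndarray | None = None,
    stride: int = 1,
    collect_series: bool = False,
):
    """Run dynamics + optimization + contact force for every ``stride``-th
    movement.  Returns (per-movement DataFrame, series dict or None)."""
    subset = movements[:: max(stride, 1)]
    if not subset:
        return pd.DataFrame(), None
    h0 = np.array([mv.posture.hip_angle for mv in subset])
    k0 = np.array([mv.posture.knee_angle for mv in subset])
    a0 = np.array([mv.posture.ankle_angle for mv in subset])
    duration, n_frames = subset[0].duration, subset[0].n_frames
    moments, hip_force = batch_joint_kinetics(h0, k0, a0, body, duration, n_frames)
    static_moments, _ = batch_joint_kinetics(
        h0, k0, a0, body, duration, n_frames, static=True
    )

    names = [m.name for m in muscles]
    hip_idx = [names.index(m) for m in HIP_MUSCLES]
    gmax = names.index("gluteus_maximus")
    hams = names.index("hamstrings")
    vast = names.index("vastus")
    rf = names.index("rectus_femoris")

    rows = []
    series = {"muscle_forces": [], "hjcf": []} if collect_series else None
    for i, mv in enumerate(subset):
        kin = JointKinetics(
            time=mv.time,
            hip_moment=moments[i, :, 0],
            knee_moment=moments[i, :, 1],
            ankle_moment=moments[i, :, 2],
            hip_joint_force=hip_force[i],
        )
        sol = solve_movement(
            mv, kin, muscles, body, objective_id=objective, k=k,
            moment_arm_matrix=moment_arm_matrix,
        )
        forces = sol.force_matrix  # (F, 8) N, NaN when infeasible
        forces_n_kg = forces / body.mass

        hip_rad = np.radians(mv.hip_series)
        knee_rad = np.radians(mv.knee_series)
        ankle_rad = np.radians(mv.ankle_series)
        _, phi_thigh, phi_hat = segment_orientation_angles(hip_rad, knee_rad, ankle_rad)
        uv = unit_vectors_series(attachments, phi_hat, phi_thigh)
        contact = hip_contact_force(kin.hip_joint_force, forces_n_kg[:, hip_idx], uv)

        def _nanmax(x):
            return float(np.nanmax(x)) if np.any(np.isfinite(x)) else float("nan")

        peak_f = np.full(len(names), np.nan)
        if np.any(np.isfinite(forces_n_kg)):
            peak_f = np.nanmax(forces_n_kg, axis=0)
        rows.append(
            {
                "movement_id": _movement_id(mv),
                "seatoff_hip_deg": mv.posture.hip_angle,
                "seatoff_knee_deg": mv.posture.knee_angle,
                "seatoff_ankle_deg": mv.posture.ankle_angle,
                "normal": mv.normal,
                "peak_hip_moment_nm_kg": float(kin.hip_moment.max()),
                "peak_knee_moment_nm_kg": float(kin.knee_moment.max()),
                "peak_ankle_moment_nm_kg": float(kin.ankle_moment.max()),
                "peak_static_hip_moment_nm_kg": float(static_moments[i, :, 0].max()),
                "peak_static_knee_moment_nm_kg": float(static_moments[i, :, 1].max()),
                "peak_static_ankle_moment_nm_kg": float(static_moments[i, :, 2].max()),
                "peak_hjcf_n_kg": contact.peak_hjcf,
                "peak_gmax_force_n_kg": peak_f[gmax],
                "peak_hamstrings_force_n_kg": peak_f[hams],
                "peak_quadriceps_force_n_kg": _nanmax(
                    forces_n_kg[:, vast] + forces_n_kg[:, rf]
                ),
                "peak_hip_extensor_force_n_kg": _nanmax(
                    forces_n_kg[:, gmax] + forces_n_kg[:, hams]
                ),
                "infeasible_frames": sol.infeasible_frame_count,
                "optimal": sol.optimal,
                "objective": objective,
            }
        )
        if collect_series:
            series["muscle_forces"].append(forces)
            series["hjcf"].append(contact.hjcf_series)
    return pd.DataFrame(rows), series


@dataclass
class SummaryTables:
    per_movement: pd.DataFrame
    aggregates: pd.Series
    relationships: pd.DataFrame


def summarize(per_movement: pd.DataFrame) -> SummaryTables:
    """Aggregate rows mirroring the study's comparison table, plus linear-fit
    statistics for the angle/moment/force/contact-force relationships."""
    tab = per_movement
    normal = tab[tab["normal"]]
    if normal.empty:
        raise ValueError("no normal movements in the per-movement table")

    def signed_min_abs(col: str) -> float:
        values = tab[col].to_numpy()
        return float(values[np.argmin(np.abs(values))])

    agg = {
        "n_movements": len(tab),
        "n_normal": int(tab["normal"].sum()),
        "min_abs_peak_static_hip_moment_nm_kg": signed_min_abs(
            "peak_static_hip_moment_nm_kg"
        ),
        "min_abs_peak_static_knee_moment_nm_kg": signed_min_abs(
            "peak_static_knee_moment_nm_kg"
        ),
        "min_abs_peak_static_ankle_moment_nm_kg": signed_min_abs(
            "peak_static_ankle_moment_nm_kg"
        ),
        "min_sum_peak_static_hip_knee_nm_kg": float(
            (tab["peak_static_hip_moment_nm_kg"] + tab["peak_static_knee_moment_nm_kg"]).min()
        ),
        "min_sum_peak_hip_knee_nm_kg": float(
            (tab["peak_hip_moment_nm_kg"] + tab["peak_knee_moment_nm_kg"]).min()
        ),
        "mean_peak_hip_moment_normal_nm_kg": float(
            normal["peak_hip_moment_nm_kg"].mean()
        ),
        "sd_peak_hip_moment_normal_nm_kg": float(
            normal["peak_hip_moment_nm_kg"].std(ddof=1)
        )
        if len(normal) > 1
        else 0.0,
        "mean_peak_hjcf_normal_n_kg": float(normal["peak_hjcf_n_kg"].mean()),
        "argmin_peak_hjcf_hip_deg": float(
            tab.loc[tab["peak_hjcf_n_kg"].idxmin(), "seatoff_hip_deg"]
        ),
    }
    for prefix, frame in (("adopted", tab), ("normal", normal)):
        for col in (
            "peak_gmax_force_n_kg",
            "peak_hamstrings_force_n_kg",
            "peak_quadriceps_force_n_kg",
            "peak_hip_extensor_force_n_kg",
        ):
            agg[f"mean_{col}_{prefix}"] = float(frame[col].mean())

    fits = []
    for x_col, y_col in _RELATIONSHIPS:
        ok = np.isfinite(tab[x_col]) & np.isfinite(tab[y_col])
        x = tab.loc[ok, x_col].to_numpy()
        y = tab.loc[ok, y_col].to_numpy()
        degenerate = len(x) < 2 or np.ptp(x) == 0.0 or np.ptp(y) == 0.0
        if degenerate:
            pear = spear = slope = intercept = float("nan")
        else:
            pear = float(stats.pearsonr(x, y).statistic)
            spear = float(stats.spearmanr(x, y).statistic)
            slope, intercept = (float(c) for c in np.polyfit(x, y, 1))
        fits.append(
            {
                "x": x_col,
                "y": y_col,
                "pearson_r": pear,
                "spearman_rho": spear,
                "slope": slope,
                "intercept": intercept,
                "n": int(ok.sum()),
            }
        )
    return SummaryTables(
        per_movement=tab,
        aggregates=pd.Series(agg),
        relationships=pd.DataFrame(fits),
    )


def seat_height_scaling_note(mean_peak_hjcf: float, factor: float = 1.3) -> float:
    """Scale a mean peak contact force to its higher-seat equivalent (the
    peak hip moment from a 0.4 m seat is about ``factor`` times that from a
    0.5 m seat, and moment and contact force are approximately linear)."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    return mean_peak_hjcf / factor


def run_full_study(config: StudyConfig | None = None, outdir: str | Path = "results"):
    """Execute the whole simulation and write all CSV artifacts.

    Returns the :class:`SummaryTables` of the baseline run.
    """
    cfg = config or StudyConfig()
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(f"[{time.strftime('%H:%M:%S')}] {msg}")

    cfg.to_yaml(out / "config.yaml")

    stage = "setup"
    try:
        body = build_body_model(cfg.height_m, cfg.mass_kg, config=cfg)
        muscles = load_muscles(sigma=cfg.specific_tension_n_cm2)
        attachments = load_attachments()

        stage = "generate"
        t0 = time.perf_counter()
        movements, adopted = generate_movements(body, cfg)
        movements_table(movements).to_csv(out / "movements.csv", index=False)
        log(
            f"generate: {len(movements)} postures, {len(adopted)} adopted, "
            f"{sum(m.normal for m in adopted)} normal "
            f"({time.perf_counter() - t0:.1f} s)"
        )

        stage = "dynamics"
        t0 = time.perf_counter()
        subset = adopted[:: cfg.movement_stride]
        h0 = np.array([m.posture.hip_angle for m in subset])
        k0 = np.array([m.posture.knee_angle for m in subset])
        a0 = np.array([m.posture.ankle_angle for m in subset])
        moments, hip_force = batch_joint_kinetics(
            h0, k0, a0, body, cfg.duration_s, cfg.n_frames
        )
        ids = np.repeat([_movement_id(m) for m in subset], cfg.n_frames)
        frames = np.tile(np.arange(cfg.n_frames), len(subset))
        pd.DataFrame(
            {
                "movement_id": ids,
                "frame": frames,
                "hip_moment_nm_kg": moments[..., 0].ravel(),
                "knee_moment_nm_kg": moments[..., 1].ravel(),
                "ankle_moment_nm_kg": moments[..., 2].ravel(),
                "hip_force_x_n_kg": hip_force[..., 0].ravel(),
                "hip_force_y_n_kg": hip_force[..., 1].ravel(),
            }
        ).to_csv(out / "kinetics.csv", index=False)
        log(f"dynamics: {len(subset)} movements ({time.perf_counter() - t0:.1f} s)")

        stage = "optimize"
        t0 = time.perf_counter()
        per_movement, series = evaluate_movements(
            adopted, body, muscles, attachments,
            objective=cfg.objective, stride=cfg.movement_stride, collect_series=True,
        )
        names = [m.name for m in muscles]
        force_rows = []
        hjcf_rows = []
        for row_idx, mid in enumerate(per_movement["movement_id"]):
            forces = series["muscle_forces"][row_idx]
            hjcf = series["hjcf"][row_idx]
            for f in range(cfg.n_frames):
                rec = {"movement_id": mid, "frame": f, "feasible": bool(np.isfinite(forces[f, 0]))}
                rec.update({name: forces[f, j] for j, name in enumerate(names)})
                force_rows.append(rec)
                hjcf_rows.append({"movement_id": mid, "frame": f, "hjcf_n_kg": hjcf[f]})
        pd.DataFrame(force_rows).to_csv(out / "muscle_forces.csv", index=False)
        pd.DataFrame(hjcf_rows).to_csv(out / "hjcf.csv", index=False)
        infeasible = int(per_movement["infeasible_frames"].sum())
        log(
            f"optimize[{cfg.objective}]: {len(per_movement)} movements, "
            f"{infeasible} infeasible frames, "
            f"{int(per_movement['optimal'].sum())} optimal movement-runs "
            f"({time.perf_counter() - t0:.1f} s)"
        )

        stage = "sensitivity"
        t0 = time.perf_counter()
        from .sensitivity import run_sensitivity

        sens = run_sensitivity(
            adopted, body, muscles, attachments,
            n_draws_per_objective=cfg.n_draws_per_objective,
            seed=cfg.seed, stride=cfg.movement_stride, per_muscle_k=cfg.per_muscle_k,
        )
        sens.runs.to_csv(out / "sensitivity.csv", index=False)
        for objective_id, found, total in sens.feasibility_counts():
            log(
                f"sensitivity[{objective_id}]: optimal solutions found "
                f"{found} of {total} movement-runs"
            )
        log(f"sensitivity: ({time.perf_counter() - t0:.1f} s)")

        stage = "summarize"
        summary = summarize(per_movement)
        summary.per_movement.to_csv(out / "summary.csv", index=False)
        summary.aggregates.to_frame("value").to_csv(out / "aggregates.csv")
        summary.relationships.to_csv(out / "relationships.csv", index=False)
        log("summarize: done")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
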