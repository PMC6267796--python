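"""Four-parameter sensitivity analysis of the muscle-force estimation.

For each objective function (activation-squared and stress-squared) the
muscle parameters are perturbed in ten random draws: PCSAs uniformly within
plus/minus one standard deviation of their means, every nonzero moment arm
uniformly within plus/minus 1 cm, and the normalised maximum muscle force
(force-length ability) scaled by a single factor k drawn uniformly from
[0.5, 1.5].  Each adopted movement is then re-evaluated end to end (20 runs
per movement), and the per-run association between seat-off hip angle and
peak hip joint contact force is recorded.

The same ten draws are applied to every movement (fixed-draws bookkeeping:
``movements x 10`` solution counts per objective); a config switch draws k
per muscle instead of globally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .body import BodyModel
from .movement import STSMovement
from .muscle import MuscleParams
from .optimization import OBJECTIVES

__all__ = ["PerturbationSpec", "SensitivityResult", "draw_perturbation", "run_sensitivity"]

_ARM_DELTA_M = 0.01  # +/- 1 cm on every nonzero moment arm
_K_RANGE = (0.5, 1.5)  # force-length-ability scaling
_MAX_REDRAWS = 1000


@dataclass
class PerturbationSpec:
    """One random parameter draw of the sensitivity sweep."""

    objective_id: str
    draw_index: int
    pcsa_delta: np.ndarray  # (n,) cm^2
    moment_arm_delta: np.ndarray  # (3, n) m, zero where the muscle has no arm
    k: np.ndarray  # (n,) force-length scaling (identical entries unless per-muscle)
    redraws: int = 0  # positivity-violation redraws that were needed


@dataclass
class SensitivityResult:
    """Per-run per-movement records plus per-draw association statistics."""

    runs: pd.DataFrame
    draws: list[PerturbationSpec]
    seed: int

    def per_draw_stats(self) -> pd.DataFrame:
        """Pearson/Spearman of seat-off hip angle vs peak HJCF per run.

        Only optimal movement-runs enter the statistics (runs where a frame's
        muscle-force demand exceeded the perturbed force bounds are counted
        in :meth:`feasibility_counts` but excluded from the relationship, as
        in the study's own bookkeeping of 'optimal solutions found').
        """
        rows = []
        for (objective_id, draw), grp in self.runs.groupby(["objective", "draw"]):
            ok = grp["optimal"] & np.isfinite(grp["peak_hjcf_n_kg"])
            x = grp.loc[ok, "seatoff_hip_deg"]
            y = grp.loc[ok, "peak_hjcf_n_kg"]
            enough = ok.sum() >= 3 and x.nunique() > 1
            rows.append(
                {
                    "objective": objective_id,
                    "draw": draw,
                    "pearson_r": float(stats.pearsonr(x, y).statistic)
                    if enough
                    else float("nan"),
                    "spearman_rho": float(stats.spearmanr(x, y).statistic)
                    if enough
                    else float("nan"),
                    "n": int(ok.sum()),
                }
            )
        return pd.DataFrame(rows)

    def feasibility_counts(self):
        """(objective, optimal movement-runs, total movement-runs) per
        objective — the study's 'optimal solutions found' bookkeeping."""
        out = []
        for objective_id, grp in self.runs.groupby("objective"):
            out.append((objective_id, int(grp["optimal"].sum()), len(grp)))
        return out


def _positive_uniform(
    rng: np.random.Generator, base: np.ndarray, half_width: np.ndarray
) -> tuple[np.ndarray, int]:
    """base + U(-half_width, +half_width), element-wise redrawn until > 0."""
    delta = rng.uniform(-half_width, half_width)
    redraws = 0
    bad = base + delta <= 0.0
    while np.any(bad):
        redraws += 1
        if redraws > _MAX_REDRAWS:
            raise RuntimeError("perturbation redraw limit exceeded")
        delta = np.where(bad, rng.uniform(-half_width, half_width), delta)
        bad = base + delta <= 0.0
    return delta, redraws


def draw_perturbation(
    base_muscles: list[MuscleParams],
    objective_id: str,
    rng: np.random.Generator,
    draw_index: int = 0,
    per_muscle_k: bool = False,
) -> tuple[PerturbationSpec, list[MuscleParams]]:
    """One independent parameter draw and the perturbed muscle set."""
    if objective_id not in OBJECTIVES:
        raise ValueError(f"unknown objective {objective_id!r}")
    n = len(base_muscles)
    pcsa_base = np.array([m.pcsa_mean for m in base_muscles])
    pcsa_sd = np.array([m.pcsa_sd for m in base_muscles])
    arm_base = np.stack([m.moment_arm for m in base_muscles], axis=1)  # (3, n)

    pcsa_delta, redraws_p = _positive_uniform(rng, pcsa_base, pcsa_sd)
    arm_half = np.where(arm_base > 0.0, _ARM_DELTA_M, 0.0)
    # flatten so the redraw logic sees only the genuine (nonzero-arm) entries
    arm_delta = np.zeros_like(arm_base)
    nz = arm_base > 0.0
    delta_nz, redraws_a = _positive_uniform(rng, arm_base[nz], arm_half[nz])
    arm_delta[nz] = delta_nz
    if per_muscle_k:
        k = rng.uniform(*_K_RANGE, size=n)
    else:
        k = np.full(n, rng.uniform(*_K_RANGE))

    spec = PerturbationSpec(
        objective_id=objective_id,
        draw_index=draw_index,
        pcsa_delta=pcsa_delta,
        moment_arm_delta=arm_delta,
        k=k,
        redraws=redraws_p + redraws_a,
    )
    perturbed = [
        m.perturbed(
            pcsa=pcsa_base[i] + pcsa_delta[i],
            moment_arm=arm_base[:, i] + arm_delta[:, i],
        )
        for i, m in enumerate(base_muscles)
    ]
    return spec, perturbed


def run_sensitivity(
    adopted_movements: list[STSMovement],
    body: BodyModel,
    base_muscles: list[MuscleParams],
    attachments: dict,
    n_draws_per_objective: int = 10,
    seed: int = 0,
    stride: int = 1,
    per_muscle_k: bool = False,
) -> SensitivityResult:
    """The full perturb-and-re-estimate sweep.

    Every adopted movement (or every ``stride``-th one) is re-evaluated under
    ``n_draws_per_objective`` draws for each of the two objectives; the
    default configuration therefore performs ``20 x len(adopted)`` muscle
    force estimations.
    """
    from .pipeline import evaluate_movements  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    frames: list[pd.DataFrame] = []
    draws: list[PerturbationSpec] = []
    for objective_id in OBJECTIVES:
        for draw in range(n_draws_per_objective):
            spec, perturbed = draw_perturbation(
                base_muscles, objective_id, rng, draw_index=draw,
                per_muscle_k=per_muscle_k,
            )
            draws.append(spec)
            arm_matrix = np.stack([m.signed_arms for m in perturbed], axis=1)
            table, _ = evaluate_movements(
                adopted_movements, body, perturbed, attachments,
                objective=objective_id, k=spec.k,
                moment_arm_matrix=arm_matrix, stride=stride,
            )
            table = table.assign(draw=draw, k=spec.k[0])
            frames.append(table)
    runs = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["movement_id", "seatoff_hip_deg", "peak_hjcf_n_kg",
                     "optimal", "objective", "draw"]
        )
    )
    return SensitivityResult(runs=runs, draws=draws, seed=seed)
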