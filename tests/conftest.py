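"""Shared fixtures.

The full-grid study objects are session-scoped because several acceptance
checks consume the same 2911-posture grid and the same per-movement
evaluation of the adopted set; computing them once keeps the suite fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from sitstand import (
    StudyConfig,
    build_body_model,
    evaluate_movements,
    generate_movements,
    load_attachments,
    load_muscles,
)
from sitstand.movement import movements_table


@pytest.fixture(scope="session")
def cfg() -> StudyConfig:
    return StudyConfig()


@pytest.fixture(scope="session")
def body(cfg):
    return build_body_model(cfg.height_m, cfg.mass_kg, config=cfg)


@pytest.fixture(scope="session")
def muscles():
    return load_muscles()


@pytest.fixture(scope="session")
def attachments():
    return load_attachments()


@pytest.fixture(scope="session")
def study(body, cfg):
    """(all movements, adopted movements) on the default grid."""
    return generate_movements(body, cfg)


@pytest.fixture(scope="session")
def adopted(study):
    return study[1]


@pytest.fixture(scope="session")
def adopted_table(adopted):
    return movements_table(adopted)


@pytest.fixture(scope="session")
def adopted_eval(adopted, body, muscles, attachments):
    """Per-movement dynamics + optimization + contact force for every
    adopted movement (activation-squared objective, nominal parameters)."""
    table, _ = evaluate_movements(adopted, body, muscles, attachments)
    return table


@pytest.fixture(scope="session")
def coarse_cfg() -> StudyConfig:
    """A reduced grid for fast end-to-end runs."""
    return StudyConfig(
        hip_x_step_m=0.05,
        trunk_step_deg=10.0,
        n_frames=21,
        n_draws_per_objective=1,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
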