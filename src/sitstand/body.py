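"""Sagittal four-segment anthropometric body model.

The model is the classic head-arms-trunk (HAT) / thigh / shank / foot
reduction used for planar sit-to-stand analysis.  Segment lengths, masses,
centre-of-mass positions and gyration radii are scaled from body height and
mass through a fraction table (shipped as ``_fixtures/anthropometry.csv``,
swappable via :func:`load_fraction_table`).

Coordinate frame: X positive anterior, Y positive up, origin at the ankle
joint's ground projection.  The model is bilaterally symmetric, so the HAT
mass plus twice the leg-segment masses equals the body mass exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .config import StudyConfig

SEGMENTS = ("hat", "thigh", "shank", "foot")
#: segments present once (HAT) vs twice (legs) in the whole-body mass budget
BILATERAL = ("thigh", "shank", "foot")


class ConfigurationError(ValueError):
    """A fixture or configuration table is missing required entries."""


@dataclass(frozen=True)
class SegmentParams:
    name: str
    length: float  # m
    mass: float  # kg
    com_ratio: float  # COM distance from proximal joint / length
    gyration_ratio: float  # radius of gyration about COM / length

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: length must be positive")
        if self.mass < 0:
            raise ValueError(f"{self.name}: mass must be non-negative")
        if not 0.0 <= self.com_ratio <= 1.0:
            raise ValueError(f"{self.name}: com_ratio outside [0, 1]")
        if not 0.0 <= self.gyration_ratio <= 1.0:
            raise ValueError(f"{self.name}: gyration_ratio outside [0, 1]")

    @property
    def moment_of_inertia(self) -> float:
        """Moment of inertia about the segment COM (kg m^2)."""
        return self.mass * (self.gyration_ratio * self.length) ** 2


@dataclass(frozen=True)
class BodyModel:
    height: float  # m
    mass: float  # kg
    hat: SegmentParams
    thigh: SegmentParams
    shank: SegmentParams
    foot: SegmentParams
    heel_to_ankle_x: float  # m, horizontal heel -> ankle offset
    foot_length: float  # m, heel -> toe support base
    hip_height_seatoff: float  # m
    ankle_height: float  # m, ankle joint centre above the floor
    gravity: float = 9.8  # m/s^2

    def segment(self, name: str) -> SegmentParams:
        if name not in SEGMENTS:
            raise ConfigurationError(f"unknown segment {name!r}")
        return getattr(self, name)

    @property
    def heel_x(self) -> float:
        return -self.heel_to_ankle_x

    @property
    def toe_x(self) -> float:
        return self.heel_x + self.foot_length

    @property
    def total_segment_mass(self) -> float:
        return self.hat.mass + 2.0 * sum(self.segment(s).mass for s in BILATERAL)


def load_fraction_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load an anthropometric fraction table (default: the shipped fixture)."""
    if path is None:
        ref = resources.files("sitstand") / "_fixtures" / "anthropometry.csv"
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, comment="#")
    else:
        table = pd.read_csv(path, comment="#")
    required = {"segment", "length_fraction", "mass_fraction", "com_ratio", "gyration_ratio"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigurationError(f"fraction table lacks columns: {sorted(missing)}")
    return table.set_index("segment")


def build_body_model(
    height: float,
    mass: float,
    fraction_table: pd.DataFrame | None = None,
    *,
    config: StudyConfig | None = None,
) -> BodyModel:
    """Scale the fraction table to a concrete body.

    Segment masses are scaled so they sum (with bilateral legs) to ``mass``
    exactly; any rounding slack in the fixture's mass fractions is folded into
    the HAT segment.
    """
    if height <= 0:
        raise ValueError("height must be positive")
    if mass < 0:
        raise ValueError("mass must be non-negative")
    cfg = config or StudyConfig()
    if fraction_table is None:
        fraction_table = load_fraction_table()

    segments: dict[str, SegmentParams] = {}
    for name in SEGMENTS:
        if name not in fraction_table.index:
            raise ConfigurationError(f"fraction table has no row for segment {name!r}")
        row = fraction_table.loc[name]
        segments[name] = SegmentParams(
            name=name,
            length=float(row["length_fraction"]) * height,
            mass=float(row["mass_fraction"]) * mass,
            com_ratio=float(row["com_ratio"]),
            gyration_ratio=float(row["gyration_ratio"]),
        )

    # enforce exact mass conservation (bilateral legs counted twice)
    leg_mass = 2.0 * sum(segments[s].mass for s in BILATERAL)
    hat = segments["hat"]
    segments["hat"] = SegmentParams(
        name="hat",
        length=hat.length,
        mass=mass - leg_mass,
        com_ratio=hat.com_ratio,
        gyration_ratio=hat.gyration_ratio,
    )

    return BodyModel(
        height=height,
        mass=mass,
        hat=segments["hat"],
        thigh=segments["thigh"],
        shank=segments["shank"],
        foot=segments["foot"],
        heel_to_ankle_x=cfg.heel_to_ankle_x_m,
        foot_length=segments["foot"].length,
        hip_height_seatoff=cfg.hip_height_seatoff_m,
        ankle_height=(
            cfg.ankle_height_m if cfg.ankle_height_m is not None else 0.039 * height
        ),
        gravity=cfg.gravity_m_s2,
    )
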