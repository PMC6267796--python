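"""Study configuration: every tunable parameter of the simulation in one place.

The defaults reproduce the reference study conditions: a 1.74 m / 73.8 kg
symmetric sagittal model standing up from a 0.4 m chair (hip height 0.513 m at
seat-off) in 1.55 s, with the 41 x 71 seat-off posture grid and the
adoption/normal-movement filters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class StudyConfig:
    # anthropometry
    height_m: float = 1.74
    mass_kg: float = 73.8
    hip_height_seatoff_m: float = 0.513
    heel_to_ankle_x_m: float = 0.06
    #: ankle joint centre height above the floor; None -> the standard
    #: malleolus fraction 0.039 * height
    ankle_height_m: float | None = None
    gravity_m_s2: float = 9.8

    # seat-off posture grid: hip X posterior to the ankle, trunk clockwise
    # from vertical
    hip_x_min_m: float = -0.40
    hip_x_max_m: float = 0.0
    hip_x_step_m: float = 0.01
    trunk_min_deg: float = 0.0
    trunk_max_deg: float = 70.0
    trunk_step_deg: float = 1.0

    # trajectory
    duration_s: float = 1.55
    n_frames: int = 101

    # adoption filters (closed intervals, degrees)
    hip_range_deg: tuple[float, float] = (85.0, 145.0)
    knee_range_deg: tuple[float, float] = (95.0, 120.0)
    ankle_range_deg: tuple[float, float] = (15.0, 45.0)
    normal_hip_range_deg: tuple[float, float] = (85.0, 101.0)

    # muscle model
    specific_tension_n_cm2: float = 60.0

    # optimization / sensitivity
    objective: str = "activation"  # "activation" (J1) or "stress" (J2)
    n_draws_per_objective: int = 10
    seed: int = 0
    movement_stride: int = 1  # evaluate every k-th adopted movement
    per_muscle_k: bool = False

    def validate(self) -> None:
        if self.height_m <= 0 or self.mass_kg < 0:
            raise ValueError("height must be positive and mass non-negative")
        if self.n_frames < 3:
            raise ValueError("n_frames must be at least 3")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.objective not in ("activation", "stress"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.hip_x_step_m <= 0 or self.trunk_step_deg <= 0:
            raise ValueError("grid steps must be positive")
        if self.movement_stride < 1:
            raise ValueError("movement_stride must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in data:
                v = data[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg
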