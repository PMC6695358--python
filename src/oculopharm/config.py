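"""Run configuration: schema-validated YAML/JSON with full defaults.

A run configuration bundles the task block, the plant block, precision
values and sweep grids, trial counts and the master seed.  Unknown keys are
rejected so a typo cannot silently fall back to a default, and the fully
resolved configuration is written next to every output directory for
provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .engine import Precisions
from .plant import PlantParams
from .task import TaskConfig


class TaskBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    eccentricity_deg: float = Field(8.0, gt=0)
    n_delay_steps: int = Field(1, ge=1)
    c_pref: float = Field(4.0, gt=0)
    p_cue: float = Field(0.99, gt=0.5, le=1.0)
    p_proprio: float = Field(0.95, gt=0.5, le=1.0)
    p_feedback: float = Field(0.995, gt=0.5, le=1.0)
    target_stickiness: float = Field(0.9, gt=0.25, le=1.0)
    obs_precision: float = Field(4.0, gt=0)

    def to_task_config(self) -> TaskConfig:
        return TaskConfig(**self.model_dump())


class PlantBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    k: float = Field(90000.0, gt=0)
    p_target: float = Field(1.0, gt=0)
    lambda0: float = Field(174.0, gt=0)
    c_lambda: float = Field(271.0, ge=0)
    tau_reflex: float = Field(0.002, gt=0)
    dt: float = Field(0.001, gt=0)
    segment_duration: float = Field(0.25, gt=0)

    def to_plant_params(self) -> PlantParams:
        return PlantParams(**self.model_dump())


class PrecisionBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    zeta: float = Field(1.0, ge=0)
    omega: float = Field(4.0, ge=0)
    beta: float = Field(0.5, gt=0)
    pi_motor: float = Field(1.0, gt=0)

    def to_precisions(self) -> Precisions:
        return Precisions(**self.model_dump())


class GridBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    gaba: list[float] = [0.25, 0.5, 1.0, 2.0, 4.0, 8.0]
    ach: list[float] = [0.0, 0.25, 0.5, 1.0, 2.0, 4.0]
    dopamine_beta: list[float] = [64.0, 16.0, 4.0, 1.0, 0.25]
    noradrenaline: list[float] = [0.5, 1.0, 2.0, 4.0]
    interaction_omega: list[float] = [0.5, 4.0]
    interaction_beta: list[float] = [4.0, 0.5]


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    task: TaskBlock = TaskBlock()
    plant: PlantBlock = PlantBlock()
    precisions: PrecisionBlock = PrecisionBlock()
    grids: GridBlock = GridBlock()
    n_trials: int = Field(100, ge=1)
    seed: int = Field(0, ge=0)
    outdir: str = "oculopharm_out"
    plot: bool = False

    @field_validator("outdir")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("outdir must be a non-empty path")
        return v


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    ``None`` or an empty file yields all defaults.  Schema violations raise
    with a message naming the offending key.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"configuration root must be a mapping, got {type(data).__name__}")
    return RunConfig(**data)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration (provenance copy)."""
    Path(path).write_text(json.dumps(cfg.model_dump(), indent=2) + "\n")


def resolve(cfg: RunConfig):
    """RunConfig -> (TaskConfig, PlantParams, Precisions)."""
    return (cfg.task.to_task_config(), cfg.plant.to_plant_params(),
            cfg.precisions.to_precisions())
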