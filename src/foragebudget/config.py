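"""YAML run-configuration loading and validation.

A run config mirrors the model's parameter tables: a ``herd`` block
(head count, %BW), a ``forage`` block (standing forage, harvest
efficiency), a ``period`` block, optional ``scenarios``, ``sensitivity``
and ``extrapolation`` blocks, file ``paths`` and a ``seed``.  Unknown
keys are rejected by name and *all* violations are reported at once,
not just the first.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid run configuration; ``problems`` lists every violation."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.problems))


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class HerdBlock(_Block):
    head_count: int = Field(ge=1)
    pct_bw: float = Field(default=2.5, gt=0, lt=100)


class ForageBlock(_Block):
    forage_kg_per_ha: float = Field(gt=0)
    harvest_efficiency: float = Field(default=0.25, gt=0, le=1)


class PeriodBlock(_Block):
    n_days: int = Field(ge=1)
    label: str = ""


class ScenarioBlock(_Block):
    kind: Literal["initial_bw", "midseason_bw", "precision"]
    static_bw_kg: Optional[float] = Field(default=None, gt=0)
    label: str = ""

    @model_validator(mode="after")
    def _needs_bw_or_matrix(self):
        if self.kind != "precision" and self.static_bw_kg is None:
            raise ValueError(f"{self.kind} scenario requires static_bw_kg")
        return self


class SensitivityBlock(_Block):
    lower: float = Field(default=1.8, gt=0)
    upper: float = 2.7
    mean: float = 2.25
    sd: float = Field(default=0.15, gt=0)
    n_draws: int = Field(default=10_000, ge=1)

    @model_validator(mode="after")
    def _ordered(self):
        if not self.lower < self.upper:
            raise ValueError("sensitivity requires lower < upper")
        return self


class ExtrapolationBlock(_Block):
    animals_state: int = Field(ge=0)
    animals_local: int = Field(ge=1)


class PathsBlock(_Block):
    weights_csv: Optional[str] = None
    forage_csv: Optional[str] = None
    out_dir: str = "out"


class RunConfig(_Block):
    herd: HerdBlock
    forage: ForageBlock
    period: PeriodBlock
    scenarios: list[ScenarioBlock] = Field(default_factory=list)
    sensitivity: Optional[SensitivityBlock] = None
    extrapolation: Optional[ExtrapolationBlock] = None
    paths: PathsBlock = Field(default_factory=PathsBlock)
    seed: int = 0


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run config.

    Raises :class:`ConfigError` carrying every violation (unknown keys,
    out-of-range values, missing blocks) rather than failing one at a
    time.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError([f"{path}: top level must be a mapping"])
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        problems = [
            f"{'.'.join(str(p) for p in e['loc']) or '<root>'}: {e['msg']}"
            for e in err.errors()
        ]
        raise ConfigError(problems) from None
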