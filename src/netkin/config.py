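"""Validated run configuration for the command-line pipeline.

A whole study is one YAML (or JSON) document: input paths, the
edge-expansion dialect, which layers are absolute, estimator settings and
the condition definitions.  Unknown keys are rejected so typos fail fast.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .estimator import Condition


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PathsConfig(_Strict):
    snapshot: str
    gene_list: str | None = None
    expression: str
    outdir: str = "netkin_out"


class InitialConfig(_Strict):
    phospho_fraction: float = 0.30
    cell_volume_ul: float = 8.0


class EstimatorConfig(_Strict):
    budget_per_param: int = 200
    cycle_tolerance: float = 1e-3
    max_cycles: int = 50
    init_policy: str = "ones"   # "ones" | "random"
    seed: int | None = None


class ConditionConfig(_Strict):
    inhibit: dict[str, float] = Field(default_factory=dict)


class ConditionsConfig(_Strict):
    train: list[str] = Field(default_factory=lambda: ["control"])
    holdout: str | None = None
    definitions: dict[str, ConditionConfig] = Field(default_factory=dict)

    def condition(self, name: str) -> Condition:
        spec = self.definitions.get(name, ConditionConfig())
        return Condition(name=name, inhibit=dict(spec.inhibit))


class RunConfig(_Strict):
    paths: PathsConfig
    dialect: str = "lumped"
    layer_mode: dict[str, str] = Field(default_factory=lambda: {
        "protein": "absolute", "phospho": "mean_normalized", "rna": "absolute"})
    rna_units: str = "per_ul"
    initial: InitialConfig = Field(default_factory=InitialConfig)
    estimator: EstimatorConfig = Field(default_factory=EstimatorConfig)
    conditions: ConditionsConfig = Field(default_factory=ConditionsConfig)
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with path.open() as fh:
            payload = yaml.safe_load(fh)
        cfg = cls.model_validate(payload)
        base = path.parent
        for attr in ("snapshot", "gene_list", "expression"):
            value = getattr(cfg.paths, attr)
            if value is not None and not Path(value).is_absolute():
                setattr(cfg.paths, attr, str(base / value))
        for attr in ("snapshot", "gene_list", "expression"):
            value = getattr(cfg.paths, attr)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"configured path {attr} = {value!r} not found")
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()).hexdigest()[:12]
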