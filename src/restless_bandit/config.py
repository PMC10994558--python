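"""Schema-validated pipeline configuration.

One JSON document configures every stage; unknown keys are rejected and
validation errors name the offending field path. Every command writes a
resolved copy of its configuration next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .cohort import CohortConfig, default_cohort_config
from .inference import FitConfig
from .task import WalkParams


class WalkConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    decay: float = 0.9836
    decay_center: float = 50.0
    diffusion_sd: float = 2.8
    observation_sd: float = 4.0
    floor: float = 0.0
    ceiling: float = 100.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "WalkConfig":
        self.to_walk_params()  # delegates range checks; raises naming the field
        return self

    def to_walk_params(self) -> WalkParams:
        return WalkParams(
            decay=self.decay,
            decay_center=self.decay_center,
            diffusion_sd=self.diffusion_sd,
            observation_sd=self.observation_sd,
            floor=self.floor,
            ceiling=self.ceiling,
        )


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    learning_rule: str = "bayes"
    choice_rule: str = "SMEP"
    bonus_on: str = "sd"


class ParamsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    alpha: float | None = None
    beta: float = 0.1
    phi: float | None = None
    rho: float | None = None


class FittingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_starts: int = Field(default=10, ge=1)
    maxiter: int = Field(default=500, ge=1)
    beta_prior_scale: float = Field(default=1.0, gt=0)
    phi_prior_scale: float = Field(default=2.0, gt=0)
    rho_prior_sd: float = Field(default=5.0, gt=0)
    allow_negative_phi: bool = False
    laplace_draws: int = Field(default=2000, ge=10)
    criterion: str = "bic"

    def to_fit_config(self, n_bandits: int = 4) -> FitConfig:
        return FitConfig(
            n_starts=self.n_starts,
            maxiter=self.maxiter,
            beta_prior_scale=self.beta_prior_scale,
            phi_prior_scale=self.phi_prior_scale,
            rho_prior_sd=self.rho_prior_sd,
            allow_negative_phi=self.allow_negative_phi,
            laplace_draws=self.laplace_draws,
            n_bandits=n_bandits,
        )


class ClassificationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    best_from: str = "latent_mean"
    block_size: int = Field(default=50, ge=1)


class RecoveryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_subjects: int = Field(default=40, ge=10)
    missed_rate: float = Field(default=0.0, ge=0.0, lt=1.0)
    model_confusion: bool = False
    n_replicates: int = Field(default=5, ge=1)


class PipelineConfig(BaseModel):
    """Top-level configuration covering every pipeline stage."""

    model_config = ConfigDict(extra="forbid")

    walk: WalkConfig = WalkConfig()
    model: ModelConfig = ModelConfig()
    params: ParamsConfig = ParamsConfig()
    fitting: FittingConfig = FittingConfig()
    cohort: CohortConfig = Field(default_factory=default_cohort_config)
    classification: ClassificationConfig = ClassificationConfig()
    recovery: RecoveryConfig = RecoveryConfig()
    seed: int = 0


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        return PipelineConfig.model_validate(json.load(fh))


def write_resolved_config(config: PipelineConfig, out_dir: str | Path) -> str:
    """Dump the resolved config next to the outputs; return its sha256."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    text = json.dumps(config.model_dump(), indent=2, sort_keys=True) + "\n"
    (out / "config.resolved.json").write_text(text)
    return hashlib.sha256(text.encode()).hexdigest()
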