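"""YAML configuration schema with defaults matching the motivating design.

An empty config file yields the canonical 18-cluster, 13-period study with
alpha = -10, sigma_b0 = 0.30, theta = log(0.6) and 500 replicates.  Unknown
keys are rejected so typos fail loudly before any computation starts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .design import DEFAULT_OFFSET_SEED, StudyDesign, build_design
from .glmm import FitOptions
from .study import StudyConfig

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Configuration file violates the schema."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DesignBlock(_Strict):
    n_clusters: int = Field(default=18, ge=1)
    n_periods: int = Field(default=13, ge=1)
    baseline_periods: int = Field(default=2, ge=0)
    clusters_per_step: int = Field(default=2, ge=1)
    period_length_months: float = Field(default=3.0, gt=0)
    offset_seed: int = DEFAULT_OFFSET_SEED
    offset_file: Optional[str] = None


class ScenarioBlock(_Strict):
    alpha: float = -10.0
    sigma_b0: float = Field(default=0.30, ge=0)
    theta: float = Field(default=float(np.log(0.6)), le=0)


class StudyBlock(_Strict):
    scenarios: list[Literal["1", "2.1", "2.2", "3", "4.1", "4.2"]] = Field(
        default_factory=lambda: list(("1", "2.1", "2.2", "3", "4.1", "4.2"))
    )
    models: list[int] = Field(default_factory=lambda: list(range(1, 11)))
    replicates: int = Field(default=500, ge=1)
    null_replicates: Optional[int] = Field(default=None, ge=1)
    master_seed: int = 20210316
    n_jobs: int = 1
    checkpoint_dir: Optional[str] = None


class FitBlock(_Strict):
    gtol: float = Field(default=1e-4, gt=0)
    ftol: float = Field(default=1e-11, gt=0)
    maxiter: int = Field(default=2000, ge=1)
    restarts: int = Field(default=3, ge=0)
    init_sd: float = Field(default=0.1, gt=0)
    warm_start_ladder: bool = True


class RunConfig(_Strict):
    """Validated top-level configuration."""

    design: DesignBlock = Field(default_factory=DesignBlock)
    scenario: ScenarioBlock = Field(default_factory=ScenarioBlock)
    study: StudyBlock = Field(default_factory=StudyBlock)
    fit: FitBlock = Field(default_factory=FitBlock)
    verbosity: Literal["quiet", "info", "debug"] = "info"

    def build_design(self) -> StudyDesign:
        d = self.design
        offsets = None
        if d.offset_file is not None:
            offsets = np.loadtxt(d.offset_file, ndmin=1)
        return build_design(
            d.n_clusters,
            d.n_periods,
            d.baseline_periods,
            d.clusters_per_step,
            d.period_length_months,
            offsets=offsets,
            offset_seed=d.offset_seed,
        )

    def fit_options(self) -> FitOptions:
        f = self.fit
        return FitOptions(
            gtol=f.gtol,
            ftol=f.ftol,
            maxiter=f.maxiter,
            restarts=f.restarts,
            init_sd=f.init_sd,
            warm_start_ladder=f.warm_start_ladder,
        )

    def study_config(self) -> StudyConfig:
        s = self.study
        return StudyConfig(
            scenarios=tuple(s.scenarios),
            models=tuple(s.models),
            replicates=s.replicates,
            null_replicates=s.null_replicates,
            master_seed=s.master_seed,
            alpha=self.scenario.alpha,
            sigma_b0=self.scenario.sigma_b0,
            theta=self.scenario.theta,
            fit_options=self.fit_options(),
            n_jobs=s.n_jobs,
            checkpoint_dir=s.checkpoint_dir,
        )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; ``None`` or empty file gives defaults."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        issues = "; ".join(
            f"{'.'.join(str(x) for x in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ConfigError(f"invalid configuration: {issues}") from exc
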