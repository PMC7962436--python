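"""Factorial simulation study: scenarios x models x replicates.

Each replicate re-randomizes the rollout order, draws one dataset under the
scenario's generative model, fits the requested analysis model, and records
the estimate, its SE, whether the 95% CI covers the true effect, and whether
the test of "no intervention effect" rejects at the 5% level.  Type 1 error
comes from a parallel sweep generated under the null (theta = 0 substituted
everywhere, including the early-adoption effect support) on a disjoint seed
substream.

Per-cell summaries report

    %bias = 100 (mean theta_hat - theta) / theta,
    SD    = empirical SD of theta_hat,
    SE    = mean of the estimated standard errors,
    cov   = fraction of 95% CIs containing theta,
    pwr   = rejection fraction under the alternative,
    alpha = rejection fraction under the null,

over converged replicates, with the convergence accounting attached.

Seeds are derived per (scenario, arm, replicate) from the master seed via
``numpy.random.SeedSequence`` spawn keys, so results are independent of
execution order and degree of parallelism, and every cell shares the same
stream of datasets regardless of which models are requested.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .design import StudyDesign, assign_rollout
from .glmm import FitOptions, fit_glmm
from .simulate import SCENARIO_IDS, ScenarioParams, generate_dataset

__all__ = [
    "StudyConfig",
    "MetricRow",
    "ReplicateResult",
    "run_replicate",
    "percent_bias",
    "summarize_cell",
    "run_study",
    "StudyConfigError",
]

logger = logging.getLogger(__name__)

_SCEN_CODE = {sid: code for code, sid in enumerate(SCENARIO_IDS)}
ALT, NULL = 0, 1


class StudyConfigError(ValueError):
    """Invalid study configuration."""


@dataclasses.dataclass(frozen=True)
class StudyConfig:
    """Specification of one factorial sweep."""

    scenarios: tuple[str, ...]
    models: tuple[int, ...]
    replicates: int = 500
    null_replicates: int | None = None  # defaults to `replicates`
    master_seed: int = 20210316
    alpha: float = -10.0
    sigma_b0: float = 0.30
    theta: float = float(np.log(0.6))
    fit_options: FitOptions = dataclasses.field(default_factory=FitOptions)
    n_jobs: int = 1
    checkpoint_dir: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "scenarios", tuple(str(s) for s in self.scenarios))
        object.__setattr__(self, "models", tuple(int(m) for m in self.models))
        if not self.scenarios or not self.models:
            raise StudyConfigError("scenarios and models must be nonempty")
        bad = [s for s in self.scenarios if s not in SCENARIO_IDS]
        if bad:
            raise StudyConfigError(
                f"unknown scenario(s) {bad}; valid: {', '.join(SCENARIO_IDS)}"
            )
        if any(m not in range(1, 11) for m in self.models):
            raise StudyConfigError("models must be in 1..10")
        if self.replicates < 1:
            raise StudyConfigError("replicates must be >= 1")

    @property
    def n_null(self) -> int:
        return self.null_replicates if self.null_replicates is not None else self.replicates


@dataclasses.dataclass(frozen=True)
class ReplicateResult:
    theta_hat: float
    se: float
    covered: bool
    rejected: bool
    converged: bool


@dataclasses.dataclass(frozen=True)
class MetricRow:
    """One cell of the results table (scenario x model)."""

    scenario: str
    model: int
    pct_bias: float
    sd_emp: float
    se_mean: float
    coverage: float
    power: float
    type1: float
    n_converged: int
    n_total: int
    n_converged_null: int
    n_total_null: int


def replicate_seed(master_seed: int, scenario: str, arm: int, rep: int):
    """SeedSequence for one replicate, independent of execution order."""
    return np.random.SeedSequence(
        entropy=master_seed, spawn_key=(_SCEN_CODE[scenario], arm, rep)
    )


def run_replicate(
    scenario: str,
    model: int,
    design: StudyDesign,
    params: ScenarioParams,
    rep_seed: np.random.SeedSequence,
    options: FitOptions | None = None,
) -> ReplicateResult:
    """Simulate one dataset (fresh rollout randomization) and fit one model.

    Coverage refers to the generative ``theta`` of ``params``; rejection to
    the Wald test of zero intervention effect at the 5% level.  Fit failures
    surface as ``converged=False``, never as exceptions.
    """
    rng = np.random.default_rng(rep_seed)
    roll_rng, data_rng = rng.spawn(2)
    randomized = assign_rollout(design, roll_rng)
    dataset = generate_dataset(randomized, params, data_rng)
    fit = fit_glmm(dataset, model, options)
    if not fit.converged or not np.isfinite(fit.se_theta):
        return ReplicateResult(fit.theta_hat, fit.se_theta, False, False, False)
    lo, hi = fit.ci95
    covered = bool(lo <= params.theta <= hi)
    rejected = bool(abs(fit.theta_hat / fit.se_theta) > 1.959963984540054)
    return ReplicateResult(fit.theta_hat, fit.se_theta, covered, rejected, True)


def percent_bias(theta_hats: np.ndarray, theta: float) -> float:
    """``100 (mean(theta_hat) - theta) / theta``; undefined at theta = 0.

    With a protective effect (``theta < 0``), estimates attenuated toward
    zero give negative percent bias.
    """
    theta_hats = np.asarray(theta_hats, dtype=float)
    if theta_hats.size == 0:
        raise ValueError("need at least one estimate")
    if theta == 0:
        raise ValueError(
            "percent bias undefined under the null; report absolute bias instead"
        )
    return float(100.0 * (theta_hats.mean() - theta) / theta)


def summarize_cell(
    alt: list[ReplicateResult],
    null: list[ReplicateResult],
    theta: float,
    scenario: str = "",
    model: int = 0,
) -> MetricRow:
    """Collapse replicate results into one row of the metrics table."""
    ok = [r for r in alt if r.converged]
    ok_null = [r for r in null if r.converged]
    if not ok:
        raise ValueError(f"no converged replicates for scenario {scenario} model {model}")
    th = np.array([r.theta_hat for r in ok])
    se = np.array([r.se for r in ok])
    return MetricRow(
        scenario=scenario,
        model=model,
        pct_bias=percent_bias(th, theta),
        sd_emp=float(th.std(ddof=1)) if len(th) > 1 else float("nan"),
        se_mean=float(se.mean()),
        coverage=float(np.mean([r.covered for r in ok])),
        power=float(np.mean([r.rejected for r in ok])),
        type1=float(np.mean([r.rejected for r in ok_null])) if ok_null else float("nan"),
        n_converged=len(ok),
        n_total=len(alt),
        n_converged_null=len(ok_null),
        n_total_null=len(null),
    )


def run_cell(
    config: StudyConfig,
    design: StudyDesign,
    scenario: str,
    model: int,
    with_null: bool = True,
) -> MetricRow:
    """All replicates of one scenario x model cell (alt + null sweeps)."""
    ckpt = _checkpoint_path(config, scenario, model)
    if ckpt is not None and ckpt.exists():
        logger.info("cell s=%s m=%d: loading checkpoint %s", scenario, model, ckpt)
        return _row_from_frame(pd.read_csv(ckpt), config.theta, scenario, model)

    params = ScenarioParams(
        scenario_id=scenario,
        alpha=config.alpha,
        sigma_b0=config.sigma_b0,
        theta=config.theta,
    )
    t0 = time.perf_counter()
    jobs = [(ALT, rep, params) for rep in range(config.replicates)]
    if with_null:
        jobs += [(NULL, rep, params.null()) for rep in range(config.n_null)]
    results = Parallel(n_jobs=config.n_jobs)(
        delayed(run_replicate)(
            scenario,
            model,
            design,
            p,
            replicate_seed(config.master_seed, scenario, arm, rep),
            config.fit_options,
        )
        for arm, rep, p in jobs
    )
    alt = [r for (arm, _, _), r in zip(jobs, results) if arm == ALT]
    null = [r for (arm, _, _), r in zip(jobs, results) if arm == NULL]
    logger.info(
        "cell s=%s m=%d: %d fits in %.1fs",
        scenario,
        model,
        len(results),
        time.perf_counter() - t0,
    )
    if ckpt is not None:
        frame = pd.DataFrame(
            [{"arm": arm, "rep": rep, **dataclasses.asdict(r)}
             for (arm, rep, _), r in zip(jobs, results)]
        )
        ckpt.parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(ckpt, index=False)
    return summarize_cell(alt, null, config.theta, scenario, model)


def _checkpoint_path(config: StudyConfig, scenario: str, model: int) -> Path | None:
    if config.checkpoint_dir is None:
        return None
    return Path(config.checkpoint_dir) / f"cell_s{scenario}_m{model}.csv"


def _row_from_frame(frame: pd.DataFrame, theta: float, scenario: str, model: int) -> MetricRow:
    def side(arm):
        return [
            ReplicateResult(
                r.theta_hat, r.se, bool(r.covered), bool(r.rejected), bool(r.converged)
            )
            for r in frame[frame.arm == arm].itertuples()
        ]

    return summarize_cell(side(ALT), side(NULL), theta, scenario, model)


def run_study(config: StudyConfig, design: StudyDesign | None = None) -> pd.DataFrame:
    """Full factorial sweep; deterministic given the master seed.

    Returns a table with one row per scenario x model cell, mirroring the
    metric suite layout (columns scenario, model, pct_bias, sd, se,
    coverage, power, type1, n_converged, n_total).
    """
    if design is None:
        from .design import build_design

        design = build_design(18, 13, 2, 2, 3.0)
    rows = []
    for scenario in config.scenarios:
        for model in config.models:
            row = run_cell(config, design, scenario, model)
            rows.append(row)
            logger.info(
                "s=%s m=%d: bias=%.1f%% sd=%.2f se=%.2f cov=%.2f pwr=%.2f a=%.2f "
                "(%d/%d converged)",
                scenario, model, row.pct_bias, row.sd_emp, row.se_mean,
                row.coverage, row.power, row.type1, row.n_converged, row.n_total,
            )
    frame = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    return frame.rename(columns={"sd_emp": "sd", "se_mean": "se"})
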