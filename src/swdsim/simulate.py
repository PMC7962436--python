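"""Scenario generators for cluster-period overdose-count data.

Outcomes are aggregate event counts ``Y_ij`` (deaths per cluster-period)
drawn from a Poisson model on the log-rate scale with a population offset:

    log E[Y_ij] = log O_i + alpha + beta_ij + theta_ij * 1{X_ij = 0}
                  + theta * X_ij + b_i,

where ``b_i ~ N(0, sigma_b0^2)`` is a cluster random intercept, ``beta_ij``
is the (latent) effect of external confounding factors, and ``theta_ij`` is
the (latent) effect of premature intervention adoption in control
cluster-periods.  Six scenario families switch these processes on and off:

========  ===========================================================
id        processes active
========  ===========================================================
``1``     none (standard)
``2.1``   confounding, beneficial  (``beta_ij ~ unif[-1, 0]``)
``2.2``   confounding, harmful     (``beta_ij ~ unif[0, 1]``)
``3``     early adoption           (``theta_ij ~ unif[theta, 0]``)
``4.1``   confounding (+) and early adoption
``4.2``   confounding (-) and early adoption
========  ===========================================================

Confounding exposure is absorbing: at each period every not-yet-exposed
cluster is exposed with probability ``1/N``.  Early adoption hits each
still-control, not-yet-adopting cluster with probability
``(N - N*_j + 1) / (2N)`` where ``N*_j`` is the size of the at-risk pool, so
the per-cluster hazard grows as the pool shrinks.  Both latent effects are
redrawn independently every period after onset.

The scenario-4 mechanism doubles as the generator for time-varying effect
modification, with ``beta_ij`` read as the effect of external factors in
intervention communities and ``theta_ij`` as the control-vs-intervention
difference in those effects.

Randomness is organized as independent child streams (intercepts,
confounding, adoption, period effects, counts) spawned from one generator,
so switching a process off never perturbs the draws of the others; e.g.
scenario 3 with ``theta = 0`` reproduces scenario 1 exactly, seed for seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .design import StudyDesign

__all__ = [
    "SCENARIO_IDS",
    "ScenarioParams",
    "ExposureHistory",
    "SimulatedDataset",
    "adoption_probability",
    "draw_confounding_exposure",
    "draw_early_adoption",
    "draw_period_effects",
    "generate_dataset",
    "dataset_to_frame",
    "truth_to_frame",
]

SCENARIO_IDS = ("1", "2.1", "2.2", "3", "4.1", "4.2")

#: default generative parameters: log-rate intercept, random-intercept SD and
#: intervention log rate ratio of the motivating 18-county design
DEFAULT_ALPHA = -10.0
DEFAULT_SIGMA_B0 = 0.30
DEFAULT_THETA = float(np.log(0.6))


class ScenarioError(ValueError):
    """Unknown or inconsistent scenario configuration."""


@dataclasses.dataclass(frozen=True)
class ScenarioParams:
    """Generative parameters for one scenario family.

    ``theta <= 0`` is required: the early-adoption perturbation is drawn from
    ``unif[theta, 0]``, a degenerate point mass at 0 when ``theta = 0`` (the
    null-generation convention for Type 1 error sweeps).
    """

    scenario_id: str = "1"
    alpha: float = DEFAULT_ALPHA
    sigma_b0: float = DEFAULT_SIGMA_B0
    theta: float = DEFAULT_THETA

    def __post_init__(self) -> None:
        sid = str(self.scenario_id)
        object.__setattr__(self, "scenario_id", sid)
        if sid not in SCENARIO_IDS:
            raise ScenarioError(
                f"unknown scenario {sid!r}; valid ids: {', '.join(SCENARIO_IDS)}"
            )
        if self.sigma_b0 < 0:
            raise ScenarioError("sigma_b0 must be nonnegative")
        if self.theta > 0:
            raise ScenarioError("theta must be <= 0 (unif[theta, 0] support)")

    @property
    def has_confounding(self) -> bool:
        return self.scenario_id in ("2.1", "2.2", "4.1", "4.2")

    @property
    def has_adoption(self) -> bool:
        return self.scenario_id in ("3", "4.1", "4.2")

    @property
    def confounding_sign(self) -> int:
        """+1: beneficial confounding (beta in [-1,0]); -1: harmful ([0,1])."""
        return -1 if self.scenario_id in ("2.2", "4.2") else +1

    def null(self) -> "ScenarioParams":
        """The same scenario with the intervention effect removed."""
        return dataclasses.replace(self, theta=0.0)


@dataclasses.dataclass(frozen=True)
class ExposureHistory:
    """Latent truth of the external-factor processes for one dataset.

    ``confound_time`` / ``adopt_time`` hold the 1-based onset periods
    ``t'_i`` / ``t*_i``; a value of ``n_periods + 1`` means the event never
    occurred.  ``beta_effects`` and ``adopt_effects`` are the realized
    ``beta_ij`` and ``theta_ij`` matrices, zero outside their windows.
    """

    confound_time: np.ndarray
    adopt_time: np.ndarray
    beta_effects: np.ndarray
    adopt_effects: np.ndarray


@dataclasses.dataclass(frozen=True)
class SimulatedDataset:
    """One simulated trial: counts plus the full latent truth."""

    design: StudyDesign
    params: ScenarioParams
    counts: np.ndarray
    random_intercepts: np.ndarray
    truth: ExposureHistory


def adoption_probability(n_clusters: int, pool_size: int) -> float:
    """Per-cluster early-adoption probability ``(N - N* + 1) / (2N)``.

    With a full pool (``N* = N``) this is ``1/(2N)``; it rises to one half
    when a single control cluster remains at risk.
    """
    return (n_clusters - pool_size + 1) / (2.0 * n_clusters)


def draw_confounding_exposure(
    design: StudyDesign, rng: np.random.Generator
) -> np.ndarray:
    """Absorbing exposure times ``t'_i`` of the confounding process.

    Sequentially over periods ``j = 1..n``: among the ``N'_j`` clusters with
    no prior exposure, ``Binomial(N'_j, 1/N)`` are newly exposed, chosen
    uniformly without replacement.  Returns 1-based onset periods with
    ``n_periods + 1`` for clusters never exposed.
    """
    N, n = design.n_clusters, design.n_periods
    t_prime = np.full(N, n + 1, dtype=int)
    for j in range(1, n + 1):
        pool = np.flatnonzero(t_prime > n)
        if pool.size == 0:
            continue
        k = rng.binomial(pool.size, 1.0 / N)
        if k:
            t_prime[rng.choice(pool, size=k, replace=False)] = j
    return t_prime


def draw_early_adoption(design: StudyDesign, rng: np.random.Generator) -> np.ndarray:
    """Early-adoption times ``t*_i`` among still-control clusters.

    Sequentially over periods: the at-risk pool ``A_j`` holds clusters with
    ``X_ij = 0`` that have not yet adopted; ``Binomial(|A_j|, (N-|A_j|+1)/(2N))``
    of them adopt, chosen uniformly.  Clusters already on intervention are
    never at risk, so adoption cannot start at or after ``t^I_i``.
    """
    N, n = design.n_clusters, design.n_periods
    X = design.intervention_matrix
    t_star = np.full(N, n + 1, dtype=int)
    for j in range(1, n + 1):
        pool = np.flatnonzero((t_star > n) & (X[:, j - 1] == 0))
        if pool.size == 0:
            continue
        k = rng.binomial(pool.size, adoption_probability(N, pool.size))
        if k:
            t_star[rng.choice(pool, size=k, replace=False)] = j
    return t_star


def draw_period_effects(
    design: StudyDesign,
    confound_time: np.ndarray,
    adopt_time: np.ndarray,
    params: ScenarioParams,
    rng: np.random.Generator,
) -> ExposureHistory:
    """Realize the per-period latent effects ``beta_ij`` and ``theta_ij``.

    Both are redrawn independently at every period inside their windows:
    ``beta_ij ~ unif[-1, 0]`` (sign +) or ``unif[0, 1]`` (sign -) for
    ``j >= t'_i``; ``theta_ij ~ unif[theta, 0]`` for
    ``t*_i <= j <= t^I_i - 1``; both zero elsewhere.
    """
    N, n = design.n_clusters, design.n_periods
    periods = np.arange(1, n + 1)
    beta = np.zeros((N, n))
    theta_ij = np.zeros((N, n))
    if params.has_confounding:
        exposed = periods[None, :] >= confound_time[:, None]
        u = rng.uniform(size=(N, n))
        beta = np.where(exposed, params.confounding_sign * -u, 0.0)
    if params.has_adoption:
        window = (periods[None, :] >= adopt_time[:, None]) & (
            periods[None, :] <= design.rollout_period[:, None] - 1
        )
        u = rng.uniform(size=(N, n))
        theta_ij = np.where(window, params.theta * u, 0.0)
    return ExposureHistory(
        confound_time=confound_time,
        adopt_time=adopt_time,
        beta_effects=beta,
        adopt_effects=theta_ij,
    )


def generate_dataset(
    design: StudyDesign, params: ScenarioParams, rng: np.random.Generator
) -> SimulatedDataset:
    """Draw one complete dataset under the scenario's generative model.

    Draw order (each from its own child stream): random intercepts,
    confounding exposure, early adoption, period effects, counts.
    """
    N, n = design.n_clusters, design.n_periods
    never = np.full(N, n + 1, dtype=int)
    b_rng, conf_rng, adopt_rng, eff_rng, count_rng = rng.spawn(5)

    b = b_rng.normal(0.0, params.sigma_b0, size=N)
    t_prime = (
        draw_confounding_exposure(design, conf_rng)
        if params.has_confounding
        else never.copy()
    )
    t_star = (
        draw_early_adoption(design, adopt_rng) if params.has_adoption else never.copy()
    )
    truth = draw_period_effects(design, t_prime, t_star, params, eff_rng)

    X = design.intervention_matrix
    eta = (
        params.alpha
        + truth.beta_effects
        + truth.adopt_effects * (1 - X)
        + params.theta * X
        + b[:, None]
    )
    counts = count_rng.poisson(design.offsets[:, None] * np.exp(eta))
    return SimulatedDataset(
        design=design,
        params=params,
        counts=counts,
        random_intercepts=b,
        truth=truth,
    )


def dataset_to_frame(data: SimulatedDataset) -> pd.DataFrame:
    """Long-format outcome table: cluster_id, period, X, t_months, offset, Y."""
    from .design import design_to_frame

    frame = design_to_frame(data.design)
    frame["Y"] = data.counts.ravel()
    return frame


def truth_to_frame(data: SimulatedDataset) -> pd.DataFrame:
    """Latent-truth sidecar: onset times and per-period beta/theta effects."""
    N, n = data.design.n_clusters, data.design.n_periods
    return pd.DataFrame(
        {
            "cluster_id": np.repeat(np.arange(1, N + 1), n),
            "period": np.tile(np.arange(1, n + 1), N),
            "t_prime": np.repeat(data.truth.confound_time, n),
            "t_star": np.repeat(data.truth.adopt_time, n),
            "beta_ij": data.truth.beta_effects.ravel(),
            "theta_ij": data.truth.adopt_effects.ravel(),
            "b_i": np.repeat(data.random_intercepts, n),
        }
    )
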