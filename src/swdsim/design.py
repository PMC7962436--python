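"""Stepped-wedge trial layouts.

A stepped-wedge design (SWD) is a uni-directional crossover cluster trial:
every cluster starts in the control condition, crosses over to the
intervention at a (randomized) rollout period, and stays on intervention for
the remainder of the study.  The layout is described by the number of
clusters ``N``, the number of equally long observation periods ``n``, a
baseline phase during which no cluster is treated, a rollout phase in which
``clusters_per_step`` clusters cross over at the start of each period, and a
follow-up phase in which every cluster is treated.

Indices are 1-based at every public interface (cluster ids ``1..N``, periods
``1..n``), matching the conventional presentation of such designs.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "DesignError",
    "ScheduleError",
    "build_design",
    "assign_rollout",
    "intervention_indicator",
    "design_to_frame",
    "generate_offsets",
    "DEFAULT_OFFSET_RANGE",
    "DEFAULT_OFFSET_SEED",
]

#: Range (persons) of the log-uniform county-population generator used when no
#: offsets are supplied.  With a log-rate intercept of -10 this yields
#: baseline expectations of roughly 2.3--22.7 events per cluster-period.
DEFAULT_OFFSET_RANGE = (5.0e4, 5.0e5)

#: Fixed seed for the default offset generator, so that the default design is
#: fully reproducible without any configuration.
DEFAULT_OFFSET_SEED = 97531


class DesignError(ValueError):
    """Inconsistent stepped-wedge layout (dimensions or invariants)."""


class ScheduleError(DesignError):
    """Rollout schedule cannot place every cluster before the study ends."""


def generate_offsets(n_clusters: int, seed: int = DEFAULT_OFFSET_SEED) -> np.ndarray:
    """Draw cluster population sizes log-uniformly on ``DEFAULT_OFFSET_RANGE``."""
    rng = np.random.default_rng(seed)
    lo, hi = np.log(DEFAULT_OFFSET_RANGE)
    return np.exp(rng.uniform(lo, hi, size=n_clusters))


@dataclasses.dataclass(frozen=True)
class StudyDesign:
    """A complete stepped-wedge layout.

    Attributes
    ----------
    n_clusters, n_periods
        ``N`` clusters observed over ``n`` common periods.
    baseline_periods
        Number of leading all-control periods.
    clusters_per_step
        Clusters crossing over at the start of each rollout period.
    period_length_months
        Length of one observation period, in months.
    rollout_period
        1-based period at which each cluster starts the intervention
        (``t^I_i``), shape ``(N,)``.
    offsets
        Population size ``O_i`` of each cluster (persons), shape ``(N,)``.
    """

    n_clusters: int
    n_periods: int
    baseline_periods: int
    clusters_per_step: int
    period_length_months: float
    rollout_period: np.ndarray
    offsets: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "rollout_period", np.asarray(self.rollout_period, dtype=int)
        )
        object.__setattr__(self, "offsets", np.asarray(self.offsets, dtype=float))
        self._validate()

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        N, n = self.n_clusters, self.n_periods
        if N < 1 or n < 1:
            raise DesignError("n_clusters and n_periods must be positive")
        if self.clusters_per_step < 1:
            raise DesignError("clusters_per_step must be positive")
        if self.baseline_periods < 0:
            raise DesignError("baseline_periods must be nonnegative")
        if not self.period_length_months > 0:
            raise DesignError("period_length_months must be positive")
        if self.baseline_periods + self.n_steps > n:
            raise ScheduleError(
                f"rollout needs {self.n_steps} steps after {self.baseline_periods} "
                f"baseline periods but only {n} periods are available"
            )
        if self.rollout_period.shape != (N,):
            raise DesignError(
                f"rollout_period has shape {self.rollout_period.shape}, expected ({N},)"
            )
        if self.offsets.shape != (N,):
            raise DesignError(
                f"offsets has shape {self.offsets.shape}, expected ({N},)"
            )
        if not np.all(self.offsets > 0):
            raise DesignError("offsets must be strictly positive")
        lo, hi = self.baseline_periods + 1, self.baseline_periods + self.n_steps
        if self.rollout_period.min() < lo or self.rollout_period.max() > hi:
            raise DesignError(
                f"rollout periods must lie in [{lo}, {hi}] for this schedule"
            )
        # each rollout step carries clusters_per_step clusters (the final step
        # absorbs the remainder when N is not a multiple of the step size)
        counts = np.bincount(self.rollout_period, minlength=hi + 1)[lo : hi + 1]
        expected = np.full(self.n_steps, self.clusters_per_step)
        expected[-1] = N - self.clusters_per_step * (self.n_steps - 1)
        if not np.array_equal(counts, expected):
            raise DesignError(
                f"clusters per rollout step {counts.tolist()} does not match the "
                f"schedule {expected.tolist()}"
            )

    # ------------------------------------------------------------------
    @property
    def n_steps(self) -> int:
        """Number of rollout periods."""
        return math.ceil(self.n_clusters / self.clusters_per_step)

    @property
    def n_tau(self) -> int:
        """Number of periods before the all-intervention follow-up phase."""
        return self.baseline_periods + self.n_steps

    @property
    def time_covariate(self) -> np.ndarray:
        """Months from study start to the beginning of each period, ``t_1 = 0``."""
        return self.period_length_months * np.arange(self.n_periods, dtype=float)

    @property
    def intervention_matrix(self) -> np.ndarray:
        """0/1 matrix ``X_ij`` of shape ``(N, n)``: 1 iff period j >= rollout."""
        periods = np.arange(1, self.n_periods + 1)
        return (periods[None, :] >= self.rollout_period[:, None]).astype(np.int8)


def build_design(
    n_clusters: int,
    n_periods: int,
    baseline_periods: int,
    clusters_per_step: int,
    period_length_months: float,
    offsets: np.ndarray | None = None,
    offset_seed: int = DEFAULT_OFFSET_SEED,
) -> StudyDesign:
    """Construct a stepped-wedge layout with a deterministic rollout order.

    Clusters ``1, ..., clusters_per_step`` cross over at the first rollout
    period, the next batch at the second, and so on; use
    :func:`assign_rollout` to randomize the order.  The default study layout
    ``build_design(18, 13, 2, 2, 3)`` has nine rollout steps at periods 3-11
    and an all-intervention follow-up phase in periods 12-13.
    """
    n_steps = math.ceil(n_clusters / clusters_per_step)
    if baseline_periods + n_steps > n_periods:
        raise ScheduleError(
            f"{n_clusters} clusters at {clusters_per_step}/step need "
            f"{n_steps} rollout periods after {baseline_periods} baseline "
            f"periods; only {n_periods} periods available"
        )
    if offsets is None:
        offsets = generate_offsets(n_clusters, seed=offset_seed)
    else:
        offsets = np.asarray(offsets, dtype=float)
        if offsets.shape != (n_clusters,):
            raise DesignError(
                f"offsets has shape {offsets.shape}, expected ({n_clusters},)"
            )
    slots = _schedule_slots(n_clusters, baseline_periods, clusters_per_step, n_steps)
    return StudyDesign(
        n_clusters=n_clusters,
        n_periods=n_periods,
        baseline_periods=baseline_periods,
        clusters_per_step=clusters_per_step,
        period_length_months=period_length_months,
        rollout_period=slots,
        offsets=offsets,
    )


def _schedule_slots(
    n_clusters: int, baseline_periods: int, clusters_per_step: int, n_steps: int
) -> np.ndarray:
    slots = np.repeat(
        baseline_periods + 1 + np.arange(n_steps, dtype=int), clusters_per_step
    )
    return slots[:n_clusters]


def assign_rollout(design: StudyDesign, rng: np.random.Generator) -> StudyDesign:
    """Randomize the rollout order by a uniform permutation of clusters.

    Returns a new design in which the schedule slots (the same multiset of
    rollout periods as in ``design``) are assigned to clusters uniformly at
    random.  Deterministic given the generator state: an identity permutation
    reproduces the deterministic :func:`build_design` order.
    """
    slots = _schedule_slots(
        design.n_clusters,
        design.baseline_periods,
        design.clusters_per_step,
        design.n_steps,
    )
    perm = np.asarray(rng.permutation(design.n_clusters))
    rollout = np.empty(design.n_clusters, dtype=int)
    rollout[perm] = slots
    return dataclasses.replace(design, rollout_period=rollout)


def intervention_indicator(design: StudyDesign, cluster: int, period: int) -> int:
    """``X_ij``: 1 iff cluster ``i`` (1-based) is on intervention in period ``j``."""
    if not 1 <= cluster <= design.n_clusters:
        raise IndexError(f"cluster {cluster} not in 1..{design.n_clusters}")
    if not 1 <= period <= design.n_periods:
        raise IndexError(f"period {period} not in 1..{design.n_periods}")
    return int(period >= design.rollout_period[cluster - 1])


def design_to_frame(design: StudyDesign) -> pd.DataFrame:
    """Long-format table with one row per cluster-period.

    Columns: ``cluster_id`` (1-based), ``period`` (1-based), ``X``,
    ``t_months``, ``offset``.
    """
    N, n = design.n_clusters, design.n_periods
    cluster = np.repeat(np.arange(1, N + 1), n)
    period = np.tile(np.arange(1, n + 1), N)
    return pd.DataFrame(
        {
            "cluster_id": cluster,
            "period": period,
            "X": design.intervention_matrix.ravel(),
            "t_months": np.tile(design.time_covariate, N),
            "offset": np.repeat(design.offsets, n),
        }
    )
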