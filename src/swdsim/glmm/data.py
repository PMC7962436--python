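"""Adapters turning datasets into the arrays the fitting engine consumes.

Fitting accepts either a :class:`~swdsim.simulate.SimulatedDataset` or a
long-format table (``cluster_id, period, X, t_months, offset, Y``), e.g. one
read from CSV.  Both are normalized to a :class:`TrialData`, which exposes
the same design attributes as :class:`~swdsim.design.StudyDesign` so the
model builders work on either.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = ["TrialData", "as_trial", "DataError"]

REQUIRED_COLUMNS = ("cluster_id", "period", "X", "t_months", "offset", "Y")


class DataError(ValueError):
    """Malformed input table."""


@dataclasses.dataclass(frozen=True)
class TrialData:
    """Counts plus the design quantities needed to build model matrices."""

    y: np.ndarray  # (N, n) counts
    offsets: np.ndarray  # (N,)
    intervention_matrix: np.ndarray  # (N, n) 0/1
    time_covariate: np.ndarray  # (n,) months
    rollout_period: np.ndarray  # (N,) 1-based; n+1 if never treated
    cluster_ids: np.ndarray  # (N,) original labels

    @property
    def n_clusters(self) -> int:
        return self.y.shape[0]

    @property
    def n_periods(self) -> int:
        return self.y.shape[1]


def _from_frame(frame: pd.DataFrame) -> TrialData:
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"missing required column(s): {', '.join(missing)}")
    df = frame.loc[:, list(REQUIRED_COLUMNS)].copy()
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise DataError(f"missing values in column(s): {', '.join(bad)}")
    y = df["Y"].to_numpy()
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        rows = np.flatnonzero((y < 0) | ~np.isclose(y, np.round(y)))[:5]
        raise DataError(f"Y must be nonnegative integers (rows {rows.tolist()})")
    if not set(np.unique(df["X"])) <= {0, 1}:
        raise DataError("X must be 0/1")
    if np.any(df["offset"].to_numpy() <= 0):
        raise DataError("offset must be strictly positive")

    clusters = np.unique(df["cluster_id"].to_numpy())
    periods = np.unique(df["period"].to_numpy())
    n, N = len(periods), len(clusters)
    if len(df) != N * n:
        raise DataError(
            f"expected a complete {N} x {n} cluster-period grid, got {len(df)} rows"
        )
    wide = df.set_index(["cluster_id", "period"]).sort_index()
    if wide.index.has_duplicates:
        raise DataError("duplicate (cluster_id, period) rows")

    def grid(col, dtype=float):
        return wide[col].to_numpy(dtype=dtype).reshape(N, n)

    Y = grid("Y")
    X = grid("X", dtype=int)
    t = grid("t_months")[0]
    if not np.all(grid("t_months") == t[None, :]):
        raise DataError("t_months must be common to all clusters within a period")
    if np.any(np.diff(t) <= 0):
        raise DataError("t_months must be strictly increasing over periods")
    off = grid("offset")[:, 0]
    if not np.all(grid("offset") == off[:, None]):
        raise DataError("offset must be constant within a cluster")
    if np.any(np.diff(X, axis=1) < 0):
        raise DataError("X must be non-decreasing over periods within a cluster")
    treated = X == 1
    rollout = np.where(treated.any(axis=1), treated.argmax(axis=1) + 1, n + 1)
    return TrialData(
        y=Y,
        offsets=off,
        intervention_matrix=X.astype(np.int8),
        time_covariate=t,
        rollout_period=rollout.astype(int),
        cluster_ids=clusters,
    )


def as_trial(data) -> TrialData:
    """Normalize a dataset, long-format table or TrialData to arrays."""
    if isinstance(data, TrialData):
        return data
    if isinstance(data, pd.DataFrame):
        return _from_frame(data)
    # SimulatedDataset (duck-typed: carries .design and .counts)
    design = getattr(data, "design", None)
    counts = getattr(data, "counts", None)
    if design is not None and counts is not None:
        return TrialData(
            y=np.asarray(counts, dtype=float),
            offsets=design.offsets,
            intervention_matrix=design.intervention_matrix,
            time_covariate=design.time_covariate,
            rollout_period=design.rollout_period,
            cluster_ids=np.arange(1, design.n_clusters + 1),
        )
    raise TypeError(f"cannot interpret {type(data).__name__} as trial data")
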