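"""The ten Poisson mixed-model structures for stepped-wedge analysis.

All models share the fixed-effect core ``alpha + theta * X_ij`` plus a main
effect of calendar time (discrete period dummies or a linear trend in
``t_j``); the group-by-time models (5-10) add a fixed control-group linear
trend ``gamma * t_j * 1{X_ij = 0}``.  They differ in the random-effect
covariance placed on the cluster-level time effects:

=====  =========  ============  ==========================================
model  fixed time control trend random structure
=====  =========  ============  ==========================================
1      discrete   --            cluster random intercept ``b_0i``
2      discrete   --            i.i.d. cluster-period effects ``b_ij``
3      discrete   --            unstructured ``Sigma_b*`` over periods
4      discrete   --            correlated random intercept + slope in t
5      discrete   yes           model 2 + i.i.d. control effects ``c_ij``
6      discrete   yes           model 3 + unstructured control block
7      discrete   yes           model 4 + control intercept/slope pair
8      linear     yes           random part of model 5
9      linear     yes           random part of model 6
10     linear     yes           random part of model 7
=====  =========  ============  ==========================================

Control-block effects (``c`` terms) load only on cluster-periods still in
the control condition, i.e. periods ``1 .. t^I_i - 1``; their covariance for
cluster ``i`` is the leading principal submatrix of the full control-block
covariance (the block for a cluster rolled out in the final rollout period).

Discrete time effects are reference-coded with ``beta_1 = 0`` so the
intercept stays identifiable.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .covariance import Composite, CovarianceStructure, Isotropic, Unstructured

__all__ = [
    "ModelSpec",
    "model_spec",
    "MODEL_INDICES",
    "build_fixed_design",
    "build_random_design",
    "covariance_structure",
    "RankError",
]

MODEL_INDICES = tuple(range(1, 11))

_RANDOM_STRUCTURES = (
    "intercept",
    "cluster_period_iid",
    "cluster_unstructured",
    "intercept_slope",
    "group_iid",
    "group_unstructured",
    "group_slope",
)


class RankError(ValueError):
    """Fixed-effect design matrix is rank deficient."""


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    index: int
    fixed_time: str  # "discrete" | "linear"
    control_trend: bool
    random_structure: str

    def __post_init__(self):
        if self.fixed_time not in ("discrete", "linear"):
            raise ValueError(f"unknown fixed_time {self.fixed_time!r}")
        if self.random_structure not in _RANDOM_STRUCTURES:
            raise ValueError(f"unknown random_structure {self.random_structure!r}")


_MODELS = {
    1: ModelSpec(1, "discrete", False, "intercept"),
    2: ModelSpec(2, "discrete", False, "cluster_period_iid"),
    3: ModelSpec(3, "discrete", False, "cluster_unstructured"),
    4: ModelSpec(4, "discrete", False, "intercept_slope"),
    5: ModelSpec(5, "discrete", True, "group_iid"),
    6: ModelSpec(6, "discrete", True, "group_unstructured"),
    7: ModelSpec(7, "discrete", True, "group_slope"),
    8: ModelSpec(8, "linear", True, "group_iid"),
    9: ModelSpec(9, "linear", True, "group_unstructured"),
    10: ModelSpec(10, "linear", True, "group_slope"),
}

#: for warm-starting the unstructured-covariance models from their
#: single-variance counterparts
IID_COUNTERPART = {3: 2, 6: 5, 9: 8}


def model_spec(index: int) -> ModelSpec:
    """The canonical specification of model ``index`` (1-10)."""
    try:
        return _MODELS[int(index)]
    except (KeyError, ValueError):
        raise ValueError(f"model index must be in 1..10, got {index!r}") from None


def build_fixed_design(spec: ModelSpec, design) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design tensor of shape ``(N, n, p)`` plus column labels.

    Columns: intercept; intervention indicator ``X``; time main effect
    (period dummies 2..n under reference coding, or a single ``t_j`` column);
    and, for models with a control trend, ``t_j * (1 - X_ij)``.

    Raises :class:`RankError` if the flattened matrix is rank deficient.
    """
    N, n = design.n_clusters, design.n_periods
    X = design.intervention_matrix.astype(float)
    t = np.broadcast_to(design.time_covariate, (N, n))

    cols = [np.ones((N, n)), X]
    labels = ["alpha", "theta"]
    if spec.fixed_time == "discrete":
        for j in range(2, n + 1):
            cols.append(np.broadcast_to(
                (np.arange(1, n + 1) == j).astype(float), (N, n)))
            labels.append(f"beta_{j}")
    else:
        cols.append(t)
        labels.append("beta_t")
    if spec.control_trend:
        cols.append(t * (1.0 - X))
        labels.append("gamma")

    A = np.stack(cols, axis=-1)
    rank = np.linalg.matrix_rank(A.reshape(N * n, -1))
    if rank < A.shape[-1]:
        raise RankError(
            f"fixed design for model {spec.index} has rank {rank} < "
            f"{A.shape[-1]} columns {labels}"
        )
    return A, labels


def _control_block_dim(design) -> int:
    # control-period effects exist for periods 1 .. t^I_i - 1; the full
    # covariance block belongs to the latest-rolled cluster
    return int(np.max(design.rollout_period)) - 1


def build_random_design(spec: ModelSpec, design) -> np.ndarray:
    """Random-effect loading tensor ``Z`` of shape ``(N, n, q)``.

    Row ``(i, j)`` maps cluster ``i``'s random-effect vector to its linear
    predictor contribution in period ``j``.  Control-block columns load only
    where ``X_ij = 0`` (zero-padded for clusters rolled out early; the
    padded coordinates are exactly integrated out by the shared covariance).
    """
    N, n = design.n_clusters, design.n_periods
    X = design.intervention_matrix.astype(float)
    t = np.broadcast_to(design.time_covariate, (N, n))
    eye = np.broadcast_to(np.eye(n), (N, n, n))
    ones = np.ones((N, n, 1))
    rs = spec.random_structure

    if rs == "intercept":
        return ones.copy()
    if rs in ("cluster_period_iid", "cluster_unstructured"):
        return eye.copy()
    if rs == "intercept_slope":
        return np.stack([np.ones((N, n)), t], axis=-1)
    if rs in ("group_iid", "group_unstructured"):
        nc = _control_block_dim(design)
        Zc = eye[:, :, :nc] * (1.0 - X)[:, :, None]
        return np.concatenate([eye, Zc], axis=-1)
    if rs == "group_slope":
        ctrl = 1.0 - X
        return np.stack([np.ones((N, n)), t, ctrl, t * ctrl], axis=-1)
    raise AssertionError(rs)


def covariance_structure(spec: ModelSpec, design) -> CovarianceStructure:
    """The covariance parameterization matching :func:`build_random_design`."""
    n = design.n_periods
    rs = spec.random_structure
    if rs == "intercept":
        return Isotropic(1, name="b0")
    if rs == "cluster_period_iid":
        return Isotropic(n, name="b")
    if rs == "cluster_unstructured":
        return Unstructured(n, name="b")
    if rs == "intercept_slope":
        return Unstructured(2, name="b")
    nc = _control_block_dim(design)
    if rs == "group_iid":
        return Composite([Isotropic(n, name="b"), Isotropic(nc, name="c")])
    if rs == "group_unstructured":
        return Composite([Unstructured(n, name="b"), Unstructured(nc, name="c")])
    if rs == "group_slope":
        return Composite([Unstructured(2, name="b"), Unstructured(2, name="c")])
    raise AssertionError(rs)
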