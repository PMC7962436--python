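import dataclasses

import numpy as np
import pytest

from swdsim.design import build_design
from swdsim.fixtures import make_fixture
from swdsim.glmm import (
    FitOptions,
    LaplaceProblem,
    build_fixed_design,
    build_random_design,
    covariance_structure,
    fit_glmm,
    model_spec,
)
from swdsim.glmm.aghq import aghq_loglik_random_intercept
from swdsim.glmm.data import as_trial
from swdsim.simulate import ScenarioParams, generate_dataset


def _problem(trial, m, **kwargs):
    spec = model_spec(m)
    A, labels = build_fixed_design(spec, trial)
    Z = build_random_design(spec, trial)
    structure = covariance_structure(spec, trial)
    return LaplaceProblem(trial.y, trial.offsets, A, Z, structure, **kwargs), labels


@pytest.fixture(scope="module")
def smoke_trial():
    return as_trial(make_fixture("smoke_s4").dataset)


@pytest.mark.parametrize("m", [1, 2, 3, 4, 5, 6, 7, 8, 9, 10])
def test_analytic_gradient_matches_finite_differences(smoke_trial, m):
    """The hand-derived Laplace gradient (mode and log-det terms included)
    agrees with central finite differences for every covariance structure."""
    prob, _ = _problem(smoke_trial, m, inner_tol=1e-12)
    rng = np.random.default_rng(m)
    beta = np.zeros(prob.p)
    beta[0] = -10.0
    phi = prob.structure.initial(0.3) + 0.1 * rng.normal(size=prob.structure.n_params)
    psi = prob.pack(beta, phi)
    _, grad = prob.value_and_grad(psi)
    for k in rng.choice(len(psi), size=min(len(psi), 12), replace=False):
        h = 1e-5 * max(1.0, abs(psi[k]))
        pp, pm = psi.copy(), psi.copy()
        pp[k] += h
        pm[k] -= h
        fd = (prob.value(pp) - prob.value(pm)) / (2 * h)
        assert grad[k] == pytest.approx(fd, rel=1e-4, abs=1e-5)


def test_laplace_matches_adaptive_quadrature():
    """On the scalar-random-effect fixture the Laplace objective agrees with
    21-node adaptive Gauss-Hermite quadrature to 1e-3 on the log scale."""
    fx = make_fixture("aghq")
    trial = as_trial(fx.dataset)
    prob, _ = _problem(trial, 1)
    rng = np.random.default_rng(0)
    for sigma in (0.2, 0.4, 0.8):
        beta = np.zeros(prob.p)
        beta[0] = -10.0 + 0.2 * rng.normal()
        lap = prob.value(prob.pack(beta, np.array([np.log(sigma)])))
        agh = aghq_loglik_random_intercept(
            trial.y, trial.offsets, prob.A, beta, sigma, n_nodes=21
        )
        assert lap == pytest.approx(agh, abs=1e-3)


def test_sigma_zero_limit_is_poisson_glm():
    """As sigma -> 0 the Laplace objective collapses onto the fixed-effect
    Poisson GLM log-likelihood."""
    sm = pytest.importorskip("statsmodels.api")
    fx = make_fixture("glm_limit")
    trial = as_trial(fx.dataset)
    prob, _ = _problem(trial, 1)
    glm = sm.GLM(
        trial.y.ravel(),
        prob.A.reshape(-1, prob.p),
        family=sm.families.Poisson(),
        offset=np.repeat(np.log(trial.offsets), trial.n_periods),
    ).fit()
    lap = prob.value(prob.pack(glm.params, np.array([-12.0])))
    assert lap == pytest.approx(glm.llf, abs=1e-6)


def test_offset_rescaling_invariance(small_design):
    """Doubling every offset while lowering alpha by log 2 leaves the
    maximizing theta unchanged."""
    params = ScenarioParams("1")
    data = generate_dataset(small_design, params, np.random.default_rng(21))
    fit_a = fit_glmm(data, 1, FitOptions(compute_se=False))
    doubled = dataclasses.replace(
        small_design, offsets=2.0 * small_design.offsets
    )
    data_b = dataclasses.replace(data, design=doubled)
    fit_b = fit_glmm(data_b, 1, FitOptions(compute_se=False))
    assert fit_b.theta_hat == pytest.approx(fit_a.theta_hat, abs=1e-5)
    assert fit_b.fixed_effects["alpha"] == pytest.approx(
        fit_a.fixed_effects["alpha"] - np.log(2), abs=1e-5
    )


def test_time_rescaling_invariance(small_design):
    """Measuring t in years instead of months rescales slope terms but
    leaves the intervention effect estimate unchanged (model 8)."""
    data = generate_dataset(small_design, ScenarioParams("1"), np.random.default_rng(22))
    trial = as_trial(data)
    rescaled = dataclasses.replace(trial, time_covariate=trial.time_covariate / 12.0)
    fit_m = fit_glmm(trial, 8, FitOptions(compute_se=False))
    fit_y = fit_glmm(rescaled, 8, FitOptions(compute_se=False))
    assert fit_y.theta_hat == pytest.approx(fit_m.theta_hat, abs=5e-4)
    assert fit_y.fixed_effects["beta_t"] == pytest.approx(
        12.0 * fit_m.fixed_effects["beta_t"], rel=5e-3
    )


@pytest.mark.parametrize("pair", [(2, 3), (5, 6), (8, 9)])
def test_nested_covariance_likelihood_ordering(smoke_trial, pair):
    """An unstructured covariance nests its single-variance counterpart, so
    its maximized objective can never be lower."""
    small, big = pair
    fit_small = fit_glmm(smoke_trial, small, FitOptions(compute_se=False))
    fit_big = fit_glmm(smoke_trial, big, FitOptions(compute_se=False))
    assert fit_big.loglik >= fit_small.loglik - 1e-4


def test_gradient_norm_small_at_reported_optimum(smoke_trial):
    """The optimizer's solution is a genuine stationary point (interior
    coordinates) of the Laplace objective."""
    fit = fit_glmm(smoke_trial, 4, FitOptions(compute_se=False))
    assert fit.converged
    prob, labels = _problem(smoke_trial, 4)
    psi = np.concatenate(
        [list(fit.fixed_effects.values()), list(fit.varcomp.values())]
    )
    _, grad = prob.value_and_grad(psi)
    bounds = [(None, None)] * prob.p + prob.structure.bounds()
    for k, g in enumerate(grad):
        lo, hi = bounds[k]
        at_bound = (lo is not None and psi[k] <= lo + 1e-6) or (
            hi is not None and psi[k] >= hi - 1e-6
        )
        if not at_bound:
            assert abs(g) < 5e-3
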