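import numpy as np
import pytest

from swdsim.design import build_design
from swdsim.simulate import (
    ScenarioParams,
    adoption_probability,
    draw_confounding_exposure,
    draw_early_adoption,
    draw_period_effects,
    generate_dataset,
    truth_to_frame,
)


class TestScenarioParams:
    def test_defaults_match_motivating_study(self):
        p = ScenarioParams()
        assert p.alpha == -10.0
        assert p.sigma_b0 == 0.30
        assert p.theta == pytest.approx(np.log(0.6))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"scenario_id": "2.3"},
            {"sigma_b0": -1.0},
            {"theta": 0.2},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScenarioParams(**kwargs)

    def test_process_flags(self):
        assert not ScenarioParams("1").has_confounding
        assert ScenarioParams("2.2").has_confounding
        assert ScenarioParams("3").has_adoption
        assert ScenarioParams("4.1").has_confounding
        assert ScenarioParams("4.1").has_adoption
        assert ScenarioParams("2.1").confounding_sign == 1
        assert ScenarioParams("4.2").confounding_sign == -1


class TestConfoundingExposure:
    def test_marginal_exposure_probability(self, paper_design):
        # per cluster, P(exposed by end) = 1 - (1 - 1/18)^13 ~ 0.524
        rng = np.random.default_rng(1)
        reps = 2000
        frac = np.empty(reps)
        for r in range(reps):
            t = draw_confounding_exposure(paper_design, rng)
            frac[r] = np.mean(t <= 13)
        expect = 1 - (1 - 1 / 18) ** 13
        mc_se = frac.std() / np.sqrt(reps)
        assert abs(frac.mean() - expect) < 4 * mc_se + 1e-3

    def test_first_period_mean_newly_exposed(self, paper_design):
        # |U_1| * 1/N = 18/18 = 1 expected new exposure at period 1
        rng = np.random.default_rng(2)
        k = np.array(
            [(draw_confounding_exposure(paper_design, rng) == 1).sum() for _ in range(2000)]
        )
        assert abs(k.mean() - 1.0) < 4 * k.std() / np.sqrt(len(k))

    def test_exposure_is_absorbing(self, paper_design):
        # onset time semantics: beta window starts at t' and never closes
        rng = np.random.default_rng(3)
        params = ScenarioParams("2.1")
        for _ in range(20):
            data = generate_dataset(paper_design, params, rng)
            tp = data.truth.confound_time
            beta = data.truth.beta_effects
            for i in range(18):
                before = beta[i, : tp[i] - 1]
                assert np.all(before == 0)


class TestEarlyAdoption:
    def test_adoption_probability_formula(self):
        assert adoption_probability(18, 18) == pytest.approx(1 / 36)
        assert adoption_probability(18, 1) == pytest.approx(0.5)

    def test_no_adoption_without_control_clusters(self):
        # all clusters treated from period 2: pool empty at every period >= 2
        d = build_design(2, 3, 1, 2, 3.0)
        rng = np.random.default_rng(4)
        stars = [draw_early_adoption(d, rng) for _ in range(200)]
        # adoption can only happen in period 1 (the only control period)
        assert all(np.all((s == 1) | (s == 4)) for s in stars)

    def test_adoption_only_while_in_control(self, paper_design):
        rng = np.random.default_rng(5)
        for _ in range(50):
            t_star = draw_early_adoption(paper_design, rng)
            adopted = t_star <= 13
            assert np.all(
                t_star[adopted] < paper_design.rollout_period[adopted]
            )

    def test_first_period_adoption_rate(self, paper_design):
        # full pool: per-cluster probability (N-N+1)/(2N) = 1/36
        rng = np.random.default_rng(6)
        k = np.array(
            [(draw_early_adoption(paper_design, rng) == 1).sum() for _ in range(3000)]
        )
        expect = 18 / 36
        assert abs(k.mean() - expect) < 4 * k.std() / np.sqrt(len(k))


class TestPeriodEffects:
    def test_effect_windows_and_supports(self, paper_design):
        rng = np.random.default_rng(7)
        n = paper_design.n_periods
        for sid in ("2.1", "2.2", "4.1", "4.2"):
            params = ScenarioParams(sid)
            tp = draw_confounding_exposure(paper_design, rng)
            ts = (
                draw_early_adoption(paper_design, rng)
                if params.has_adoption
                else np.full(18, n + 1)
            )
            tr = draw_period_effects(paper_design, tp, ts, params, rng)
            periods = np.arange(1, n + 1)
            exposed = periods[None, :] >= tp[:, None]
            assert np.all(tr.beta_effects[~exposed] == 0)
            if params.confounding_sign == 1:
                assert np.all(tr.beta_effects <= 0)
            else:
                assert np.all(tr.beta_effects >= 0)
            window = (periods[None, :] >= ts[:, None]) & (
                periods[None, :] < paper_design.rollout_period[:, None]
            )
            assert np.all(tr.adopt_effects[~window] == 0)
            assert np.all(tr.adopt_effects >= params.theta)
            assert np.all(tr.adopt_effects <= 0)

    def test_null_theta_kills_adoption_effects(self, paper_design):
        rng = np.random.default_rng(8)
        params = ScenarioParams("3").null()
        data = generate_dataset(paper_design, params, rng)
        assert np.all(data.truth.adopt_effects == 0)

    def test_adoption_effect_mean_is_half_theta(self, paper_design):
        rng = np.random.default_rng(9)
        params = ScenarioParams("3")
        vals = []
        for _ in range(300):
            data = generate_dataset(paper_design, params, rng)
            th = data.truth.adopt_effects
            vals.extend(th[th != 0].tolist())
        vals = np.array(vals)
        expect = params.theta / 2
        assert abs(vals.mean() - expect) < 4 * vals.std() / np.sqrt(len(vals))


class TestGenerateDataset:
    def test_expected_count_closed_form(self):
        # E[Y] = O exp(alpha) = 1e5 exp(-10) ~ 4.54 with no random effects
        d = build_design(4, 4, 1, 2, 3.0, offsets=np.full(4, 1e5))
        params = ScenarioParams("1", sigma_b0=0.0, theta=0.0)
        rng = np.random.default_rng(10)
        ys = np.concatenate(
            [generate_dataset(d, params, rng).counts.ravel() for _ in range(400)]
        )
        expect = 1e5 * np.exp(-10)
        assert ys.mean() == pytest.approx(expect, abs=4 * ys.std() / np.sqrt(len(ys)))

    def test_intervention_rate_ratio(self):
        # treated vs control rate ratio is exp(theta) = 0.6
        d = build_design(4, 4, 1, 2, 3.0, offsets=np.full(4, 5e5))
        params = ScenarioParams("1", sigma_b0=0.0)
        rng = np.random.default_rng(11)
        treated, control = [], []
        for _ in range(400):
            data = generate_dataset(d, params, rng)
            X = d.intervention_matrix.astype(bool)
            treated.extend(data.counts[X].tolist())
            control.extend(data.counts[~X].tolist())
        ratio = np.mean(treated) / np.mean(control)
        assert ratio == pytest.approx(0.6, abs=0.02)

    def test_random_intercept_lognormal_mean(self):
        # E[exp(b)] = exp(sigma^2/2) ~ 1.046 at sigma = 0.30
        d = build_design(4, 4, 1, 2, 3.0, offsets=np.full(4, 5e5))
        params = ScenarioParams("1", theta=0.0)
        rng = np.random.default_rng(12)
        ys = np.concatenate(
            [generate_dataset(d, params, rng).counts.ravel() for _ in range(600)]
        )
        rel = ys.mean() / (5e5 * np.exp(-10))
        assert rel == pytest.approx(np.exp(0.30**2 / 2), abs=0.01)

    def test_poisson_dispersion(self):
        # conditional on latent values, var/mean ~ 1
        d = build_design(6, 5, 1, 2, 3.0, offsets=np.full(6, 2e5))
        params = ScenarioParams("1", sigma_b0=0.0, theta=0.0)
        rng = np.random.default_rng(13)
        ys = np.stack(
            [generate_dataset(d, params, rng).counts.ravel() for _ in range(500)]
        )
        dispersion = ys.var(axis=0, ddof=1) / ys.mean(axis=0)
        assert dispersion.mean() == pytest.approx(1.0, abs=0.05)

    def test_confounding_orders_counts_by_sign(self, paper_design):
        # beneficial confounding lowers exposed-period counts, harm raises
        rng = np.random.default_rng(14)
        for sid, comparator in [("2.1", np.less), ("2.2", np.greater)]:
            exp_mean, unexp_mean = [], []
            for _ in range(150):
                data = generate_dataset(paper_design, ScenarioParams(sid), rng)
                X = paper_design.intervention_matrix.astype(bool)
                exposed = data.truth.beta_effects != 0
                rate = data.counts / paper_design.offsets[:, None]
                ctrl = ~X
                if (exposed & ctrl).any() and (~exposed & ctrl).any():
                    exp_mean.append(rate[exposed & ctrl].mean())
                    unexp_mean.append(rate[~exposed & ctrl].mean())
            assert comparator(np.mean(exp_mean), np.mean(unexp_mean))

    def test_null_early_adoption_identical_to_standard(self, paper_design):
        # with theta = 0 the adoption scenario collapses onto scenario 1,
        # reproducing it draw for draw thanks to the substream discipline
        a = generate_dataset(
            paper_design, ScenarioParams("1", theta=0.0), np.random.default_rng(15)
        )
        b = generate_dataset(
            paper_design, ScenarioParams("3", theta=0.0), np.random.default_rng(15)
        )
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.random_intercepts, b.random_intercepts)

    def test_truth_sidecar_shapes(self, paper_design):
        data = generate_dataset(
            paper_design, ScenarioParams("4.2"), np.random.default_rng(16)
        )
        frame = truth_to_frame(data)
        assert len(frame) == 18 * 13
        assert {"t_prime", "t_star", "beta_ij", "theta_ij", "b_i"} <= set(frame.columns)
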