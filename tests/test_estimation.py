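import numpy as np
import pandas as pd
import pytest

from dcemcda import (
    PreferencePopulation,
    build_long_format,
    simulate_responses,
)
from dcemcda.estimation import (
    LongFormatData,
    ModelSpec,
    conditional_logit_loglik,
    fit_conditional_logit,
    fit_mixed_logit,
    halton_sequence,
    information_criteria,
    make_normal_draws,
    mixed_logit_simulated_loglik,
)


@pytest.fixture(scope="module")
def small_survey(schema, questionnaires):
    pop = PreferencePopulation(careless_fraction=0.0)
    return simulate_responses(questionnaires, pop, 50, seed=23, schema=schema)


@pytest.fixture(scope="module")
def small_long(small_survey, schema):
    return build_long_format(small_survey, schema)


class TestBuildLongFormat:
    def test_row_counts(self, valid_survey, schema):
        n = valid_survey.n_respondents
        long = build_long_format(valid_survey, schema)
        assert long.n_obs == n * 10 * 3
        full = build_long_format(valid_survey, schema, drop_consistency_repeat=False)
        assert full.n_obs == n * 11 * 3

    def test_one_chosen_row_per_task(self, long_valid):
        per_task = long_valid.frame.groupby(["respondent_id", "task_id"])["chosen"].sum()
        assert (per_task == 1).all()

    def test_opt_out_rows_have_zero_design_vector(self, long_valid):
        oo = long_valid.frame[long_valid.frame["opt_out"] == 1]
        assert (oo[long_valid.design_columns].to_numpy() == 0).all()
        assert (oo["alt_id"] == 0).all()

    def test_multiple_chosen_rows_rejected(self, long_valid):
        bad = long_valid.frame.copy()
        bad.loc[:, "chosen"] = 1
        with pytest.raises(ValueError, match="exactly one chosen"):
            LongFormatData(frame=bad, design_columns=long_valid.design_columns)


class TestConditionalLogitLoglik:
    def test_zero_parameters_give_uniform_likelihood(self, small_long):
        ll, _ = conditional_logit_loglik(np.zeros(14), small_long)
        n_tasks = small_long.n_obs // 3
        assert ll == pytest.approx(n_tasks * np.log(1 / 3), rel=1e-12)

    def test_gradient_matches_central_differences(self, small_long):
        rng = np.random.default_rng(1)
        theta = 0.2 * rng.standard_normal(14)
        ll, grad = conditional_logit_loglik(theta, small_long)
        h = 1e-6
        for i in range(14):
            e = np.zeros(14)
            e[i] = h
            lp, _ = conditional_logit_loglik(theta + e, small_long)
            lm, _ = conditional_logit_loglik(theta - e, small_long)
            fd = (lp - lm) / (2 * h)
            assert grad[i] == pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_shift_invariance_within_task(self, small_long):
        """Adding a constant to all three utilities of one task (via a
        uniform shift of the cost column) leaves the likelihood unchanged."""
        theta = np.full(14, 0.1)
        ll0, _ = conditional_logit_loglik(theta, small_long)
        shifted = small_long.frame.copy()
        task = shifted["task_id"].iloc[0]
        rows = shifted["task_id"] == task
        # same cost shift on all three rows => same utility shift per row
        shifted.loc[rows, "cost_10k"] += 5.0
        data2 = LongFormatData(frame=shifted, design_columns=small_long.design_columns)
        ll1, _ = conditional_logit_loglik(theta, data2)
        assert ll1 == pytest.approx(ll0, rel=1e-10)

    def test_non_finite_parameters_rejected(self, small_long):
        with pytest.raises(ValueError):
            conditional_logit_loglik(np.full(14, np.nan), small_long)


class TestFitConditionalLogit:
    def test_parameter_recovery_without_mixing(self, schema, questionnaires):
        pop = PreferencePopulation(sd_coefficients=np.zeros(13), careless_fraction=0.0)
        survey = simulate_responses(questionnaires, pop, 1000, seed=29, schema=schema)
        long = build_long_format(survey, schema)
        fit = fit_conditional_logit(long)
        assert fit.converged
        truth = np.append(np.asarray(pop.mean_coefficients), pop.asc_opt_out)
        est = np.append(fit.means.to_numpy(), fit.asc)
        se = np.append(fit.mean_se.to_numpy(), fit.asc_se)
        within = np.abs(est - truth) / se < 3
        assert within.sum() >= 12

    def test_one_parameter_toy_matches_grid_search(self):
        """Single-dummy model: the BFGS optimum matches a 1-D grid scan."""
        rng = np.random.default_rng(7)
        rows = []
        for t in range(300):
            x = np.array([1.0, 0.0])
            u = 1.2 * x
            p = np.exp(u) / np.exp(u).sum()
            choice = rng.choice(2, p=p)
            for j in range(2):
                rows.append((0, t, j + 1, int(choice == j), 0, x[j]))
        frame = pd.DataFrame(
            rows, columns=["respondent_id", "task_id", "alt_id", "chosen", "opt_out", "x"]
        )
        data = LongFormatData(frame=frame, design_columns=["x"])
        fit = fit_conditional_logit(data)
        grid = np.linspace(-3, 4, 7001)
        lls = [conditional_logit_loglik(np.array([b, 0.0]), data)[0] for b in grid]
        assert fit.means["x"] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-3)

    def test_duplicated_data_same_estimates_smaller_se(self, small_long):
        fit1 = fit_conditional_logit(small_long)
        doubled = small_long.frame.copy()
        doubled2 = doubled.copy()
        doubled2["respondent_id"] += 10_000
        doubled2["task_id"] += 10_000_000
        data2 = LongFormatData(
            frame=pd.concat([doubled, doubled2], ignore_index=True),
            design_columns=small_long.design_columns,
        )
        fit2 = fit_conditional_logit(data2)
        np.testing.assert_allclose(fit2.means.to_numpy(), fit1.means.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(
            fit2.mean_se.to_numpy(), fit1.mean_se.to_numpy() / np.sqrt(2), rtol=1e-4
        )

    def test_estimates_invariant_to_row_order(self, small_long):
        fit1 = fit_conditional_logit(small_long)
        shuffled = small_long.frame.sample(frac=1.0, random_state=0)
        fit2 = fit_conditional_logit(
            LongFormatData(frame=shuffled, design_columns=small_long.design_columns)
        )
        np.testing.assert_allclose(fit1.means.to_numpy(), fit2.means.to_numpy(), atol=1e-9)

    def test_matches_statsmodels_conditional_logit(self, small_long):
        """Independent route: conditional logistic regression with one case
        per stratum is the same model; coefficients must agree."""
        from statsmodels.discrete.conditional_models import ConditionalLogit

        df = small_long.frame
        exog = df[small_long.design_columns + ["opt_out"]].to_numpy()
        sm_fit = ConditionalLogit(
            df["chosen"].to_numpy(), exog, groups=df["task_id"].to_numpy()
        ).fit(disp=0)
        ours = fit_conditional_logit(small_long)
        mine = np.append(ours.means.to_numpy(), ours.asc)
        np.testing.assert_allclose(mine, sm_fit.params, atol=2e-4)


class TestHalton:
    def test_base2_prefix(self):
        pts = halton_sequence(1, 3)
        np.testing.assert_allclose(pts[:, 0], [0.5, 0.25, 0.75])

    def test_burn_drops_prefix(self):
        full = halton_sequence(3, 30)
        burned = halton_sequence(3, 20, burn=10)
        np.testing.assert_allclose(burned, full[10:])

    def test_marginals_near_uniform(self):
        from scipy.stats import kstest

        pts = halton_sequence(12, 1000, burn=100)
        for d in range(12):
            assert kstest(pts[:, d], "uniform").statistic < 0.05

    def test_scramble_is_seeded(self):
        a = halton_sequence(4, 50, seed_scramble=True, seed=5)
        b = halton_sequence(4, 50, seed_scramble=True, seed=5)
        c = halton_sequence(4, 50, seed_scramble=True, seed=6)
        np.testing.assert_array_equal(a, b)
        assert not np.allclose(a, c)

    def test_dimension_limit(self):
        with pytest.raises(ValueError):
            halton_sequence(100, 10)


class TestMixedLogitLoglik:
    def test_zero_sds_equal_conditional_logit(self, small_long):
        theta14 = np.concatenate([0.3 * np.ones(13), [0.5]])
        draws = make_normal_draws(50, 20, 12, seed=0)
        theta26 = np.concatenate([theta14, np.zeros(12)])
        ll_mix, _ = mixed_logit_simulated_loglik(theta26, small_long, draws)
        ll_cl, _ = conditional_logit_loglik(theta14, small_long)
        assert ll_mix == pytest.approx(ll_cl, rel=1e-10)

    def test_monotone_approach_as_sds_shrink(self, small_long):
        theta14 = np.concatenate([0.3 * np.ones(13), [0.5]])
        draws = make_normal_draws(50, 50, 12, seed=1)
        ll_cl, _ = conditional_logit_loglik(theta14, small_long)
        gaps = []
        for s in [0.8, 0.4, 0.2, 0.1]:
            theta = np.concatenate([theta14, np.full(12, s)])
            ll, _ = mixed_logit_simulated_loglik(theta, small_long, draws)
            gaps.append(abs(ll - ll_cl))
        assert all(a > b for a, b in zip(gaps, gaps[1:]))

    def test_loglik_is_nonpositive(self, small_long):
        rng = np.random.default_rng(3)
        draws = make_normal_draws(50, 20, 12, seed=2)
        theta = rng.normal(size=26)
        ll, _ = mixed_logit_simulated_loglik(theta, small_long, draws)
        assert ll <= 0

    def test_gradient_matches_central_differences(self, small_long):
        draws = make_normal_draws(50, 15, 12, seed=4)
        rng = np.random.default_rng(5)
        theta = 0.2 * rng.standard_normal(26) + np.concatenate([np.zeros(14), 0.3 * np.ones(12)])
        _, grad = mixed_logit_simulated_loglik(theta, small_long, draws)
        h = 1e-6
        for i in [0, 5, 12, 13, 14, 20, 25]:
            e = np.zeros(26)
            e[i] = h
            lp, _ = mixed_logit_simulated_loglik(theta + e, small_long, draws)
            lm, _ = mixed_logit_simulated_loglik(theta - e, small_long, draws)
            assert grad[i] == pytest.approx((lp - lm) / (2 * h), rel=1e-5, abs=1e-7)

    def test_draw_doubling_stability(self, small_long):
        """Simulated likelihood on a 50-respondent fixture moves < 0.1%
        between 500 and 1,000 Halton draws."""
        theta = np.concatenate([0.3 * np.ones(13), [0.5], 0.2 * np.ones(12)])
        ll500, _ = mixed_logit_simulated_loglik(
            theta, small_long, make_normal_draws(50, 500, 12, seed=6)
        )
        ll1000, _ = mixed_logit_simulated_loglik(
            theta, small_long, make_normal_draws(50, 1000, 12, seed=6)
        )
        assert abs(ll1000 - ll500) / abs(ll500) < 1e-3

    def test_zero_draws_rejected(self, small_long):
        theta = np.zeros(26)
        with pytest.raises(ValueError):
            mixed_logit_simulated_loglik(theta, small_long, np.empty((50, 0, 12)))


class TestFitMixedLogit:
    def test_empty_random_mask_reproduces_conditional_logit(self, small_long):
        cl = fit_conditional_logit(small_long)
        mx = fit_mixed_logit(
            small_long, ModelSpec(random_columns=()), n_draws=5, seed=0, compute_se=False
        )
        np.testing.assert_allclose(mx.means.to_numpy(), cl.means.to_numpy(), atol=1e-5)
        assert mx.asc == pytest.approx(cl.asc, abs=1e-5)
        assert mx.log_likelihood == pytest.approx(cl.log_likelihood, abs=1e-6)

    def test_same_seed_same_result(self, small_long):
        a = fit_mixed_logit(small_long, n_draws=30, seed=3, compute_se=False, maxiter=40)
        b = fit_mixed_logit(small_long, n_draws=30, seed=3, compute_se=False, maxiter=40)
        assert a.to_json() == b.to_json()

    def test_reported_sds_nonnegative_and_settings_recorded(self, small_long):
        fit = fit_mixed_logit(small_long, n_draws=30, seed=9, compute_se=False, maxiter=40)
        assert (fit.sds >= 0).all()
        assert fit.n_draws == 30 and fit.seed == 9
        assert fit.k == 26


class TestInformationCriteria:
    @pytest.mark.parametrize(
        "ll,n_obs,aic,bic",
        [
            (-575.88767, 2070, 1203.775, 1350.293),
            (-281.83149, 1110, 615.663, 745.978),
            (-254.76378, 960, 561.5276, 688.0678),
        ],
    )
    def test_reproduces_published_triples(self, ll, n_obs, aic, bic):
        a, b = information_criteria(ll, 26, n_obs)
        assert a == pytest.approx(aic, abs=5e-4)
        assert b == pytest.approx(bic, abs=5e-4)

    def test_degenerate_input(self):
        assert information_criteria(0.0, 0, 1) == (0.0, 0.0)

    def test_identities_hold_on_fit_results(self, small_long):
        fit = fit_conditional_logit(small_long)
        aic, bic = information_criteria(fit.log_likelihood, fit.k, fit.n_obs)
        assert fit.aic == pytest.approx(aic) and fit.bic == pytest.approx(bic)
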