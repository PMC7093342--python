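"""Weighted-combination model family: prediction, fitting, LOOCV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from glimpse import (
    COMBINED,
    ONE_PLEASURE,
    ComparisonError,
    InsufficientDataError,
    ModelSpec,
    TrialObservations,
    combined_specs,
    compare,
    fit,
    loocv,
    one_pleasure_specs,
    predict,
    simulate_cohort,
)
from glimpse.models import _fit_linear, _fit_nonlinear


def make_obs(p1, p2, y, trial_type=ONE_PLEASURE):
    return TrialObservations(
        p1=np.asarray(p1, float),
        p2=np.asarray(p2, float),
        y=np.asarray(y, float),
        trial_type=trial_type,
    )


def grid_obs(w=1.0, a=0.0, b=1.0, noise=None, seed=0):
    """All (target, distractor) pairs on the integer grid, rated by Eq-family arithmetic."""
    p1, p2 = np.meshgrid(np.arange(1.0, 10.0), np.arange(1.0, 10.0))
    p1, p2 = p1.ravel(), p2.ravel()
    y = predict(a, b, w, p1, p2)
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, size=len(y))
    return make_obs(p1, p2, y)


class TestPredict:
    @pytest.mark.parametrize(
        "params,p1,p2,expected",
        [
            ((0, 1, 1), 3, 9, 3.0),  # faithful identity
            ((0, 1, 0.5), 3, 9, 6.0),  # plain averaging
            ((0.39, 0.85, 0.5), 5, 5, 4.64),  # mean compressive fit
            ((-0.70, 1.05, 0.5), 2, 4, 2.45),  # mean expansive fit
        ],
    )
    def test_arithmetic(self, params, p1, p2, expected):
        a, b, w = params
        assert predict(a, b, w, p1, p2) == pytest.approx(expected)

    @given(
        st.floats(-2, 2),
        st.floats(0.1, 2),
        st.floats(0.5, 1),
        st.floats(1, 9),
        st.floats(1, 9),
        st.floats(-3, 3),
    )
    @settings(deadline=None, derandomize=True)
    def test_shift_equivariance(self, a, b, w, p1, p2, c):
        # adding c to the intercept shifts the prediction by exactly c
        assert predict(a + c, b, w, p1, p2) == pytest.approx(
            predict(a, b, w, p1, p2) + c, abs=1e-9
        )


class TestFit:
    def test_noiseless_faithful_data_fits_exactly(self):
        obs = grid_obs(w=1.0)
        res = fit(obs, one_pleasure_specs()[0])
        assert res.rmse_train == pytest.approx(0.0, abs=1e-12)

    def test_recovers_generative_weight(self):
        obs = grid_obs(w=0.7)
        res = fit(obs, one_pleasure_specs()[2])  # partial averaging, free w
        assert res.params["w"] == pytest.approx(0.7, abs=1e-4)
        assert res.rmse_train == pytest.approx(0.0, abs=1e-8)

    def test_faithful_residual_on_averaging_data_closed_form(self):
        obs = grid_obs(w=0.5)
        res = fit(obs, one_pleasure_specs()[0])
        expected = np.sqrt(np.mean(((obs.p2 - obs.p1) / 2) ** 2))
        assert res.rmse_train == pytest.approx(expected, abs=1e-12)

    def test_recovers_compressive_parameters(self):
        obs = grid_obs(w=0.5, a=0.39, b=0.85)
        obs.trial_type = COMBINED
        res = fit(obs, combined_specs()[1])
        assert res.params["a"] == pytest.approx(0.39, abs=1e-6)
        assert res.params["b"] == pytest.approx(0.85, abs=1e-6)

    def test_fitted_parameters_respect_bounds(self):
        obs = grid_obs(w=0.5, a=1.5, b=0.4, noise=0.5)
        for spec in one_pleasure_specs() + combined_specs():
            res = fit(obs, spec)
            for name in ("a", "b", "w"):
                bound = getattr(spec, name)
                if isinstance(bound, tuple):
                    assert bound[0] <= res.params[name] <= bound[1]
                else:
                    assert res.params[name] == bound

    def test_nesting_partial_never_worse_in_sample(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            obs = grid_obs(w=rng.uniform(0.5, 1), noise=rng.uniform(0.2, 2), seed=rng.integers(1000))
            faithful = fit(obs, one_pleasure_specs()[0]).rmse_train
            partial = fit(obs, one_pleasure_specs()[2]).rmse_train
            assert partial <= faithful + 1e-12

    def test_summing_observer_recovered_by_free_slope(self):
        # combined rating = sum of the two pleasures, i.e. slope 2 on the mean
        p1, p2 = np.meshgrid(np.arange(1.0, 10.0), np.arange(1.0, 10.0))
        p1, p2 = p1.ravel(), p2.ravel()
        y = p1 + p2
        obs = make_obs(p1, p2, y, trial_type=COMBINED)
        free_b = ModelSpec("free_slope", COMBINED, a=0.0, b=(0.5, 2.5), w=0.5)
        res = fit(obs, free_b)
        assert res.params["b"] == pytest.approx(2.0, abs=1e-8)
        faithful = fit(obs, combined_specs()[0])
        assert faithful.rmse_train > res.rmse_train

    def test_shift_equivariance_of_free_intercept_fit(self):
        obs = grid_obs(w=0.5, a=0.3, b=0.9, noise=0.4)
        spec = ModelSpec("free_ab", COMBINED, a=(-5.0, 5.0), b=(0.1, 2.0), w=0.5)
        base = fit(obs, spec)
        shifted = make_obs(obs.p1, obs.p2, obs.y + 2.0, trial_type=COMBINED)
        res = fit(shifted, spec)
        assert res.params["a"] == pytest.approx(base.params["a"] + 2.0, abs=1e-6)
        assert res.params["b"] == pytest.approx(base.params["b"], abs=1e-6)

    def test_exact_and_multistart_paths_agree(self):
        # the bounded quasi-Newton path must land on the exact solution
        obs = grid_obs(w=0.5, a=0.8, b=0.7, noise=0.6)
        spec = ModelSpec("free_ab", COMBINED, a=(0.0, 4.0), b=(0.1, 1.5), w=0.5)
        exact = _fit_linear(spec, obs.p1, obs.p2, obs.y)
        numeric = _fit_nonlinear(spec, obs.p1, obs.p2, obs.y)

        def rmse(params):
            return np.sqrt(
                np.mean((obs.y - predict(params["a"], params["b"], params["w"], obs.p1, obs.p2)) ** 2)
            )

        assert rmse(numeric) == pytest.approx(rmse(exact), abs=1e-6)

    def test_too_few_trials_raise(self):
        obs = make_obs([1, 2], [2, 3], [1, 2])
        with pytest.raises(InsufficientDataError):
            fit(obs, one_pleasure_specs()[0])


class TestLoocv:
    def test_zero_free_parameters_equals_training_rmse(self):
        obs = grid_obs(w=1.0, noise=1.0)
        res = loocv(obs, one_pleasure_specs()[0])
        assert res.rmse_loocv == pytest.approx(res.rmse_train, abs=1e-12)

    def test_noiseless_matched_model_scores_zero(self):
        obs = grid_obs(w=0.8)
        res = loocv(obs, one_pleasure_specs()[2])
        assert res.rmse_loocv == pytest.approx(0.0, abs=1e-8)

    def test_matches_bruteforce_refits_on_tiny_instance(self):
        # independent oracle: scalar bounded minimisation per left-out trial
        obs = make_obs([2, 9, 4, 7, 5], [8, 1, 6, 3, 9], [3, 8, 4.5, 6, 6.5])
        spec = one_pleasure_specs()[2]
        sq = []
        for i in range(5):
            mask = np.arange(5) != i

            def cost(w):
                pred = predict(0.0, 1.0, w, obs.p1[mask], obs.p2[mask])
                return np.sum((obs.y[mask] - pred) ** 2)

            res = minimize_scalar(cost, bounds=(0.5, 1.0), method="bounded", options={"xatol": 1e-12})
            pred_i = predict(0.0, 1.0, res.x, obs.p1[i], obs.p2[i])
            sq.append((obs.y[i] - pred_i) ** 2)
        oracle = float(np.sqrt(np.mean(sq)))
        ours = loocv(obs, spec).rmse_loocv
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_two_free_parameter_loocv_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        obs = make_obs(
            rng.uniform(1, 9, 8), rng.uniform(1, 9, 8), rng.uniform(1, 9, 8), COMBINED
        )
        spec = combined_specs()[1]  # compressive, free (a, b)
        sq = []
        for i in range(8):
            mask = np.arange(8) != i
            params = _fit_nonlinear(spec, obs.p1[mask], obs.p2[mask], obs.y[mask])
            pred_i = predict(params["a"], params["b"], params["w"], obs.p1[i], obs.p2[i])
            sq.append((obs.y[i] - pred_i) ** 2)
        oracle = float(np.sqrt(np.mean(sq)))
        assert loocv(obs, spec).rmse_loocv == pytest.approx(oracle, abs=1e-6)

    def test_anti_overfitting_on_noisy_faithful_data(self):
        # extra freedom must not pay off out of sample, on average
        rng = np.random.default_rng(11)
        diffs = []
        for _ in range(60):
            obs = grid_obs(w=1.0, noise=1.4, seed=rng.integers(2**31))
            f = loocv(obs, one_pleasure_specs()[0]).rmse_loocv
            p = loocv(obs, one_pleasure_specs()[2]).rmse_loocv
            diffs.append(p - f)
        assert np.mean(diffs) >= 0


class TestCompare:
    def test_faithful_cohort_recovered(self, faithful_cohort):
        result = compare(faithful_cohort)
        for (trial_type, timing), winner in result.winners.items():
            assert winner == "faithful", (trial_type, timing)

    def test_noiseless_cohort_winners_score_zero(self, catalog):
        ds = simulate_cohort(
            3,
            catalog,
            model_name="faithful",
            late_noise_sd=0.0,
            seed=2,
            discretize=False,
            participant_noise_scale_sd=0.0,
        )
        result = compare(ds)
        summary = result.summary
        for (tt, ct), winner in result.winners.items():
            row = summary[
                (summary.trial_type == tt)
                & (summary.cue_timing == ct)
                & (summary.model == winner)
            ]
            assert row["mean_loocv_rmse"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_single_participant_rejected(self, catalog):
        ds = simulate_cohort(1, catalog, model_name="faithful", seed=2)
        with pytest.raises(ComparisonError, match="fewer than 2"):
            compare(ds)

    def test_summary_sem_is_sd_over_sqrt_n(self, faithful_cohort):
        result = compare(faithful_cohort)
        per = result.per_participant
        row = result.summary.iloc[0]
        vals = per[
            (per.trial_type == row.trial_type)
            & (per.cue_timing == row.cue_timing)
            & (per.model == row.model)
        ]["rmse_loocv"]
        assert row.sem_loocv_rmse == pytest.approx(vals.std(ddof=1) / np.sqrt(len(vals)))
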