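"""Unit tests for the intensity matrix, transition probabilities and likelihood."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from mslt.model import (
    ModelSpec,
    InvalidParameterError,
    intensity_matrix,
    transition_probability,
    log_likelihood,
    fit,
    hazard_ratios,
    validate_panel,
    FittedModel,
)
from mslt.cohort import GroundTruthIntensities

from conftest import make_panel, toy_params

REF = {"female": 0, "overweight": 0, "obese": 0}


class TestIntensityMatrix:
    def test_unit_intensities_at_reference(self):
        """All-zero parameters give unit allowed intensities at the reference."""
        spec = ModelSpec()
        Q = intensity_matrix(np.zeros(spec.n_params), spec, REF, spec.age_center)
        expected = np.array([[-2.0, 1.0, 1.0], [1.0, -2.0, 1.0], [0.0, 0.0, 0.0]])
        np.testing.assert_allclose(Q, expected)

    def test_age_effect_multiplies_incidence(self):
        """A per-year log-HR of ln(1.06) scales q12 by 1.06 per year of age."""
        spec = ModelSpec()
        params = np.zeros(spec.n_params)
        params[4] = math.log(1.06)  # beta_age on 1->2
        Q70 = intensity_matrix(params, spec, REF, 70.0)
        Q71 = intensity_matrix(params, spec, REF, 71.0)
        assert Q71[0, 1] / Q70[0, 1] == pytest.approx(1.06)
        assert Q71[1, 0] == pytest.approx(Q70[1, 0])  # other transitions untouched

    def test_female_hazard_ratio_on_incidence(self):
        """beta_female = ln(1.82) makes the female/male q12 ratio 1.82."""
        spec = ModelSpec()
        params = np.zeros(spec.n_params)
        params[8] = math.log(1.82)  # beta_female on 1->2
        Qm = intensity_matrix(params, spec, REF, 70.0)
        Qf = intensity_matrix(params, spec, {**REF, "female": 1}, 70.0)
        assert Qf[0, 1] / Qm[0, 1] == pytest.approx(1.82)

    def test_rows_sum_to_zero_and_dead_absorbing(self):
        spec = ModelSpec()
        truth = GroundTruthIntensities()
        Q = intensity_matrix(truth.to_params(), spec, {**REF, "obese": 1}, 83.0)
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(Q[2], 0.0)

    def test_overflow_raises(self):
        spec = ModelSpec()
        params = np.zeros(spec.n_params)
        params[0] = 1000.0
        with pytest.raises(InvalidParameterError):
            intensity_matrix(params, spec, REF, 70.0)


class TestTransitionProbability:
    def test_zero_length_interval_is_identity(self, nocov_spec):
        P = transition_probability(toy_params(0.3, 0.2, 0.1, 0.4), nocov_spec, {}, 65, 65)
        np.testing.assert_allclose(P, np.eye(3))

    def test_death_only_toy_closed_form(self, nocov_spec):
        """With only 1->3 at rate mu, P13(t) = 1 - exp(-mu t)."""
        mu, t = 0.37, 4.2
        P = transition_probability(toy_params(q13=mu), nocov_spec, {}, 60, 60 + t)
        assert P[0, 2] == pytest.approx(1 - math.exp(-mu * t), abs=1e-10)
        assert P[0, 0] == pytest.approx(math.exp(-mu * t), abs=1e-10)

    def test_chapman_kolmogorov(self, nocov_spec):
        """P(a,c) = P(a,b) P(b,c) when Q is constant on [a,c]."""
        params = toy_params(0.15, 0.25, 0.02, 0.12)
        Pac = transition_probability(params, nocov_spec, {}, 60, 70)
        Pab = transition_probability(params, nocov_spec, {}, 60, 64)
        Pbc = transition_probability(params, nocov_spec, {}, 64, 70)
        np.testing.assert_allclose(Pac, Pab @ Pbc, atol=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        logq=st.lists(st.floats(-6.0, 1.0), min_size=4, max_size=4),
        dt=st.floats(0.01, 20.0),
    )
    def test_matches_scipy_expm(self, nocov_spec, logq, dt):
        """The closed-form living-block exponential agrees with scipy.linalg.expm."""
        params = np.array(logq)
        P = transition_probability(params, nocov_spec, {}, 70, 70 + dt)
        Q = intensity_matrix(params, nocov_spec, {}, 70)
        np.testing.assert_allclose(P, expm(Q * dt), atol=1e-10)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(P >= -1e-15) and np.all(P <= 1 + 1e-12)

    def test_internal_grid_follows_age_dependence(self):
        """With a time-dependent age effect, a finer grid changes (refines) P."""
        spec = ModelSpec(covariates=("age",))
        params = np.array([math.log(0.1), math.log(0.1), math.log(0.05),
                           math.log(0.2), math.log(1.1), 0.0, math.log(1.1),
                           math.log(1.1)])
        coarse = transition_probability(params, spec, {}, 70, 80)
        fine = transition_probability(params, spec, {}, 70, 80, grid_step=0.1)
        finer = transition_probability(params, spec, {}, 70, 80, grid_step=0.05)
        # refreshing Q along the interval must raise the death probability
        assert fine[0, 2] > coarse[0, 2]
        # and the refinement converges
        assert abs(finer[0, 2] - fine[0, 2]) < abs(fine[0, 2] - coarse[0, 2])


class TestLogLikelihood:
    def test_exact_death_exponential_density(self, nocov_spec):
        """Alive at 0, dead exactly at t, no other exits: loglik = -mu t + ln mu."""
        mu, t = 0.21, 6.5
        df = make_panel([(1, 60.0, 1, "panel"), (1, 60.0 + t, 3, "death")])
        ll = log_likelihood(toy_params(q13=mu), df, nocov_spec)
        assert ll == pytest.approx(-mu * t + math.log(mu), abs=1e-9)

    def test_censored_immediately_after_baseline(self, nocov_spec):
        """A censored-alive record at t -> 0 contributes ln(1) = 0."""
        df = make_panel([(1, 60.0, 1, "panel"), (1, 60.0 + 1e-9, None, "censored")])
        ll = log_likelihood(toy_params(0.2, 0.1, 0.05, 0.3), df, nocov_spec)
        assert ll == pytest.approx(0.0, abs=1e-8)

    def test_invariant_to_subject_order(self, nocov_spec):
        params = toy_params(0.2, 0.15, 0.03, 0.25)
        df = make_panel(
            [
                (1, 60, 1, "panel"), (1, 65, 2, "panel"), (1, 68.3, 3, "death"),
                (2, 72, 2, "panel"), (2, 76, 1, "panel"), (2, 82.5, None, "censored"),
                (3, 61, 1, "panel"), (3, 66, 1, "panel"),
            ]
        )
        shuffled = df.iloc[[6, 7, 3, 4, 5, 0, 1, 2]].reset_index(drop=True)
        assert log_likelihood(params, df, nocov_spec) == pytest.approx(
            log_likelihood(params, shuffled, nocov_spec), abs=1e-12
        )

    def test_impossible_path_is_minus_infinity(self, nocov_spec):
        """Observing a 1->2 transition when q12 is off has zero probability."""
        df = make_panel([(1, 60, 1, "panel"), (1, 65, 2, "panel")])
        ll = log_likelihood(toy_params(q13=0.1, q23=0.1), df, nocov_spec)
        assert ll < -20  # numerically -inf territory for the 1e-12 floor


class TestValidation:
    def test_rejects_decreasing_ages(self, nocov_spec):
        df = make_panel([(1, 65, 1, "panel"), (1, 60, 2, "panel")])
        with pytest.raises(ValueError, match="strictly increasing"):
            validate_panel(df, nocov_spec)

    def test_rejects_records_after_terminal(self, nocov_spec):
        df = make_panel([(1, 60, 1, "panel"), (1, 65, 3, "death"),
                         (1, 66, 1, "panel")])
        with pytest.raises(ValueError, match="after a terminal"):
            validate_panel(df, nocov_spec)

    def test_rejects_death_without_state_3(self, nocov_spec):
        df = make_panel([(1, 60, 1, "panel"), (1, 65, 1, "death")])
        with pytest.raises(ValueError, match="state 3"):
            validate_panel(df, nocov_spec)


class TestFit:
    def test_duplicated_dataset_same_mle_half_covariance(self, nocov_spec):
        """Duplicating every subject leaves the MLE alone and halves the covariance."""
        rng = np.random.default_rng(5)
        rates = {(1, 2): 0.3, (2, 1): 0.2, (1, 3): 0.15, (2, 3): 0.3}
        truth = toy_params(*(rates[t] for t in ((1, 2), (2, 1), (1, 3), (2, 3))))
        records = []
        # data simulated from the model itself, observed yearly, so the MLE is
        # interior and every transition's rate is identified
        for sid in range(1, 201):
            age = 60 + 20 * rng.random()
            state = 1 + int(rng.random() < 0.4)
            records.append((sid, age, state, "panel"))
            t = 0.0
            while t < 3.0 and state != 3:
                hazards = [(s, q) for (r, s), q in rates.items() if r == state]
                total = sum(q for _, q in hazards)
                wait = rng.exponential(1.0 / total)
                if t + wait >= min(3.0, math.floor(t) + 1.0):
                    # no event before the next yearly interview
                    t = math.floor(t) + 1.0
                    if t <= 3.0:
                        records.append((sid, age + t, state, "panel"))
                    continue
                t += wait
                u = rng.random() * total
                acc = 0.0
                for s, q in hazards:
                    acc += q
                    if u <= acc:
                        state = s
                        break
                if state == 3:
                    records.append((sid, age + t, 3, "death"))
        df = make_panel(records)
        f1 = fit(df, nocov_spec, init=truth)
        dup = df.copy()
        dup["id"] = dup["id"] + 1000
        f2 = fit(pd.concat([df, dup], ignore_index=True), nocov_spec, init=truth)
        np.testing.assert_allclose(f2.params, f1.params, atol=5e-3)
        np.testing.assert_allclose(f2.covariance, f1.covariance / 2, rtol=0.05)
        assert f2.log_likelihood == pytest.approx(2 * f1.log_likelihood, rel=1e-3)

    def test_init_at_truth_converges_quickly(self, small_modelling):
        """Starting at the generating truth, the fit converges with a small gradient."""
        modelling, _ = small_modelling
        truth = GroundTruthIntensities()
        fitted = fit(modelling, ModelSpec(), init=truth.to_params(),
                     compute_covariance=False)
        assert fitted.converged
        assert fitted.convergence["gradient_max_norm"] < 1e-4 * max(
            1.0, abs(fitted.log_likelihood)
        )

    def test_roundtrip_json(self, tmp_path, small_modelling):
        modelling, _ = small_modelling
        fitted = fit(modelling, ModelSpec(), compute_covariance=True)
        path = tmp_path / "model.json"
        fitted.to_json(path)
        back = FittedModel.from_json(path)
        np.testing.assert_allclose(back.params, fitted.params)
        np.testing.assert_allclose(back.covariance, fitted.covariance)
        assert back.spec == fitted.spec


class TestHazardRatios:
    def test_zero_beta_gives_unit_hr(self, nocov_spec):
        spec = ModelSpec()
        fitted = FittedModel(
            spec=spec,
            params=np.zeros(spec.n_params),
            covariance=np.eye(spec.n_params) * 0.04,
            log_likelihood=0.0,
            convergence={"converged": True},
        )
        table = hazard_ratios(fitted)
        np.testing.assert_allclose(table["hr"], 1.0)
        assert (table["lo95"] < 1.0).all() and (table["hi95"] > 1.0).all()

    def test_ci_reconstructs_from_beta_and_se(self):
        """beta = ln(0.64) with se = ln(0.83/0.64)/1.96 gives CI (0.49, 0.83)."""
        spec = ModelSpec()
        params = np.zeros(spec.n_params)
        j = 4 + 4 + 3  # beta_female on 2->3
        params[j] = math.log(0.64)
        se = math.log(0.83 / 0.64) / 1.96
        cov = np.zeros((spec.n_params, spec.n_params))
        cov[j, j] = se**2
        fitted = FittedModel(spec, params, cov, 0.0, {"converged": True})
        row = hazard_ratios(fitted)
        row = row[(row["covariate"] == "female") & (row["to"] == 3) & (row["from"] == 2)]
        assert row["hr"].iloc[0] == pytest.approx(0.64)
        assert row["hi95"].iloc[0] == pytest.approx(0.83, abs=0.005)
        assert row["lo95"].iloc[0] == pytest.approx(0.49, abs=0.005)

    def test_ci_brackets_hr(self, small_modelling):
        modelling, _ = small_modelling
        fitted = fit(modelling, ModelSpec())
        table = hazard_ratios(fitted)
        assert (table["lo95"] <= table["hr"]).all()
        assert (table["hi95"] >= table["hr"]).all()
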