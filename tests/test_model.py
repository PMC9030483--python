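"""Transform, censored likelihoods, and the closed-form predictive law."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from rppdecay import (
    ModelParams,
    RandomEffects,
    censored_loglik,
    closed_form_predictive,
    inverse_log_shift,
    log_shift,
    marginal_loglik,
    prepare_observations,
)
from rppdecay.model import ObservationSet, TransformedObservation, draw_new_patient_y
from conftest import make_cohort


class TestLogShift:
    def test_zero_maps_to_zero(self):
        assert log_shift(0.0) == 0.0

    def test_e_minus_one_maps_to_one(self):
        assert log_shift(np.e - 1.0) == pytest.approx(1.0)

    @given(st.floats(min_value=0.0, max_value=1e6, allow_nan=False))
    @settings(deadline=None)
    def test_round_trip(self, v):
        assert inverse_log_shift(log_shift(v)) == pytest.approx(v, rel=1e-12, abs=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_shift(-0.5)

    def test_inverse_floors_at_zero(self):
        assert inverse_log_shift(-2.0) == 0.0


class TestPrepareObservations:
    def test_transforms_volume_and_centers_day(self):
        table = make_cohort({"A": {3: 9.58, 7: 0.0}})
        obs = sorted(prepare_observations(table, 0.05), key=lambda o: o.x_day)
        assert obs[0].y == pytest.approx(np.log(10.58))
        assert obs[0].x_day == 0.0 and not obs[0].censored
        assert obs[1].censored and obs[1].x_day == 4.0
        assert obs[1].censor_bound == pytest.approx(np.log1p(0.05))

    def test_empty_table_yields_empty_collection(self):
        table = make_cohort({"A": {3: 1.0}})
        table.measurements = table.measurements.iloc[:0]
        assert prepare_observations(table, 0.05) == []

    def test_one_observation_per_row(self):
        table = make_cohort({"A": {3: 1.0, 5: 2.0}, "B": {3: 0.0}})
        assert len(prepare_observations(table, 0.05)) == 3


def _single_obs(y, x=0.0, censored=False, bound=-1.0):
    return [
        TransformedObservation(
            patient_index=0, y=y, x_day=x, bmi_group="normal",
            censored=censored, censor_bound=bound if censored else -np.inf,
        )
    ]


class TestCensoredLoglik:
    params = ModelParams(
        mu_alpha=0.0, mu_beta=0.0, sigma_alpha=1.0, sigma_beta=1.0, rho=0.0, sigma_y=1.0
    )
    re = RandomEffects(alpha=[1.3], beta=[0.0])

    def test_density_at_mode(self):
        obs = _single_obs(y=1.3)
        assert censored_loglik(self.params, self.re, obs) == pytest.approx(
            np.log(1.0 / np.sqrt(2.0 * np.pi))
        )

    def test_censored_at_mean_gives_log_half(self):
        obs = _single_obs(y=1.3, censored=True, bound=1.3)
        assert censored_loglik(self.params, self.re, obs) == pytest.approx(np.log(0.5))

    def test_uncensored_equals_plain_normal_loglik(self, rng):
        y = rng.normal(size=8)
        x = rng.choice([0.0, 2.0, 4.0], size=8)
        obs = [
            TransformedObservation(0, yi, xi, "normal", False, -np.inf)
            for yi, xi in zip(y, x)
        ]
        re = RandomEffects(alpha=[0.4], beta=[-0.2])
        expected = stats.norm.logpdf(y, loc=0.4 - 0.2 * x, scale=1.0).sum()
        assert censored_loglik(self.params, re, obs) == pytest.approx(expected)

    def test_censored_terms_match_numerical_integration(self):
        """Each censored term equals the integral of the normal density below c."""
        re = RandomEffects(alpha=[0.8], beta=[-0.3])
        sy = 0.6
        params = self.params.replace(sigma_y=sy)
        total = 0.0
        obs = []
        for x, bound in [(0.0, 0.2), (2.0, 0.5), (4.0, -0.1)]:
            obs.append(TransformedObservation(0, bound, x, "normal", True, bound))
            mean = 0.8 - 0.3 * x
            area, _ = integrate.quad(
                lambda t: stats.norm.pdf(t, mean, sy), mean - 12 * sy, bound
            )
            total += np.log(area)
        assert censored_loglik(params, re, obs) == pytest.approx(total, abs=1e-8)

    def test_missing_random_effect_rejected(self):
        obs = [TransformedObservation(3, 0.0, 0.0, "normal", False, -np.inf)]
        with pytest.raises(ValueError, match="random-effect"):
            censored_loglik(self.params, self.re, obs)


def _quadrature_marginal(params, obs_by_patient):
    """Integrate exp(censored_loglik) over the bivariate random-effects law."""
    total = 0.0
    for rows in obs_by_patient.values():
        n_idx = max(o.patient_index for o in rows) + 1
        rv = stats.multivariate_normal(
            mean=[params.mu_alpha, params.mu_beta], cov=params.random_effects_cov()
        )

        def integrand(b, a):
            re = RandomEffects(alpha=np.full(n_idx, a), beta=np.full(n_idx, b))
            return np.exp(censored_loglik(params, re, rows)) * rv.pdf([a, b])

        sa, sb = params.sigma_alpha, params.sigma_beta
        val, _ = integrate.dblquad(
            integrand,
            params.mu_alpha - 8 * sa, params.mu_alpha + 8 * sa,
            lambda a: params.mu_beta - 8 * sb, lambda a: params.mu_beta + 8 * sb,
            epsabs=1e-13, epsrel=1e-11,
        )
        total += np.log(val)
    return total


class TestMarginalLoglik:
    params = ModelParams(
        mu_alpha=1.2, mu_beta=-0.4, sigma_alpha=0.7, sigma_beta=0.3, rho=0.3,
        delta=-0.8, eta=-1.5, sigma_y=0.5,
    )

    def _group_obs(self, obs):
        by_patient = {}
        for o in obs:
            by_patient.setdefault(o.patient_index, []).append(o)
        return by_patient

    def test_matches_quadrature_with_censoring(self):
        table = make_cohort(
            {"A": {3: 4.0, 5: 1.5, 7: 0.0}, "B": {3: 0.0}, "C": {3: 2.0, 5: 0.8, 7: 0.2}},
            bmi={"A": 22.0, "B": 27.0, "C": 31.0},
        )
        obs = prepare_observations(table, 0.05)
        expected = _quadrature_marginal(self.params, self._group_obs(obs))
        assert marginal_loglik(self.params, obs) == pytest.approx(expected, abs=1e-8)

    def test_matches_quadrature_with_two_censored_scans(self):
        """A patient with two zeros exercises the multivariate-CDF branch."""
        table = make_cohort({"A": {3: 3.0, 5: 0.0, 7: 0.0}})
        obs = prepare_observations(table, 0.05)
        oset = ObservationSet(obs)
        assert max(len(b["m_idx"]) for b in oset.buckets) == 2
        expected = _quadrature_marginal(self.params, self._group_obs(obs))
        assert marginal_loglik(self.params, oset) == pytest.approx(expected, abs=1e-7)

    def test_uncensored_equals_multivariate_normal_density(self):
        table = make_cohort({"A": {3: 4.0, 5: 1.5, 7: 0.4}})
        obs = prepare_observations(table, 0.05)
        x = np.array([0.0, 2.0, 4.0])
        Z = np.column_stack([np.ones(3), x])
        cov = Z @ self.params.random_effects_cov() @ Z.T + 0.5**2 * np.eye(3)
        mean = 1.2 - 0.8 - 0.4 * x  # overweight patient (bmi 26.5)
        y = np.log1p([4.0, 1.5, 0.4])
        expected = stats.multivariate_normal(mean, cov).logpdf(y)
        assert marginal_loglik(self.params, obs) == pytest.approx(expected, abs=1e-10)


class TestClosedFormPredictive:
    params = ModelParams(
        mu_alpha=2.0, mu_beta=-0.5, sigma_alpha=0.8, sigma_beta=0.25, rho=0.4,
        delta=-1.0, eta=-2.0, sigma_y=0.4,
    )

    def test_pod3_variance_excludes_slope(self):
        _, var = closed_form_predictive(self.params, "normal", 3)
        assert var == pytest.approx(0.8**2 + 0.4**2)

    def test_uncorrelated_pod4_variance_is_additive(self):
        p = self.params.replace(rho=0.0)
        _, var = closed_form_predictive(p, "obese", 4)
        assert var == pytest.approx(0.8**2 + 0.25**2 + 0.4**2)
        mean, _ = closed_form_predictive(p, "obese", 4)
        assert mean == pytest.approx(2.0 - 0.5 - 2.0)

    def test_monte_carlo_agrees_with_closed_form(self, rng):
        for pod in (3, 5, 7):
            y = draw_new_patient_y(self.params, "overweight", pod, 200_000, rng)
            mean, var = closed_form_predictive(self.params, "overweight", pod)
            assert y.mean() == pytest.approx(mean, abs=4 * np.sqrt(var / len(y)))
            assert y.var() == pytest.approx(var, rel=0.02)

    def test_invalid_pod_rejected(self):
        with pytest.raises(ValueError):
            closed_form_predictive(self.params, "normal", -1)
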