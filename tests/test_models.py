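import dataclasses
import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats
from scipy.optimize import brentq

from collinear import models
from collinear.models import (
    MODEL_IDS,
    NoiseProfile,
    ObserverParams,
    bayes_accept_halfwidth,
    bayes_log_posterior_ratio,
    dataset_log_likelihood,
    effective_criterion,
    free_parameter_count,
    history_criterion,
    p_collinear_response,
    p_right_higher,
    param_space,
    read_params,
    write_params,
)
from collinear.synthetic import COLLINEAR, NONCOLLINEAR, RIGHT_HIGHER

from conftest import make_collinearity_trial, make_height_trial


def brute_force_dstar(x_left, x_right, y, sigma_x, sigma_y, p_common):
    """Independent oracle: numerical integration over the latent positions."""

    def same_contour(z):
        return (
            stats.norm.pdf(x_left, z, sigma_x)
            * stats.norm.pdf(x_right, z, sigma_x)
            * stats.norm.pdf(z, y, sigma_y)
        )

    f1 = integrate.quad(same_contour, y - 12, y + 12)[0]

    def marginal(x):
        return integrate.quad(
            lambda t: stats.norm.pdf(x, t, sigma_x) * stats.norm.pdf(t, y, sigma_y),
            y - 12,
            y + 12,
        )[0]

    f0 = marginal(x_left) * marginal(x_right)
    return math.log(p_common / (1 - p_common)) + math.log(f1) - math.log(f0)


class TestDecisionVariable:
    @pytest.mark.parametrize(
        "x_left,x_right,y,sigma_x",
        [
            (0.3, -0.3, 0.0, 0.5),
            (0.1, 0.2, 0.0, 0.35),
            (5.1, 4.2, 4.8, 1.0),
            (17.0, 16.0, 16.8, 2.0),
        ],
    )
    def test_matches_brute_force_integration(self, x_left, x_right, y, sigma_x):
        expected = brute_force_dstar(x_left, x_right, y, sigma_x, 0.48, 0.5)
        got = bayes_log_posterior_ratio(x_left, x_right, y, sigma_x, 0.48, 0.5)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_symmetric_in_measurements(self):
        a = bayes_log_posterior_ratio(0.7, -0.2, 0.0, 0.5, 0.48, 0.4)
        b = bayes_log_posterior_ratio(-0.2, 0.7, 0.0, 0.5, 0.48, 0.4)
        assert a == pytest.approx(b, abs=1e-12)

    def test_sigma_y_zero_gives_log_prior_ratio(self):
        for p in (0.3, 0.5, 0.8):
            d = bayes_log_posterior_ratio(0.9, -1.3, 0.0, 0.5, 0.0, p)
            assert d == pytest.approx(math.log(p / (1 - p)), abs=1e-10)

    def test_rejects_bad_noise(self):
        with pytest.raises(ValueError):
            bayes_log_posterior_ratio(0.0, 0.0, 0.0, 0.0, 0.48, 0.5)
        with pytest.raises(ValueError):
            bayes_log_posterior_ratio(0.0, 0.0, 0.0, 0.5, -1.0, 0.5)
        with pytest.raises(ValueError):
            bayes_log_posterior_ratio(0.0, 0.0, 0.0, 0.5, 0.48, 1.0)


class TestAcceptHalfwidth:
    def test_matches_bisection_on_dstar(self):
        for v in (0.0, 0.4, 1.1):
            b = bayes_accept_halfwidth(v, 0.0, 0.5, 0.48, 0.5)
            assert np.isfinite(b)

            def dstar_at(u):
                return bayes_log_posterior_ratio(v + u / 2, v - u / 2, 0.0, 0.5, 0.48, 0.5)

            root = brentq(dstar_at, 0.0, 30.0)
            assert float(b) == pytest.approx(root, abs=1e-9)

    def test_boundary_flares_quadratically(self):
        # b(v)^2 - b(y)^2 proportional to (v - y)^2 with nonnegative slope
        y, sx, sy, p = 4.8, 0.6, 0.48, 0.5
        b0 = float(bayes_accept_halfwidth(y, y, sx, sy, p))
        deltas = np.array([0.5, 1.0, 2.0])
        gaps = np.array(
            [float(bayes_accept_halfwidth(y + d, y, sx, sy, p)) ** 2 - b0**2 for d in deltas]
        )
        slopes = gaps / deltas**2
        assert np.all(slopes >= 0)
        assert np.allclose(slopes, slopes[0], rtol=1e-9)

    def test_boundary_depends_on_mean_coordinate(self):
        # the accept region is not a function of the offset alone
        b_near = float(bayes_accept_halfwidth(0.0, 0.0, 0.5, 0.48, 0.5))
        b_far = float(bayes_accept_halfwidth(1.5, 0.0, 0.5, 0.48, 0.5))
        assert b_far > b_near + 1e-3

    def test_empty_region_for_small_prior(self):
        b = bayes_accept_halfwidth(0.0, 0.0, 0.5, 0.48, 0.001)
        assert np.isnan(float(b))


class TestPCollinear:
    def test_fixed_closed_form_example(self, single_level_noise):
        # kappa = sqrt(2) sigma, zero offset -> 2 Phi(1) - 1
        params = ObserverParams(
            model_id="Fixed", noise=single_level_noise, kappa=math.sqrt(2) * 0.5, lapse=0.0
        )
        trial = make_collinearity_trial(0.2, 0.2)
        assert p_collinear_response(params, trial) == pytest.approx(
            2 * stats.norm.cdf(1) - 1, abs=1e-12
        )

    def test_pure_lapse_is_half(self, single_level_noise):
        for model_id, extra in [
            ("Fixed", {"kappa": 1.0}),
            ("Bayes", {"p_common": 0.4}),
            ("Lin", {"kappa0": 0.5, "kappa1": 0.5}),
        ]:
            params = ObserverParams(model_id=model_id, noise=single_level_noise, lapse=1.0, **extra)
            assert p_collinear_response(params, make_collinearity_trial(0.3, -0.2)) == pytest.approx(0.5)

    def test_lin_zero_slope_equals_fixed(self, noise):
        trial = make_collinearity_trial(0.4, -0.1, eccentricity=4.8)
        lin = ObserverParams(model_id="Lin", noise=noise, kappa0=0.8, kappa1=0.0, lapse=0.02)
        fixed = ObserverParams(model_id="Fixed", noise=noise, kappa=0.8, lapse=0.02)
        assert p_collinear_response(lin, trial) == p_collinear_response(fixed, trial)

    def test_bayes_matches_monte_carlo(self, single_level_noise):
        params = ObserverParams(
            model_id="Bayes", noise=single_level_noise, p_common=0.5, lapse=0.0, sigma_y=0.48
        )
        trial = make_collinearity_trial(0.25, -0.15)
        p = p_collinear_response(params, trial)
        rng = np.random.default_rng(0)
        n = 400_000
        xl = rng.normal(trial.y_left, 0.5, n)
        xr = rng.normal(trial.y_right, 0.5, n)
        d = bayes_log_posterior_ratio(xl, xr, 0.0, 0.5, 0.48, 0.5)
        p_mc = float(np.mean(d >= 0))
        assert abs(p - p_mc) < 3 * math.sqrt(p_mc * (1 - p_mc) / n)

    def test_negative_criterion_clipped_to_zero_probability(self, single_level_noise):
        params = ObserverParams(model_id="Lin", noise=single_level_noise, kappa0=-2.0, kappa1=0.0, lapse=0.0)
        assert p_collinear_response(params, make_collinearity_trial(0.0, 0.0)) == 0.0

    @given(
        delta=st.floats(min_value=0.0, max_value=3.0),
        widen=st.floats(min_value=0.01, max_value=2.0),
        kappa=st.floats(min_value=0.0, max_value=4.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_fixed_monotone_in_offset(self, delta, widen, kappa):
        noise = NoiseProfile((0.0,), (0.7,))
        params = ObserverParams(model_id="Fixed", noise=noise, kappa=kappa, lapse=0.0)
        near = p_collinear_response(params, make_collinearity_trial(delta / 2, -delta / 2))
        far = p_collinear_response(
            params, make_collinearity_trial((delta + widen) / 2, -(delta + widen) / 2)
        )
        assert far <= near + 1e-12

    @given(
        lapse=st.floats(min_value=0.0, max_value=1.0),
        y_left=st.floats(min_value=-1.5, max_value=1.5),
        y_right=st.floats(min_value=-1.5, max_value=1.5),
        p_common=st.floats(min_value=0.15, max_value=0.85),
    )
    @settings(max_examples=50, deadline=None)
    def test_probability_bounded_by_lapse_mixture(self, lapse, y_left, y_right, p_common):
        noise = NoiseProfile((0.0,), (0.6,))
        params = ObserverParams(
            model_id="Bayes", noise=noise, lapse=lapse, p_common=p_common, sigma_y=0.48
        )
        p = p_collinear_response(params, make_collinearity_trial(y_left, y_right))
        assert lapse / 2 - 1e-12 <= p <= 1 - lapse / 2 + 1e-12

    def test_height_trial_rejected(self, single_level_noise):
        params = ObserverParams(model_id="Fixed", noise=single_level_noise, kappa=1.0)
        with pytest.raises(ValueError):
            p_collinear_response(params, make_height_trial(0.1, 0.3))


class TestModelEquivalences:
    def test_noise_mismatch_identity_equals_bayes(self, noise):
        trial = make_collinearity_trial(0.3, -0.2, eccentricity=9.6)
        mismatch = ObserverParams(
            model_id="NoiseMismatch", noise=noise, mm_a=0.0, mm_b=1.0, p_common=0.5, lapse=0.0
        )
        bayes = ObserverParams(model_id="Bayes", noise=noise, p_common=0.5, lapse=0.0)
        assert p_collinear_response(mismatch, trial) == pytest.approx(
            p_collinear_response(bayes, trial), abs=1e-12
        )

    def test_width_mismatch_identity_equals_bayes(self, noise):
        trial = make_collinearity_trial(0.1, -0.4, eccentricity=4.8)
        mismatch = ObserverParams(
            model_id="WidthMismatch", noise=noise, sigma_y_assumed=0.48, p_common=0.6, lapse=0.0
        )
        bayes = ObserverParams(model_id="Bayes", noise=noise, p_common=0.6, lapse=0.0)
        assert p_collinear_response(mismatch, trial) == pytest.approx(
            p_collinear_response(bayes, trial), abs=1e-12
        )

    def test_decision_noise_converges_to_bayes(self, noise):
        trial = make_collinearity_trial(0.2, -0.1, eccentricity=0.0)
        bayes = ObserverParams(model_id="Bayes", noise=noise, p_common=0.5, lapse=0.0)
        dn = ObserverParams(model_id="BayesDN", noise=noise, p_common=0.5, lapse=0.0, sigma_d=1e-4)
        assert p_collinear_response(dn, trial) == pytest.approx(
            p_collinear_response(bayes, trial), abs=1e-4
        )


class TestPRightHigher:
    def test_equal_heights_give_half(self, single_level_noise):
        params = ObserverParams(model_id="HeightJudgment", noise=single_level_noise, lapse=0.0)
        assert p_right_higher(params, make_height_trial(0.3, 0.3)) == pytest.approx(0.5)

    def test_normal_cdf_oracle(self, single_level_noise):
        # offset sqrt(2) sigma -> Phi(1)
        params = ObserverParams(model_id="HeightJudgment", noise=single_level_noise, lapse=0.0)
        offset = math.sqrt(2) * 0.5
        trial = make_height_trial(0.0, offset)
        assert p_right_higher(params, trial) == pytest.approx(stats.norm.cdf(1), abs=1e-12)

    def test_pure_lapse(self, single_level_noise):
        params = ObserverParams(model_id="HeightJudgment", noise=single_level_noise, lapse=1.0)
        assert p_right_higher(params, make_height_trial(0.0, 2.0)) == pytest.approx(0.5)


class TestDatasetLogLikelihood:
    def test_single_trial_half(self, single_level_noise):
        params = ObserverParams(model_id="Fixed", noise=single_level_noise, kappa=1.0, lapse=1.0)
        trial = make_collinearity_trial(0.1, -0.1, response=COLLINEAR)
        assert dataset_log_likelihood(params, [trial]) == pytest.approx(math.log(0.5))

    def test_concatenation_additivity(self, noise, design):
        from collinear.synthetic import generate_collinearity_trials, simulate_responses

        params = ObserverParams(model_id="Lin", noise=noise, kappa0=0.3, kappa1=0.6, lapse=0.05)
        a = simulate_responses(params, generate_collinearity_trials(design, 40, 0), 1)
        b = simulate_responses(params, generate_collinearity_trials(design, 30, 2), 3)
        assert dataset_log_likelihood(params, a + b) == pytest.approx(
            dataset_log_likelihood(params, a) + dataset_log_likelihood(params, b), abs=1e-9
        )

    def test_matches_naive_per_trial_product(self, single_level_noise):
        # independently coded oracle using scipy's normal CDF directly
        kappa, sigma, lapse = 0.9, 0.5, 0.08
        params = ObserverParams(model_id="Fixed", noise=single_level_noise, kappa=kappa, lapse=lapse)
        rng = np.random.default_rng(5)
        trials = []
        expected = 0.0
        pointwise_expected = []
        for i in range(10):
            yl, yr = rng.normal(0, 0.48, 2)
            resp = COLLINEAR if i % 2 == 0 else NONCOLLINEAR
            trials.append(make_collinearity_trial(yl, yr, response=resp))
            delta = yl - yr
            scale = math.sqrt(2) * sigma
            p_rule = stats.norm.cdf((kappa - delta) / scale) - stats.norm.cdf((-kappa - delta) / scale)
            p = lapse / 2 + (1 - lapse) * p_rule
            term = math.log(p if resp == COLLINEAR else 1 - p)
            expected += term
            pointwise_expected.append(term)
        total, pointwise = dataset_log_likelihood(params, trials, pointwise=True)
        assert total == pytest.approx(expected, abs=1e-10)
        assert pointwise == pytest.approx(pointwise_expected, abs=1e-10)

    def test_zero_probability_gives_neg_inf(self, single_level_noise):
        params = ObserverParams(model_id="Lin", noise=single_level_noise, kappa0=-1.0, kappa1=0.0, lapse=0.0)
        trial = make_collinearity_trial(0.0, 0.0, response=COLLINEAR)
        assert dataset_log_likelihood(params, [trial]) == -np.inf

    def test_missing_response_rejected(self, single_level_noise):
        params = ObserverParams(model_id="Fixed", noise=single_level_noise, kappa=1.0)
        with pytest.raises(ValueError):
            dataset_log_likelihood(params, [make_collinearity_trial(0.1, 0.2)])


class TestHistoryCriterion:
    def _params(self, noise, weights, kappa0=0.2):
        return ObserverParams(
            model_id="History", noise=noise, kappa0=kappa0, history_weights=weights, lapse=0.0
        )

    def _sequence(self, eccs):
        return [
            make_collinearity_trial(0.0, 0.0, eccentricity=e) for e in eccs
        ]

    def test_only_current_weight_reduces_to_lin(self, noise):
        params = self._params(noise, (0.7, 0.0, 0.0, 0.0, 0.0), kappa0=0.1)
        trials = self._sequence([0.0, 9.6, 16.8, 4.8])
        lin = ObserverParams(model_id="Lin", noise=noise, kappa0=0.1, kappa1=0.7, lapse=0.0)
        assert effective_criterion(params, trials) == pytest.approx(
            effective_criterion(lin, trials)
        )

    def test_constant_sequence(self, noise):
        weights = (0.5, 0.4, 0.3, 0.2, 0.1)
        params = self._params(noise, weights)
        trials = self._sequence([4.8] * 8)
        expected = 0.2 + 0.55 * sum(weights)
        assert effective_criterion(params, trials) == pytest.approx([expected] * 8)

    def test_hand_computed_six_trial_sequence(self, noise):
        # sigma sequence: 0.35, 1.0, 2.0, 0.55, 0.35, 1.0
        params = self._params(noise, (0.5, 0.4, 0.3, 0.2, 0.1))
        trials = self._sequence([0.0, 9.6, 16.8, 4.8, 0.0, 9.6])
        # trial 5 (full history): 0.2 + .5*1.0 + .4*0.35 + .3*0.55 + .2*2.0 + .1*1.0
        assert history_criterion(params, trials, 5) == pytest.approx(
            0.2 + 0.5 * 1.0 + 0.4 * 0.35 + 0.3 * 0.55 + 0.2 * 2.0 + 0.1 * 1.0
        )
        # trial 1 (padded with current trial's sigma = 1.0 for lags 2..4)
        assert history_criterion(params, trials, 1) == pytest.approx(
            0.2 + 0.5 * 1.0 + 0.4 * 0.35 + (0.3 + 0.2 + 0.1) * 1.0
        )
        # vectorized path agrees
        assert effective_criterion(params, trials)[5] == pytest.approx(
            history_criterion(params, trials, 5)
        )

    def test_mixed_sessions_rejected(self, noise):
        params = self._params(noise, (0.5, 0.1, 0.0, 0.0, 0.0))
        trials = self._sequence([0.0, 4.8, 0.0])
        trials[1] = dataclasses.replace(trials[1], session=2)
        with pytest.raises(ValueError):
            history_criterion(params, trials, 2)
        trials_interleaved = self._sequence([0.0, 4.8, 0.0, 4.8])
        trials_interleaved[1] = dataclasses.replace(trials_interleaved[1], session=2)
        with pytest.raises(ValueError):
            effective_criterion(params, trials_interleaved)


class TestParamSpaces:
    EXPECTED_FREE = {
        "Fixed": 6,
        "Bayes": 6,
        "Lin": 7,
        "NoiseMismatch": 7,
        "WidthMismatch": 7,
        "BayesDN": 7,
        "HybridDNWidth": 8,
        "Nonparametric": 9,
        "History": 11,
        "HeightJudgment": 5,
    }
    EXPECTED_CONSTRAINED = {"Fixed": 2, "Bayes": 2, "Lin": 3}

    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_free_parameter_counts(self, model_id):
        assert free_parameter_count(model_id) == self.EXPECTED_FREE[model_id]

    @pytest.mark.parametrize("model_id", ["Fixed", "Bayes", "Lin"])
    def test_constrained_parameter_counts(self, model_id):
        assert free_parameter_count(model_id, constrained=True) == self.EXPECTED_CONSTRAINED[model_id]

    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_vector_round_trip(self, model_id, design):
        space = param_space(model_id, design.eccentricity_levels)
        rng = np.random.default_rng(hash(model_id) % 2**32)
        lo = np.array([e.lower for e in space.entries])
        hi = np.array([e.upper for e in space.entries])
        theta = rng.uniform(np.where(lo > -np.inf, lo, -1), hi)
        # keep criteria positive so validation passes
        theta = np.clip(theta, np.where([e.name.startswith("sigma") for e in space.entries], 0.06, lo), hi)
        params = space.to_params(theta)
        assert space.from_params(params) == pytest.approx(theta)


class TestParamFiles:
    @pytest.mark.parametrize(
        "params_kwargs",
        [
            {"model_id": "Fixed", "kappa": 1.25, "lapse": 0.04},
            {"model_id": "Lin", "kappa0": 0.3, "kappa1": 0.6, "lapse": 0.03},
            {"model_id": "Bayes", "p_common": 0.55, "lapse": 0.02, "sigma_y": 0.48},
            {
                "model_id": "History",
                "kappa0": 0.2,
                "history_weights": (0.5, 0.1, -0.1, 0.0, 0.2),
            },
            {"model_id": "Nonparametric", "level_criteria": (0.4, 0.6, 1.0, 1.7)},
            {"model_id": "HybridDNWidth", "sigma_y_assumed": 0.7, "sigma_d": 1.1},
        ],
    )
    def test_round_trip(self, noise, params_kwargs):
        params = ObserverParams(noise=noise, **params_kwargs)
        buffer = io.StringIO()
        write_params(buffer, params)
        buffer.seek(0)
        assert read_params(buffer) == params

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            read_params(io.StringIO("model_id = Fixed\nbogus = 1\nnoise[0.0] = 0.5\n"))
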