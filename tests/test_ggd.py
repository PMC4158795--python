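"""Generalized-Gaussian model and discriminant-unit mathematics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from hdsn.ggd import (
    EstimatorPrior,
    GGDClassModel,
    RectifierParams,
    expected_saliency,
    ggd_pdf,
    log_likelihood_ratio,
    map_scale_estimate,
    parametric_relu,
    rectifier_from_model,
    target_posterior,
)
from hdsn.synth import sample_ggd

REF_MODEL = GGDClassModel(scale_pow_background=1.0, scale_pow_target=2.0, shape=0.5)


class TestGGDPdf:
    @pytest.mark.parametrize("x, scale, shape, expected", [
        (0.0, 1.0, 1.0, 0.5),                      # Laplace mode
        (0.0, 1.0, 2.0, 1.0 / np.sqrt(np.pi)),     # Gaussian mode
    ])
    def test_mode_values(self, x, scale, shape, expected):
        assert ggd_pdf(x, scale, shape) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("shape", [0.5, 1.0, 2.0])
    def test_normalization(self, shape):
        # beta=0.5 has heavy tails (P(|X|>50) ~ 7e-3 at alpha=1), so the
        # integral must extend over the full line to reach 1e-6 accuracy
        val, _ = quad(lambda x: ggd_pdf(x, 1.0, shape), 0, np.inf, limit=400)
        assert 2 * val == pytest.approx(1.0, abs=1e-6)

    def test_symmetry(self, rng):
        x = rng.standard_normal(50) * 3
        assert np.allclose(ggd_pdf(x, 1.3, 0.7), ggd_pdf(-x, 1.3, 0.7))

    @pytest.mark.parametrize("scale, shape", [(-1, 1), (0, 1), (1, 0), (1, -2)])
    def test_invalid_parameters(self, scale, shape):
        with pytest.raises(ValueError):
            ggd_pdf(0.0, scale, shape)


class TestMapScaleEstimate:
    def test_prior_only(self):
        # kappa = eta*beta = 0.5, so the empty-sample estimate is nu/kappa
        assert map_scale_estimate([], shape=0.5) == pytest.approx(2e-3)

    def test_hand_case(self):
        # (|1|^0.5 + |4|^0.5 + nu) / (2 + 0.5) = 1.2004
        assert map_scale_estimate([1.0, 4.0], shape=0.5) == pytest.approx(1.2004)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0, 4.0])
    def test_recovers_closed_form_moment(self, alpha):
        # the estimator targets E|X|^beta = alpha^beta / beta
        x = sample_ggd(alpha, 0.5, 100_000, seed=101)
        est = map_scale_estimate(x, shape=0.5)
        assert est == pytest.approx(alpha**0.5 / 0.5, rel=0.03)

    def test_monotone_in_sample_magnitudes(self):
        lo = map_scale_estimate([1.0, 2.0], shape=0.5)
        hi = map_scale_estimate([1.0, 3.0], shape=0.5)
        assert hi > lo

    def test_nonfinite_samples_rejected(self):
        with pytest.raises(ValueError):
            map_scale_estimate([1.0, np.inf])

    def test_prior_disabled_is_plain_mean(self):
        x = np.array([1.0, 4.0, 9.0])
        est = map_scale_estimate(x, shape=0.5, prior=None)
        assert est == pytest.approx(np.mean(np.abs(x) ** 0.5))

    def test_invalid_prior(self):
        with pytest.raises(ValueError):
            EstimatorPrior(eta=0.0)


class TestLLRAndRectifier:
    def test_hand_llr(self):
        # gamma=0.5, T=log 4; g(16) = 0.5*4 - log 4
        assert log_likelihood_ratio(16.0, REF_MODEL) == pytest.approx(
            2.0 - np.log(4.0), abs=1e-12)

    def test_identical_classes_silent(self):
        m = GGDClassModel(scale_pow_background=1.7, scale_pow_target=1.7, shape=0.5)
        x = np.linspace(-20, 20, 101)
        assert np.all(log_likelihood_ratio(x, m) == 0.0)
        r = rectifier_from_model(m)
        assert r.gain == 0.0 and r.threshold == 0.0
        assert np.all(parametric_relu(x, r) == 0.0)

    def test_llr_even(self, rng):
        x = rng.standard_normal(64) * 5
        assert np.allclose(log_likelihood_ratio(x, REF_MODEL),
                           log_likelihood_ratio(-x, REF_MODEL))

    def test_rectifier_presence_case(self):
        r = rectifier_from_model(REF_MODEL)
        assert r.gain == pytest.approx(0.5)
        assert r.threshold == pytest.approx(np.log(4.0))

    def test_rectifier_absence_case(self):
        m = GGDClassModel(scale_pow_background=2.0, scale_pow_target=1.0, shape=0.5)
        r = rectifier_from_model(m)
        assert r.gain == pytest.approx(-0.5)
        assert r.threshold == pytest.approx(-np.log(4.0))

    def test_gain_threshold_sign_invariant(self):
        with pytest.raises(ValueError):
            RectifierParams(gain=0.5, threshold=-0.1, shape=0.5)
        with pytest.raises(ValueError):
            RectifierParams(gain=0.0, threshold=0.3, shape=0.5)

    def test_dead_zone_presence(self):
        r = rectifier_from_model(REF_MODEL)  # gamma=0.5, T=log4
        edge = (r.threshold / r.gain) ** (1 / 0.5)  # ~7.6874
        assert edge == pytest.approx(7.6874, abs=1e-3)
        assert parametric_relu(0.99 * edge, r) == 0.0
        assert parametric_relu(1.01 * edge, r) > 0.0
        assert parametric_relu(16.0, r) == pytest.approx(2.0 - np.log(4.0))

    def test_dead_zone_absence(self):
        m = GGDClassModel(scale_pow_background=2.0, scale_pow_target=1.0, shape=0.5)
        r = rectifier_from_model(m)
        # absence detector: responds at zero, silent for large responses
        assert parametric_relu(0.0, r) == pytest.approx(np.log(4.0))
        edge_u = r.threshold / r.gain  # in |x|^beta space: ~2.7726
        assert edge_u == pytest.approx(2 * np.log(4.0), abs=1e-12)
        x_out = (1.01 * edge_u) ** 2
        assert parametric_relu(x_out, r) == 0.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a0=st.floats(0.25, 4.0), a1=st.floats(0.25, 4.0),
           beta=st.floats(0.3, 2.0), x=st.floats(-10.0, 10.0))
    def test_rectifier_equals_rectified_llr(self, a0, a1, beta, x):
        m = GGDClassModel(scale_pow_background=a0, scale_pow_target=a1, shape=beta)
        r = rectifier_from_model(m)
        g = log_likelihood_ratio(x, m)
        assert parametric_relu(x, r) == pytest.approx(max(g, 0.0), abs=1e-12)


class TestPosterior:
    def test_midpoint(self):
        m = GGDClassModel(scale_pow_background=1.0, scale_pow_target=1.0)
        assert target_posterior(3.0, m) == 0.5

    def test_hand_value(self):
        assert target_posterior(16.0, REF_MODEL) == pytest.approx(0.6488, abs=1e-4)

    def test_open_interval_and_large_response_dominance(self, rng):
        x = rng.standard_normal(100) * 10
        p = target_posterior(x, REF_MODEL)
        assert np.all((p > 0) & (p < 1))
        # heavier-tailed target: the posterior approaches 1 for extreme responses
        assert target_posterior(1e6, REF_MODEL) > 0.999


class TestExpectedSaliency:
    def test_matched_classes_zero(self):
        m = GGDClassModel(scale_pow_background=1.5, scale_pow_target=1.5)
        assert expected_saliency(m, 3.0) == 0.0

    def test_affine_root(self):
        # gamma=0.5, T=log4: root of gamma*u - T at u = 2 log 4
        assert expected_saliency(REF_MODEL, 2 * np.log(4.0)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_mean_llr_under_target(self):
        r = rectifier_from_model(REF_MODEL)
        alpha1 = REF_MODEL.scale_pow_target ** (1 / 0.5)
        x = sample_ggd(alpha1, 0.5, 100_000, seed=77)
        mean_llr = np.mean(log_likelihood_ratio(x, REF_MODEL))
        closed = r.gain * REF_MODEL.scale_pow_target / 0.5 - r.threshold
        assert mean_llr == pytest.approx(closed, rel=0.02)

    def test_nonpositive_local_scale_rejected(self):
        with pytest.raises(ValueError):
            expected_saliency(REF_MODEL, 0.0)


def test_class_model_serialization_roundtrip():
    d = REF_MODEL.to_dict()
    assert GGDClassModel.from_dict(d) == REF_MODEL
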