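"""Free-response closed forms: decision-state inversion, phi posterior, moments."""

import numpy as np
import pytest
from scipy.integrate import simpson

from ddmconf import (
    InvalidTrialError,
    ThresholdSpec,
    decision_state,
    derived_stats,
    free_confidence_dist,
    free_confidence_matrix,
    free_moments,
    generate_frames,
    phi_posterior,
    sufficient_stats,
    theta,
)
from ddmconf.oracle import pipeline_mc_check


class TestDecisionState:
    def test_inversion(self, params):
        p = params.replace(threshold=ThresholdSpec("constant", (2.0,)))
        ds = decision_state(2, 0.8, p)
        assert ds.t_d == pytest.approx(0.8 - p.pipeline_I)
        assert ds.x_d == 2.0 and ds.L == 1
        ds1 = decision_state(1, 0.8, p)
        assert ds1.x_d == -2.0 and ds1.L == -1

    def test_time_dependent_threshold(self, params):
        p = params.replace(threshold=ThresholdSpec("linear", (2.0, 1.0, 0.5)))
        ds = decision_state(2, 1.1, p)
        assert ds.x_d == pytest.approx(2.0 - 1.0 * 1.0)

    def test_response_before_pipeline_clears_is_invalid(self, params):
        with pytest.raises(InvalidTrialError):
            decision_state(2, 0.05, params)  # t_r <= I = 0.1


class TestPhiPosterior:
    def test_degenerate_prior(self, params):
        p0 = params.replace(sigma_phi=0.0)
        post = phi_posterior(decision_state(2, 0.8, p0), 1.3, p0)
        assert (post.m_phi, post.v_phi) == (1.0, 0.0)

    def test_uninformative_evidence_returns_prior(self, params):
        post = phi_posterior(decision_state(2, 0.8, params), 0.0, params)
        assert post.m_phi == pytest.approx(1.0)
        assert post.v_phi == pytest.approx(params.sigma_phi**2)

    @pytest.mark.parametrize("E_bar,R", [(1.4, 2), (-0.6, 2), (0.9, 1), (3.0, 2)])
    def test_matches_grid_normalisation(self, params, E_bar, R):
        """Posterior mean/variance vs numeric normalisation of
        prior(phi) * N(phi; x_d/(E_bar t_d), sigma_acc^2/(E_bar^2 t_d))."""
        ds = decision_state(R, 0.7, params)
        post = phi_posterior(ds, E_bar, params)
        phi = np.linspace(-25, 27, 2_000_001)
        log_w = -0.5 * (phi - 1.0) ** 2 / params.sigma_phi**2
        log_w += -0.5 * (phi - ds.x_d / (E_bar * ds.t_d)) ** 2 / (
            params.sigma_acc**2 / (E_bar**2 * ds.t_d)
        )
        w = np.exp(log_w - log_w.max())
        Z = simpson(w, x=phi)
        m = simpson(w * phi, x=phi) / Z
        v = simpson(w * phi**2, x=phi) / Z - m**2
        assert post.m_phi == pytest.approx(m, abs=1e-8)
        assert post.v_phi == pytest.approx(v, abs=1e-8)

    def test_variance_never_exceeds_prior(self, params, rng):
        for _ in range(50):
            ds = decision_state(int(rng.integers(1, 3)), rng.uniform(0.15, 3.0), params)
            post = phi_posterior(ds, rng.normal(0, 3), params)
            assert 0.0 <= post.v_phi <= params.sigma_phi**2 + 1e-15


class TestFreeMoments:
    def test_no_scaling_variability_reduction(self, params, stim):
        """With sigma_phi = 0 the pipeline term reduces to delta_E itself."""
        p0 = params.replace(sigma_phi=0.0)
        ds = decision_state(2, 0.8, p0)
        fr = generate_frames(0.12, stim, 40, rng=2)
        st_ = sufficient_stats(fr, ds.t_d, 0.8)
        fm = free_moments(ds, st_, 0.8, p0, stim)
        th = theta(0.8, derived_stats(stim, p0))
        assert fm.mu_lf == pytest.approx((ds.x_d + st_.delta_E) / th, abs=1e-12)
        assert fm.sigma_lf2 == pytest.approx(p0.sigma_acc**2 * p0.pipeline_I / th**2)

    def test_no_pipeline_degenerates(self, params, stim):
        p = params.replace(pipeline_I=0.0)
        ds = decision_state(2, 0.6, p)
        fr = generate_frames(0.12, stim, 40, rng=3)
        st_ = sufficient_stats(fr, 0.6, 0.6)
        fm = free_moments(ds, st_, 0.6, p, stim)
        assert fm.mu_lf == pytest.approx(ds.x_d / theta(0.6, derived_stats(stim, p)))
        assert fm.sigma_lf2 == 0.0

    def test_pipeline_monte_carlo(self, params, stim):
        """Step-level pipeline continuations at fixed phi reproduce the
        conditional mean (x_d + phi delta_E)/theta and variance sigma_acc^2 I / theta^2."""
        fr = generate_frames(0.12, stim, 40, rng=4)
        t_d, I = 0.5, params.pipeline_I
        st_ = sufficient_stats(fr, t_d, t_d + I)
        th = theta(t_d + I, derived_stats(stim, params))
        for phi in (0.6, 1.3):
            mc = pipeline_mc_check(1.0, phi, fr, t_d, I, params, stim, n=100_000, seed=9)
            assert mc["mean"] == pytest.approx(
                (1.0 + phi * st_.delta_E) / th, abs=3 * mc["se_mean"]
            )
            assert mc["var"] == pytest.approx(
                params.sigma_acc**2 * I / th**2, abs=3 * mc["se_var"]
            )


class TestFreeConfidenceDist:
    def test_normalises_and_mirror(self, params, stim, rng):
        n = 40
        R = rng.integers(1, 3, n)
        t_r = rng.uniform(0.2, 3.0, n)
        E_bar = rng.normal(0, 2, n)
        dE = rng.normal(0, 0.5, n)
        p = free_confidence_matrix(R, t_r, E_bar, dE, params, stim)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(p >= 0)
        q = free_confidence_matrix(3 - R, t_r, -E_bar, -dE, params, stim)
        np.testing.assert_allclose(p, q, atol=1e-12)

    def test_frames_route_equals_stats_route(self, params, stim):
        fr = generate_frames(0.12, stim, 40, rng=5)
        t_r = 0.6
        a = free_confidence_dist(2, t_r, fr, params, stim).probabilities
        st_ = sufficient_stats(fr, t_r - params.pipeline_I, t_r)
        b = free_confidence_matrix([2], [t_r], [st_.E_bar], [st_.delta_E], params, stim)[0]
        np.testing.assert_allclose(a, b, atol=1e-14)

    def test_degenerate_variance_gives_point_mass(self, params, stim):
        p = params.replace(sigma_m=0.0, sigma_phi=0.0, pipeline_I=0.0)
        dist = free_confidence_dist(2, 0.6, None if False else _stats_zero(), p, stim)
        assert set(np.unique(dist.probabilities)) <= {0.0, 1.0}
        assert dist.probabilities.sum() == 1.0

    def test_pipeline_evidence_toward_choice_raises_confidence(self, params, stim):
        """Larger delta_E in the choice direction never lowers mu_lf when the
        inferred drift-rate scaling is positive (monotone mean category)."""
        dE = np.linspace(-1, 1, 21)
        p = free_confidence_matrix(
            np.full(21, 2), np.full(21, 0.6), np.full(21, 1.0), dE, params, stim
        )
        mean_cat = (p * np.arange(p.shape[1])).sum(axis=1)
        assert np.all(np.diff(mean_cat) > -1e-12)

    def test_censored_timing_propagates_error(self, params, stim):
        with pytest.raises(InvalidTrialError):
            free_confidence_matrix([2], [0.05], [1.0], [0.0], params, stim)


def _stats_zero():
    from ddmconf import SufficientStats

    return SufficientStats(E=1.0, E_pre=1.0, E_bar=2.0, delta_E=0.0)
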