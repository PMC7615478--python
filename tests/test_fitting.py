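"""Trial-level likelihood and maximum-likelihood fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri

from ddmconf import ConfidenceModel, FitSpec, SimConfig, recovery_study, simulate_free
from ddmconf.model import _pack, _unpack


def mirror_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Flip all frame signs: swap S and R labels, negate evidence summaries."""
    t = trials.copy()
    t["S"] = 3 - t["S"]
    t["R"] = np.where(t["R"] > 0, 3 - t["R"], t["R"])
    for col in ("E", "E_pre", "E_bar", "delta_E"):
        t[col] = -t[col]
    return t


@pytest.fixture
def free_data(params, stim):
    trials, _ = simulate_free(params, stim, SimConfig(n_trials=3000, seed=17))
    return trials


class TestNll:
    def test_uniform_prediction_gives_log_ncat(self, params, stim):
        """A trial engineered so the predictive distribution is uniform over
        the 4 categories contributes exactly log 4."""
        p = params.replace(sigma_phi=0.0)
        sd_tot = np.sqrt(p.sigma_acc**2 * p.pipeline_I + p.sigma_m**2)
        p = p.replace(boundaries=tuple(sd_tot * ndtri([0.25, 0.5, 0.75])))
        # delta_E = -x_d makes mu_lf = 0 (m_phi = 1 when sigma_phi = 0)
        trial = pd.DataFrame({
            "trial_id": [0], "condition": ["free"], "S": [2], "R": [2], "C": [1],
            "t_r": [0.6], "t_e": [0.6], "t_d": [0.5], "censored": [False],
            "E": [1.0], "E_pre": [2.0], "E_bar": [4.0], "delta_E": [-1.0],
        })
        m = ConfidenceModel(trial, stim)
        assert m.nll(p) == pytest.approx(np.log(4), abs=1e-9)

    def test_additivity_under_duplication(self, free_data, params, stim):
        m1 = ConfidenceModel(free_data, stim)
        m2 = ConfidenceModel(pd.concat([free_data, free_data]), stim)
        assert m2.nll(params) == pytest.approx(2 * m1.nll(params), rel=1e-12)

    def test_mirror_invariance(self, free_data, params, stim):
        m = ConfidenceModel(free_data, stim)
        mm = ConfidenceModel(mirror_trials(free_data), stim)
        assert mm.nll(params) == pytest.approx(m.nll(params), rel=1e-12)

    def test_censored_trials_excluded_with_count(self, free_data, params, stim):
        t = free_data.copy()
        t.loc[t.index[:5], "censored"] = True
        m = ConfidenceModel(t, stim)
        assert m.n_censored == 5
        assert m.nobs == len(t) - 5

    def test_likelihood_dominance_at_truth(self, params, stim):
        """Mean NLL at the generating parameters is below the NLL with the
        metacognitive noise doubled, across replicate datasets."""
        diffs = []
        for seed in range(5):
            trials, _ = simulate_free(params, stim, SimConfig(n_trials=2000, seed=100 + seed))
            m = ConfidenceModel(trials, stim)
            diffs.append(m.nll(params.replace(sigma_m=2 * params.sigma_m)) - m.nll(params))
        assert np.mean(diffs) > 0

    def test_misspecified_scaling_variability_fits_worse(self, params, stim):
        trials, _ = simulate_free(params, stim, SimConfig(n_trials=4000, seed=23))
        m = ConfidenceModel(trials, stim)
        assert m.nll(params) < m.nll(params.replace(sigma_phi=0.0))


class TestFit:
    def test_all_fixed_returns_inputs(self, free_data, params, stim):
        m = ConfidenceModel(free_data, stim)
        res = m.fit(params, free=())
        assert res.params == params
        assert res.nll == pytest.approx(m.nll(params))

    def test_transform_roundtrip(self, params):
        free = ("sigma_acc", "sigma_m", "boundaries", "threshold")
        v = _pack(params, free)
        p2 = _unpack(v, params, free)
        assert p2.sigma_acc == pytest.approx(params.sigma_acc)
        assert p2.boundaries == pytest.approx(params.boundaries)
        assert p2.threshold.params == pytest.approx(params.threshold.params)

    def test_short_fit_improves_on_perturbed_start(self, free_data, params, stim):
        m = ConfidenceModel(free_data, stim)
        start = params.replace(sigma_m=0.8)
        res = m.fit(start, free=("sigma_m",), n_restarts=1, maxiter=300)
        assert res.nll <= m.nll(start)
        assert abs(res.params.sigma_m - params.sigma_m) < abs(0.8 - params.sigma_m)

    def test_profile_in_sigma_m_locally_convex(self, params, stim):
        """The sigma_m profile NLL on a 9-point grid around truth is
        single-dipped near the generating value."""
        trials, _ = simulate_free(params, stim, SimConfig(n_trials=4000, seed=29))
        m = ConfidenceModel(trials, stim)
        grid = params.sigma_m * np.linspace(0.5, 1.8, 9)
        nll = [m.nll(params.replace(sigma_m=s)) for s in grid]
        k = int(np.argmin(nll))
        assert 0 < k < 8
        assert all(nll[i] >= nll[i + 1] for i in range(k))
        assert all(nll[i] <= nll[i + 1] for i in range(k, 8))

    def test_summary_mentions_estimates(self, free_data, params, stim):
        m = ConfidenceModel(free_data, stim)
        res = m.fit(params, free=())
        s = res.summary()
        assert "negative log-likelihood" in s

    def test_pipeline_not_fittable_from_interrogation(self, params, stim):
        from ddmconf import simulate_interrogation
        trials, _ = simulate_interrogation(params, stim, 20, SimConfig(n_trials=200, seed=1))
        m = ConfidenceModel(trials, stim)
        with pytest.raises(ValueError):
            m.fit(params, free=("pipeline_I",))


class TestRecoveryStudy:
    def test_table_rows_match_free_scalars(self, params, stim):
        spec = FitSpec(free=("sigma_m", "boundaries"), n_restarts=1, maxiter=200, seed=0)
        tab = recovery_study(params, stim, SimConfig(n_trials=800, seed=31), spec)
        assert len(tab) == 1 + len(params.boundaries)
        assert set(tab["name"]) == {"sigma_m", "d_1", "d_2", "d_3"}

    def test_error_shrinks_with_sample_size(self, params, stim):
        """Median absolute error of sigma_m decreases from n=500 to n=8000."""
        spec = FitSpec(free=("sigma_m",), n_restarts=1, maxiter=400, seed=0)
        start = params.replace(sigma_m=0.6)
        errs = {}
        for n in (500, 8000):
            e = []
            for seed in (41, 43, 47):
                tab = recovery_study(params, stim, SimConfig(n_trials=n, seed=seed), spec, start=start)
                e.append(float(tab["abs_error"].iloc[0]))
            errs[n] = np.median(e)
        assert errs[8000] < errs[500]


def test_sigma_phi_zero_identifies_only_total_readout_variance(params, stim):
    """With sigma_phi = 0 the free-response likelihood depends on sigma_acc and
    sigma_m only through sigma_acc^2 I + sigma_m^2: trading one for the other
    along that ridge leaves the NLL unchanged (the documented degeneracy)."""
    p0 = params.replace(sigma_phi=0.0)
    trials, _ = simulate_free(p0, stim, SimConfig(n_trials=2000, seed=37))
    m = ConfidenceModel(trials, stim)
    total = p0.sigma_acc**2 * p0.pipeline_I + p0.sigma_m**2
    alt_acc = 0.5 * p0.sigma_acc
    alt_m = np.sqrt(total - alt_acc**2 * p0.pipeline_I)
    p_alt = p0.replace(sigma_acc=alt_acc, sigma_m=alt_m)
    assert m.nll(p_alt) == pytest.approx(m.nll(p0), rel=1e-10)
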