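"""Scripted simulation experiments validating and exercising the closed forms.

``validation_curves`` reproduces the standard approximation check: simulate
trials from the generative model, draw one confidence report per trial from
the closed-form predicted distribution, and compare binned means/variances of
simulated vs prediction-drawn confidence as functions of response time and of
unsigned average evidence (|sum of frame evidence| / stimulus duration).

``error_confidence_experiment`` probes the relationship between signal
strength and confidence on error trials in free response.  Signal-strength
variability is generated by drift-rate variability (sigma_phi > 0); each
trial's signal-strength level is its drift-rate scaling phi binned into a
configured number of levels.  Per simulated participant, the correlation
between level and confidence category over error trials is computed, and the
per-participant coefficients are t-tested against zero.  With no pipeline
(I = 0) error confidence increases with signal strength (t > 0); with 100 ms
of pipeline evidence it decreases (t < 0), because the pipeline evidence on
error trials favours the unchosen, correct option, more strongly so at high
signal strength.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import ModelParams, StimulusSpec
from .free_response import free_confidence_matrix
from .interrogation import interrogation_confidence_matrix
from .simulate import SimConfig, simulate_free, simulate_interrogation

__all__ = [
    "default_stimulus",
    "default_params",
    "draw_from_predictions",
    "validation_curves",
    "error_confidence_experiment",
]


def default_stimulus() -> StimulusSpec:
    """Stated-world stimulus: 40 Hz frames, moderate per-frame signal-to-noise.

    delta_mu/t_f gives a mean drift of 4.8 evidence units per second against
    accumulator noise of SD 1 per sqrt-second and stimulus-driven variance
    sigma_E^2/t_f = 2.5 per second; with the unit flat threshold this yields
    accuracies around 90% and decision times of a few hundred milliseconds,
    typical of fast two-alternative fluctuating-stimulus experiments.
    """
    return StimulusSpec(delta_mu=0.12, sigma_E=0.25, t_f=0.025)


def default_params(sigma_phi: float = 0.5) -> ModelParams:
    """Stated-world observer: flat unit threshold, 4 ordinal confidence categories."""
    from .core import ThresholdSpec

    return ModelParams(
        sigma_acc=1.0, sigma_phi=sigma_phi, sigma_m=0.3, pipeline_I=0.1,
        boundaries=(0.5, 1.0, 1.5), threshold=ThresholdSpec("constant", (1.0,)),
    )


def draw_from_predictions(probabilities, rng) -> np.ndarray:
    """Draw one confidence category per trial from predicted distributions."""
    p = np.asarray(probabilities, dtype=float)
    rng = np.random.default_rng(rng)
    cdf = np.cumsum(p, axis=1)
    u = rng.random(p.shape[0])
    return (u[:, None] > cdf).sum(axis=1)


def _binned_table(values, C_sim, C_pred, n_bins):
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1))
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    idx = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = idx == b
        n = int(m.sum())
        if n == 0:
            rows.append({"bin": b, "n": 0, "flag": "empty"})
            continue
        cs, cp = C_sim[m], C_pred[m]
        rows.append({
            "bin": b, "n": n,
            "lo": float(edges[b]), "hi": float(edges[b + 1]),
            "mean_sim": cs.mean(), "se_sim": cs.std(ddof=1) / np.sqrt(n),
            "mean_pred": cp.mean(), "se_pred": cp.std(ddof=1) / np.sqrt(n),
            "var_sim": cs.var(ddof=1), "var_pred": cp.var(ddof=1),
            "flag": "",
        })
    return pd.DataFrame(rows)


def validation_curves(
    params: ModelParams,
    stim: StimulusSpec,
    sim: SimConfig,
    condition: str = "free",
    n_bins: int = 10,
    n_frames=(10, 40),
) -> dict:
    """Binned simulated vs prediction-drawn confidence, by RT and by average evidence.

    Returns a report dict with the two binned tables, the configuration
    snapshot, and counts.  For interrogation, per-trial stimulus durations are
    drawn uniformly over the ``n_frames`` range so that the response-time axis
    varies.
    """
    if sim.n_trials == 0:
        raise ValueError("n_trials must be positive")
    rng = np.random.default_rng(sim.seed + 1)
    if condition == "interrogation":
        nf = rng.integers(n_frames[0], n_frames[1] + 1, size=sim.n_trials)
        trials, _ = simulate_interrogation(params, stim, nf, sim)
        probs = interrogation_confidence_matrix(
            trials["E"].to_numpy(), trials["t_e"].to_numpy(), trials["R"].to_numpy(),
            params, stim,
        )
        ok = np.ones(len(trials), dtype=bool)
    elif condition == "free":
        trials, _ = simulate_free(params, stim, sim)
        ok = ~trials["censored"].to_numpy()
        trials = trials[ok].reset_index(drop=True)
        probs = free_confidence_matrix(
            trials["R"].to_numpy(), trials["t_r"].to_numpy(),
            trials["E_bar"].to_numpy(), trials["delta_E"].to_numpy(), params, stim,
        )
    else:
        raise ValueError("condition must be 'interrogation' or 'free'")

    C_sim = trials["C"].to_numpy()
    C_pred = draw_from_predictions(probs, np.random.default_rng(sim.seed + 2))
    t_r = trials["t_r"].to_numpy()
    avg_ev = np.abs(trials["E"].to_numpy() / trials["t_e"].to_numpy())
    return {
        "condition": condition,
        "n_trials": int(len(trials)),
        "n_censored": int((~ok).sum()),
        "seed": sim.seed,
        "config": {"params": params, "stim": stim},
        "by_response_time": _binned_table(t_r, C_sim, C_pred, n_bins),
        "by_average_evidence": _binned_table(avg_ev, C_sim, C_pred, n_bins),
    }


def error_confidence_experiment(
    params: ModelParams,
    stim: StimulusSpec,
    n_participants: int = 40,
    n_trials: int = 6000,
    pipeline_values=(0.0, 0.1),
    n_levels: int = 5,
    seed: int = 0,
    dt: float = 1e-3,
    t_max: float = 10.0,
    min_error_trials: int = 10,
) -> dict:
    """Error-trial confidence vs signal strength, with and without pipeline evidence.

    Requires ``params.sigma_phi > 0`` (drift-rate variability generates the
    signal-strength variability) and at least two signal-strength levels.
    Returns, per pipeline duration, the per-participant correlations, the
    one-sample t statistic (df = n_participants - 1) and its p-value.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 signal-strength levels for a correlation")
    if params.sigma_phi <= 0:
        raise ValueError("signal-strength variability requires sigma_phi > 0")
    report = {"n_participants": n_participants, "n_trials": n_trials,
              "n_levels": n_levels, "seed": seed,
              "config": {"params": params, "stim": stim}, "conditions": {}}
    ss = np.random.SeedSequence([seed, 202_407])
    for I in pipeline_values:
        p_I = params.replace(pipeline_I=float(I))
        seeds = ss.spawn(n_participants)
        corr = np.full(n_participants, np.nan)
        flagged = []
        for p_idx in range(n_participants):
            pseed = int(seeds[p_idx].generate_state(1)[0] % (2**31))
            trials, _ = simulate_free(
                p_I, stim, SimConfig(n_trials=n_trials, seed=pseed, dt=dt, t_max=t_max)
            )
            ok = ~trials["censored"].to_numpy()
            phi = trials["phi"].to_numpy()[ok]
            C = trials["C"].to_numpy()[ok]
            err = trials["R"].to_numpy()[ok] != trials["S"].to_numpy()[ok]
            edges = np.quantile(phi, np.linspace(0, 1, n_levels + 1))
            level = np.clip(np.searchsorted(edges, phi, side="right") - 1, 0, n_levels - 1)
            lvl_e, C_e = level[err], C[err]
            if lvl_e.size < min_error_trials or np.unique(lvl_e).size < 2 or C_e.std() == 0:
                flagged.append(p_idx)
                continue
            corr[p_idx] = np.corrcoef(lvl_e, C_e)[0, 1]
        valid = corr[np.isfinite(corr)]
        t_res = sstats.ttest_1samp(valid, 0.0)
        report["conditions"][float(I)] = {
            "correlations": corr,
            "mean_correlation": float(valid.mean()),
            "t": float(t_res.statistic),
            "p": float(t_res.pvalue),
            "df": int(valid.size - 1),
            "participants_flagged": flagged,
        }
    return report
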