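"""Closed-form per-trial confidence distribution, free-response condition.

From a response R at time t_r, with pipeline duration I and threshold f(t), the
decision state is recovered exactly: the accumulator hit ``x_d = L f(t_d)`` at
``t_d = t_r - I``.  The drift-rate scaling phi is then inferred from how fast
evidence was accumulated: combining the N(1, sigma_phi^2) prior with the
likelihood kernel implied by first passage (approximating the pre-decision
evidence stream by its time average E_bar) gives a normal posterior

    m_phi = (sigma_acc^2 + x_d sigma_phi^2 E_bar) / (sigma_acc^2 + t_d sigma_phi^2 E_bar^2)
    v_phi = sigma_phi^2 sigma_acc^2 / (sigma_acc^2 + t_d sigma_phi^2 E_bar^2)

written in a division-free form that is well defined at E_bar = 0.  Continuing
accumulation through the pipeline evidence delta_E yields a normal distribution
for the final scaled log-posterior ratio,

    mu_lf = (x_d + delta_E * m_phi) / theta(t_e)
    sigma_lf^2 = (delta_E^2 * v_phi + sigma_acc^2 * I) / theta(t_e)^2

and adding metacognitive noise, the probability of confidence category i is a
difference of normal CDFs over the corresponding x_c bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .core import ModelParams, StimulusSpec, derived_stats, theta
from .interrogation import ConfidenceDistribution
from .stimulus import FrameSequence, SufficientStats, sufficient_stats

__all__ = [
    "InvalidTrialError",
    "DecisionState",
    "PhiPosterior",
    "FreeMoments",
    "decision_state",
    "phi_posterior",
    "free_moments",
    "free_confidence_dist",
    "free_confidence_matrix",
]


class InvalidTrialError(ValueError):
    """Raised when a trial's timing makes its confidence likelihood undefined."""


@dataclass(frozen=True)
class DecisionState:
    t_d: float
    x_d: float
    L: int


@dataclass(frozen=True)
class PhiPosterior:
    m_phi: float
    v_phi: float


@dataclass(frozen=True)
class FreeMoments:
    mu_lf: float
    sigma_lf2: float


def decision_state(R: int, t_r: float, params: ModelParams) -> DecisionState:
    """Invert response and response time into the decision time and threshold state."""
    t_d = t_r - params.pipeline_I
    if t_d <= 0:
        raise InvalidTrialError(
            f"t_r = {t_r} does not exceed the pipeline duration I = {params.pipeline_I}"
        )
    L = 1 if R == 2 else -1
    x_d = L * float(params.threshold(t_d))
    return DecisionState(t_d=float(t_d), x_d=x_d, L=L)


def phi_posterior(dstate: DecisionState, E_bar: float, params: ModelParams) -> PhiPosterior:
    """Posterior over the drift-rate scaling given the decision state and E_bar."""
    s2a = params.sigma_acc**2
    sp2 = params.sigma_phi**2
    denom = s2a + dstate.t_d * sp2 * E_bar**2
    m = (s2a + dstate.x_d * sp2 * E_bar) / denom
    v = sp2 * s2a / denom
    return PhiPosterior(m_phi=float(m), v_phi=float(v))


def free_moments(
    dstate: DecisionState,
    stats: SufficientStats,
    t_e: float,
    params: ModelParams,
    stim: StimulusSpec,
) -> FreeMoments:
    """Moments of the final scaled log-posterior ratio given (R, t_r, E)."""
    I = t_e - dstate.t_d
    if I < -1e-9:
        raise InvalidTrialError(f"t_e = {t_e} precedes the decision time t_d = {dstate.t_d}")
    I = max(I, 0.0)
    post = phi_posterior(dstate, stats.E_bar, params)
    th = theta(t_e, derived_stats(stim, params))
    mu_lf = (dstate.x_d + stats.delta_E * post.m_phi) / th
    sigma_lf2 = (stats.delta_E**2 * post.v_phi + params.sigma_acc**2 * I) / th**2
    return FreeMoments(mu_lf=float(mu_lf), sigma_lf2=float(sigma_lf2))


def _bin_probs_from_moments(mu_eff, total_var, boundaries):
    """Category probabilities for x_c ~ N(mu_eff, total_var) in the R = 2 frame.

    ``mu_eff`` is L * mu_lf, so the R = 1 case (integration limits -d_{i+1} to
    -d_i) maps exactly onto the R = 2 rule; degenerate variance yields a point
    mass on the bin containing the mean.
    """
    mu_eff = np.atleast_1d(np.asarray(mu_eff, dtype=float))
    total_var = np.broadcast_to(np.asarray(total_var, dtype=float), mu_eff.shape)
    d = np.asarray(boundaries, dtype=float)
    edges = np.concatenate(([-np.inf], d, [np.inf]))
    n_cat = d.size + 1
    p = np.empty((mu_eff.size, n_cat))
    pos = total_var > 0
    if np.any(pos):
        sd = np.sqrt(total_var[pos])
        z = (edges[None, :] - mu_eff[pos, None]) / sd[:, None]
        p[pos] = np.diff(ndtr(z), axis=1)
    if np.any(~pos):
        idx = np.searchsorted(d, mu_eff[~pos], side="right")
        pm = np.zeros((int((~pos).sum()), n_cat))
        pm[np.arange(pm.shape[0]), idx] = 1.0
        p[~pos] = pm
    return p


def free_confidence_matrix(R, t_r, E_bar, delta_E, params: ModelParams, stim: StimulusSpec):
    """Vectorised free-response category probabilities from per-trial summaries."""
    R = np.atleast_1d(np.asarray(R))
    t_r = np.broadcast_to(np.asarray(t_r, dtype=float), R.shape)
    E_bar = np.broadcast_to(np.asarray(E_bar, dtype=float), R.shape)
    delta_E = np.broadcast_to(np.asarray(delta_E, dtype=float), R.shape)
    t_d = t_r - params.pipeline_I
    if np.any(t_d <= 0):
        bad = np.nonzero(t_d <= 0)[0]
        raise InvalidTrialError(
            f"{bad.size} trial(s) have t_r <= pipeline_I (first at row {bad[0]})"
        )
    L = np.where(R == 2, 1.0, -1.0)
    x_d = L * np.asarray(params.threshold(t_d), dtype=float)
    s2a = params.sigma_acc**2
    sp2 = params.sigma_phi**2
    denom = s2a + t_d * sp2 * E_bar**2
    m_phi = (s2a + x_d * sp2 * E_bar) / denom
    v_phi = sp2 * s2a / denom
    t_e = t_d + params.pipeline_I
    th = np.asarray(theta(t_e, derived_stats(stim, params)), dtype=float)
    mu_lf = (x_d + delta_E * m_phi) / th
    sigma_lf2 = (delta_E**2 * v_phi + s2a * params.pipeline_I) / th**2
    return _bin_probs_from_moments(L * mu_lf, sigma_lf2 + params.sigma_m**2, params.boundaries)


def free_confidence_dist(
    R: int,
    t_r: float,
    frames: FrameSequence | SufficientStats,
    params: ModelParams,
    stim: StimulusSpec,
) -> ConfidenceDistribution:
    """Closed-form p(C = i | R, t_r, E) for a single free-response trial.

    ``frames`` may be the trial's frame sequence (sufficient statistics are
    computed by the proportional split at t_d = t_r - I and t_e = t_r) or
    precomputed :class:`SufficientStats`.
    """
    dstate = decision_state(R, t_r, params)
    t_e = t_r  # free response: the stimulus ends at the response
    if isinstance(frames, FrameSequence):
        stats = sufficient_stats(frames, dstate.t_d, t_e)
    else:
        stats = frames
    fm = free_moments(dstate, stats, t_e, params, stim)
    p = _bin_probs_from_moments(
        dstate.L * fm.mu_lf, fm.sigma_lf2 + params.sigma_m**2, params.boundaries
    )[0]
    return ConfidenceDistribution(probabilities=p, response_prob=None)
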