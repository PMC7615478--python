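"""Closed-form per-trial confidence distribution, interrogation condition.

Given the summed evidence ``E`` of a trial and the stimulus duration ``t_e``,
the scaled log-posterior ratio at the end of accumulation is normally
distributed,

    x_lp | E  ~  N( mu_lp, sigma_lp^2 ),
    mu_lp = E / theta(t_e),
    sigma_lp^2 = (E^2 sigma_phi^2 + t_e sigma_acc^2) / theta(t_e)^2,

and the response R is the sign of x_lp, so conditioning on R truncates this
normal to a half line.  The readout x_c adds independent N(0, sigma_m^2) noise
and is binned by the confidence boundaries.  The probability of each ordinal
category then reduces to differences of bivariate-normal CDF values; with
sigma_m = 0 it is the binned mass of the truncated normal itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, owens_t, roots_legendre
from scipy.stats import truncnorm

from .core import DerivedStats, ModelParams, StimulusSpec, derived_stats, theta

__all__ = [
    "InterrogationMoments",
    "ConfidenceDistribution",
    "bvn_cdf",
    "interrogation_moments",
    "interrogation_confidence_dist",
    "interrogation_confidence_matrix",
]

# trigger the stable truncated-normal quadrature route when the closed form's
# normaliser Phi(L mu_lp / sigma_lp) would be smaller than ~1e-12
_EXTREME_Z = -7.0


@dataclass(frozen=True)
class InterrogationMoments:
    """Pre-truncation moments of x_lp given the evidence, plus the response sign."""

    mu_lp: float
    sigma_lp2: float
    L: int


@dataclass(frozen=True)
class ConfidenceDistribution:
    """Categorical distribution over ordinal confidence reports for one trial.

    ``response_prob`` is p(R | E) where defined (interrogation); the
    response/response-time factor is not modelled for free response, so it is
    None there.
    """

    probabilities: np.ndarray
    response_prob: float | None = None


def bvn_cdf(l1, l2, rho):
    """Standard bivariate normal CDF P(X <= l1, Y <= l2) with correlation rho.

    Evaluated through Owen's T function (absolute accuracy ~1e-14); vectorised
    over broadcastable ``l1``, ``l2``, ``rho``.  ``|rho| -> 1`` is handled by
    the comonotone/antithetic limits; infinite limits are allowed.
    """
    l1, l2, rho = np.broadcast_arrays(*(np.asarray(a, dtype=float) for a in (l1, l2, rho)))
    scalar = l1.ndim == 0
    h = np.atleast_1d(l1).copy()
    k = np.atleast_1d(l2).copy()
    r = np.atleast_1d(rho).copy()
    if np.any(np.abs(r) > 1):
        raise ValueError("rho must lie in [-1, 1]")
    out = np.empty_like(h)

    # infinite limits: reduce to univariate CDFs
    neg_inf = np.isneginf(h) | np.isneginf(k)
    pos_h = np.isposinf(h)
    pos_k = np.isposinf(k)
    out[neg_inf] = 0.0
    out[pos_h & ~neg_inf] = ndtr(k[pos_h & ~neg_inf])
    out[pos_k & ~neg_inf & ~pos_h] = ndtr(h[pos_k & ~neg_inf & ~pos_h])

    lim = np.abs(r) > 1.0 - 1e-12
    core = ~(neg_inf | pos_h | pos_k)
    m = core & lim
    if np.any(m):
        up = r[m] > 0
        mn = np.minimum(h[m], k[m])
        out[m] = np.where(up, ndtr(mn), np.maximum(ndtr(h[m]) + ndtr(k[m]) - 1.0, 0.0))

    m = core & ~lim
    if np.any(m):
        hh = h[m]
        kk = k[m]
        rr = r[m]
        # nudge exact zeros so Owen's decomposition has a well-defined branch
        hh = np.where(hh == 0.0, 1e-15, hh)
        kk = np.where(kk == 0.0, 1e-15, kk)
        den = np.sqrt(1.0 - rr * rr)
        with np.errstate(divide="ignore", over="ignore"):
            a_h = (kk - rr * hh) / (hh * den)
            a_k = (hh - rr * kk) / (kk * den)
        c = np.where(hh * kk < 0, 0.5, 0.0)
        val = 0.5 * (ndtr(hh) + ndtr(kk)) - owens_t(hh, a_h) - owens_t(kk, a_k) - c
        out[m] = np.clip(val, 0.0, 1.0)
    return float(out[0]) if scalar else out.reshape(l1.shape)


def interrogation_moments(
    E, t_e, params: ModelParams, stim: StimulusSpec, R=2, stats: DerivedStats | None = None
):
    """Pre-truncation mean and variance of x_lp given E and t_e.

    The associated response probability is ``p(R | E) = Phi(L mu_lp / sigma_lp)``
    with L = +1 for R = 2 and L = -1 for R = 1 (see :func:`response_prob`).
    """
    t_e = np.asarray(t_e, dtype=float)
    if np.any(t_e <= 0):
        raise ValueError("t_e must be positive")
    d = stats if stats is not None else derived_stats(stim, params)
    th = theta(t_e, d)
    E = np.asarray(E, dtype=float)
    mu_lp = E / th
    sigma_lp2 = (E**2 * params.sigma_phi**2 + t_e * params.sigma_acc**2) / th**2
    L = np.where(np.asarray(R) == 2, 1, -1)
    if mu_lp.ndim == 0:
        return InterrogationMoments(float(mu_lp), float(sigma_lp2), int(L))
    return mu_lp, sigma_lp2, L


def response_prob(E, t_e, R, params: ModelParams, stim: StimulusSpec):
    """p(R | E) = Phi(L mu_lp / sigma_lp)."""
    scalar = np.ndim(E) == 0
    mu_lp, sigma_lp2, L = interrogation_moments(
        np.atleast_1d(np.asarray(E, float)), np.atleast_1d(np.asarray(t_e, float)),
        params, stim, R=np.atleast_1d(R),
    )
    out = ndtr(L * mu_lp / np.sqrt(sigma_lp2))
    return float(out[0]) if scalar else out


def _gauss_legendre_01(n=96):
    x, w = roots_legendre(n)
    return 0.5 * (x + 1.0), 0.5 * w


def _truncnorm_bin_probs(mu, sigma, boundaries, sigma_m, n_nodes=200):
    """Bin probabilities of x_c = TN(mu, sigma^2; 0, inf) + N(0, sigma_m^2).

    Stable for arbitrarily negative mu/sigma; quadrature over the truncated
    normal's quantile function.  ``mu``/``sigma`` are scalars (R = 2 frame).
    """
    d = np.concatenate(([-np.inf], boundaries, [np.inf]))
    a = (0.0 - mu) / sigma
    tn = truncnorm(a, np.inf, loc=mu, scale=sigma)
    u, w = _gauss_legendre_01(n_nodes)
    x = tn.ppf(u)
    upper = ndtr((d[1:, None] - x[None, :]) / sigma_m)
    lower = ndtr((d[:-1, None] - x[None, :]) / sigma_m)
    return ((upper - lower) * w[None, :]).sum(axis=1)


def _truncnorm_bin_probs_noiseless(mu, sigma, boundaries):
    """sigma_m = 0 limit: mass of TN(mu, sigma^2; 0, inf) between bin bounds."""
    d = np.concatenate(([-np.inf], np.asarray(boundaries, float), [np.inf]))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), mu.shape)
    lo = np.clip(d[:-1], 0.0, None)
    hi = np.clip(d[1:], 0.0, None)
    a = (0.0 - mu) / sigma
    tn = truncnorm(a[:, None], np.inf, loc=mu[:, None], scale=sigma[:, None])
    p = tn.cdf(hi[None, :]) - tn.cdf(lo[None, :])
    return np.clip(p, 0.0, 1.0)


def interrogation_confidence_matrix(E, t_e, R, params: ModelParams, stim: StimulusSpec):
    """Per-trial category probabilities, vectorised: rows trials, columns categories.

    The R = 1 case is computed by the exact mirror map (evidence sign flipped,
    R = 2 formula applied), which the paper's L-signed expression reduces to.
    """
    E = np.atleast_1d(np.asarray(E, dtype=float))
    t_e = np.broadcast_to(np.asarray(t_e, dtype=float), E.shape)
    R = np.broadcast_to(np.asarray(R), E.shape)
    mu_lp, sigma_lp2, L = interrogation_moments(E, t_e, params, stim, R=R)
    mu = L * mu_lp  # mirror into the R = 2 frame
    sig = np.sqrt(sigma_lp2)
    d = np.asarray(params.boundaries, dtype=float)

    if params.sigma_m == 0.0:
        return _truncnorm_bin_probs_noiseless(mu, sig, d)

    s_t = np.sqrt(sigma_lp2 + params.sigma_m**2)
    gt = mu / sig  # equals g / sqrt(1 + h^2)
    hh = sig / params.sigma_m
    rho = -hh / np.sqrt(1.0 + hh**2)
    edges = np.concatenate(([-np.inf], d, [np.inf]))
    e = (edges[None, :] - mu[:, None]) / s_t[:, None]
    cdf = bvn_cdf(gt[:, None], e, rho[:, None])
    denom = ndtr(gt)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.diff(cdf, axis=1) / denom[:, None]

    extreme = gt < _EXTREME_Z
    for i in np.nonzero(extreme)[0]:
        p[i] = _truncnorm_bin_probs(mu[i], sig[i], d, params.sigma_m)
    return np.clip(p, 0.0, 1.0)


def interrogation_confidence_dist(
    E: float, t_e: float, R: int, params: ModelParams, stim: StimulusSpec
) -> ConfidenceDistribution:
    """Closed-form p(C = i | R, E) for a single interrogation trial."""
    p = interrogation_confidence_matrix([E], [t_e], [R], params, stim)[0]
    rp = float(response_prob(E, t_e, R, params, stim))
    return ConfidenceDistribution(probabilities=p, response_prob=rp)
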