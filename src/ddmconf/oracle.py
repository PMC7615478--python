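"""Independent brute-force validators for the closed-form predictions.

Nothing here imports from the closed-form modules (``interrogation``,
``free_response``); agreement between the two routes is what the validation
tests assert.  The oracles work from the pre-closed-form integrals: numeric
marginalisation over the drift-rate scaling phi and over the scaled
log-posterior ratio x_lp, randomized probability-integral-transform (PIT)
calibration against simulated trials, and step-level Monte-Carlo of the
post-decision pipeline accumulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import integrate
from scipy.special import ndtr, roots_legendre
from scipy.stats import kstest

from .core import ModelParams, StimulusSpec, derived_stats, theta
from .stimulus import FrameSequence

__all__ = [
    "QuadratureSettings",
    "lpr_numeric",
    "interrogation_dist_numeric",
    "pit_calibration",
    "pipeline_mc_check",
]


@dataclass(frozen=True)
class QuadratureSettings:
    rtol: float = 1e-10
    atol: float = 1e-12
    trunc_sd: float = 10.0
    n_phi_nodes: int = 160

    def __post_init__(self) -> None:
        if self.rtol > 1e-8 or self.atol > 1e-8:
            raise ValueError("oracle duty requires tolerances <= 1e-8")


def _norm_pdf(x, mu, var):
    return np.exp(-0.5 * (x - mu) ** 2 / var) / np.sqrt(2.0 * np.pi * var)


def lpr_numeric(x: float, t: float, params: ModelParams, stim: StimulusSpec,
                n_nodes: int = 4001, trunc_sd: float = 12.0) -> float:
    """log[p(S=2 | x, t) / p(S=1 | x, t)] by direct quadrature over nu.

    The observer's generative model: nu ~ N(+/- nu0, sigma_nu^2) given S, and
    x | nu, t ~ N(nu t, s^2 t).  Marginalises nu on a fine grid.
    """
    d = derived_stats(stim, params)
    lik = []
    for sign in (1.0, -1.0):
        mu_nu = sign * d.nu0
        if d.sigma_nu == 0.0:
            lik.append(_norm_pdf(x, mu_nu * t, d.s2 * t))
            continue
        lo = mu_nu - trunc_sd * d.sigma_nu
        hi = mu_nu + trunc_sd * d.sigma_nu
        nu = np.linspace(lo, hi, n_nodes)
        integrand = _norm_pdf(nu, mu_nu, d.sigma_nu**2) * _norm_pdf(x, nu * t, d.s2 * t)
        lik.append(integrate.simpson(integrand, x=nu))
    return math.log(lik[0]) - math.log(lik[1])


def _xlp_density_factory(E, t_e, params: ModelParams, stim: StimulusSpec, q: QuadratureSettings):
    """p(x_lp | E) by numeric marginalisation of phi (validates the closed-form
    normal for x_lp as a by-product)."""
    d = derived_stats(stim, params)
    th = float(theta(t_e, d))
    acc_var = params.sigma_acc**2 * t_e / th**2
    if params.sigma_phi == 0.0:
        mu0 = E / th
        return lambda xlp: _norm_pdf(xlp, mu0, acc_var)
    nodes, weights = roots_legendre(q.n_phi_nodes)
    lo = 1.0 - q.trunc_sd * params.sigma_phi
    hi = 1.0 + q.trunc_sd * params.sigma_phi
    phi = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
    w = 0.5 * (hi - lo) * weights * _norm_pdf(phi, 1.0, params.sigma_phi**2)
    mus = phi * E / th

    def density(xlp):
        xlp = np.asarray(xlp, dtype=float)
        return (_norm_pdf(xlp[..., None], mus, acc_var) * w).sum(axis=-1)

    return density


def interrogation_dist_numeric(
    E: float, t_e: float, R: int, params: ModelParams, stim: StimulusSpec,
    q: QuadratureSettings | None = None,
) -> np.ndarray:
    """Category probabilities p(C = i | R, E) by adaptive quadrature.

    Integrates the truncated x_lp density (region consistent with R) against
    the Gaussian readout mass in each confidence bin, then normalises by the
    numerically computed p(R | E).  Returns an array of category probabilities.
    """
    if q is None:
        q = QuadratureSettings()
    density = _xlp_density_factory(E, t_e, params, stim, q)
    d = derived_stats(stim, params)
    th = float(theta(t_e, d))
    mu0 = E / th
    sd0 = math.sqrt(E**2 * params.sigma_phi**2 + t_e * params.sigma_acc**2) / th

    if R == 2:
        lo_r, hi_r = 0.0, max(mu0 + q.trunc_sd * sd0, q.trunc_sd * sd0)
    else:
        lo_r, hi_r = min(mu0 - q.trunc_sd * sd0, -q.trunc_sd * sd0), 0.0

    def quad(fn, a, b):
        if b <= a:
            return 0.0
        val, _ = integrate.quad(fn, a, b, epsabs=q.atol, epsrel=q.rtol, limit=400)
        return val

    norm = quad(density, lo_r, hi_r)

    b = np.asarray(params.boundaries, dtype=float)
    edges = np.concatenate(([-np.inf], b, [np.inf]))
    if R == 2:
        bins = [(edges[i], edges[i + 1]) for i in range(edges.size - 1)]
    else:
        bins = [(-edges[i + 1], -edges[i]) for i in range(edges.size - 1)]

    probs = np.empty(len(bins))
    for i, (lo_c, hi_c) in enumerate(bins):
        if params.sigma_m == 0.0:
            a = max(lo_r, lo_c)
            bb = min(hi_r, hi_c)
            probs[i] = quad(density, a, bb)
        else:
            sm = params.sigma_m

            def integrand(xlp, lo_c=lo_c, hi_c=hi_c):
                mass_hi = 1.0 if np.isposinf(hi_c) else ndtr((hi_c - xlp) / sm)
                mass_lo = 0.0 if np.isneginf(lo_c) else ndtr((lo_c - xlp) / sm)
                return density(xlp) * (mass_hi - mass_lo)

            probs[i] = quad(integrand, lo_r, hi_r)
    return probs / norm


class KSResult(NamedTuple):
    statistic: float
    pvalue: float


def pit_calibration(C, probabilities, rng) -> KSResult:
    """Randomized probability-integral-transform calibration test.

    For each trial, u = F(C - 1) + V * p(C) with V ~ Uniform(0, 1), where F is
    the predicted CDF over categories.  If the predictions equal the true
    conditional distributions, u ~ Uniform(0, 1); returns the one-sample KS
    test of that uniformity.
    """
    C = np.asarray(C, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if C.size == 0:
        raise ValueError("empty input")
    if C.size < 1000:
        raise ValueError("PIT calibration requires at least 1000 trials")
    if p.ndim != 2 or p.shape[0] != C.size:
        raise ValueError("probabilities must be (n_trials, n_categories)")
    rng = np.random.default_rng(rng)
    cdf = np.cumsum(p, axis=1)
    rows = np.arange(C.size)
    F_prev = np.where(C > 0, cdf[rows, C - 1], 0.0)
    u = F_prev + rng.random(C.size) * p[rows, C]
    res = kstest(u, "uniform")
    return KSResult(float(res.statistic), float(res.pvalue))


def pipeline_mc_check(
    x_d: float, phi: float, frames: FrameSequence, t_d: float, I: float,
    params: ModelParams, stim: StimulusSpec, n: int, seed, dt: float = 1e-3,
):
    """Empirical moments of x_lp from step-level pipeline continuations at fixed phi.

    Simulates Delta-x over (t_d, t_d + I] with increments
    N(phi * deltaE_j, sigma_acc^2 dt) where deltaE_j comes from the frame
    stream, and returns the mean and variance of (x_d + Delta-x) / theta(t_e)
    with their standard errors.
    """
    if n < 10_000:
        raise ValueError("n must be >= 1e4 for a meaningful check")
    rng = np.random.default_rng(seed)
    d = derived_stats(stim, params)
    t_e = t_d + I
    m_steps = round(I / dt)
    th = float(theta(t_e, d))
    if m_steps == 0:
        x = np.full(n, x_d / th)
        return {"mean": x_d / th, "var": 0.0, "se_mean": 0.0, "se_var": 0.0, "n": n}
    # per-step evidence: exact integral of the piecewise-constant frame stream
    # over each step (evidence delivered uniformly in time within a frame)
    from .stimulus import _cum_evidence

    t_grid = t_d + np.arange(m_steps + 1) * dt
    cum = np.array([_cum_evidence(frames, t) for t in t_grid])
    dE = np.diff(cum)
    drift = phi * dE.sum()
    noise = params.sigma_acc * math.sqrt(dt) * rng.standard_normal((n, m_steps))
    delta_x = drift + noise.sum(axis=1)
    x_lp = (x_d + delta_x) / th
    mean = float(x_lp.mean())
    var = float(x_lp.var(ddof=1))
    return {
        "mean": mean,
        "var": var,
        "se_mean": math.sqrt(var / n),
        "se_var": var * math.sqrt(2.0 / (n - 1)),
        "n": n,
    }
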