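"""Model parameters, derived observer statistics, the confidence readout and binning.

The observer accumulates the noisy difference in evidence measurements between two
options.  Stimulus evidence arrives in short frames of duration ``t_f``; the
difference-in-evidence per frame fluctuates around ``+/- delta_mu`` with standard
deviation ``sigma_E``.  Accumulation adds Gaussian noise with variance
``sigma_acc**2`` per unit time, scaled per trial by a drift-rate factor
``phi ~ N(1, sigma_phi**2)``.

From the observer's point of view the mean accumulation rate ``nu`` is drawn from
``N(+/- nu0, sigma_nu**2)`` with ``nu0 = delta_mu / t_f`` and ``sigma_nu = nu0 *
sigma_phi``, and increments have variance ``s2 = sigma_acc**2 + sigma_E**2 / t_f``
per unit time.  The scaled log-posterior ratio after accumulating ``x`` over time
``t`` is ``x_lp = x / theta(t)`` with ``theta(t) = (s2 + t sigma_nu^2) / (s2 +
sigma_nu^2)``; ``x_lp / K`` is the exact log-posterior odds of option 2 over
option 1, with ``K = (s2 + sigma_nu^2) / (2 nu0)``.

Confidence reports are ordinal: a noisy readout ``x_c ~ N(x_lp, sigma_m**2)`` is
compared against boundaries ``d_1 < ... < d_{n-1}`` (applied to ``x_c`` after a
response for option 2, and to ``-x_c`` after a response for option 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "StimulusSpec",
    "ThresholdSpec",
    "ModelParams",
    "DerivedStats",
    "derived_stats",
    "theta",
    "scaled_lpr",
    "prob_correct",
    "bin_confidence",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Experimenter-known stimulus statistics (not fit parameters).

    Parameters
    ----------
    delta_mu : float
        Absolute mean difference-in-evidence per frame (> 0).
    sigma_E : float
        Standard deviation of the per-frame difference-in-evidence (> 0).
    t_f : float
        Frame duration in seconds (> 0).
    """

    delta_mu: float
    sigma_E: float
    t_f: float

    def __post_init__(self) -> None:
        for name in ("delta_mu", "t_f"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"StimulusSpec.{name} must be a positive finite real, got {v!r}")
        # sigma_E = 0 is the degenerate noiseless-stimulus limit (constant frames)
        if not np.isfinite(self.sigma_E) or self.sigma_E < 0:
            raise ValueError(f"StimulusSpec.sigma_E must be a nonnegative finite real, got {self.sigma_E!r}")


_THRESHOLD_FAMILIES = ("constant", "linear", "exponential")


@dataclass(frozen=True)
class ThresholdSpec:
    """Decision threshold f(t) >= 0 on |x|, evaluable at any t >= 0.

    Families
    --------
    constant : ``f(t) = a``; params ``(a,)``.
    linear : ``f(t) = max(a - b*t, c)`` (linearly decaying, floored); params ``(a, b, c)``.
    exponential : ``f(t) = c + (a - c) * exp(-t / tau)``; params ``(a, c, tau)``.
    """

    family: str
    params: tuple

    def __post_init__(self) -> None:
        if self.family not in _THRESHOLD_FAMILIES:
            raise ValueError(f"unknown threshold family {self.family!r}; expected one of {_THRESHOLD_FAMILIES}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        n_expected = {"constant": 1, "linear": 3, "exponential": 3}[self.family]
        if len(self.params) != n_expected:
            raise ValueError(f"threshold family {self.family!r} takes {n_expected} parameters, got {len(self.params)}")
        if self.family == "constant":
            (a,) = self.params
            if a < 0:
                raise ValueError("constant threshold must be nonnegative")
        elif self.family == "linear":
            a, b, c = self.params
            if a < 0 or c < 0:
                raise ValueError("linear threshold start and floor must be nonnegative")
        else:
            a, c, tau = self.params
            if a < 0 or c < 0 or tau <= 0:
                raise ValueError("exponential threshold requires a, c >= 0 and tau > 0")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.family == "constant":
            (a,) = self.params
            out = np.full_like(t, a)
        elif self.family == "linear":
            a, b, c = self.params
            out = np.maximum(a - b * t, c)
        else:
            a, c, tau = self.params
            out = c + (a - c) * np.exp(-t / tau)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class ModelParams:
    """Fit parameters of the observer model.

    Parameters
    ----------
    sigma_acc : float
        Accumulator noise SD per sqrt-second (> 0).
    sigma_phi : float
        SD of the per-trial drift-rate scaling (>= 0).
    sigma_m : float
        Metacognitive (readout) noise SD (>= 0).
    pipeline_I : float
        Duration in seconds of stimulus still in the processing pipeline at the
        time of response (>= 0).
    boundaries : tuple of float
        Strictly increasing confidence-bin boundaries ``d_1 < ... < d_{n-1}`` on
        the x_c axis, defining ``n >= 2`` ordinal categories.
    threshold : ThresholdSpec
        Decision threshold shape (free-response condition only).
    """

    sigma_acc: float
    sigma_phi: float
    sigma_m: float
    pipeline_I: float
    boundaries: tuple
    threshold: ThresholdSpec = field(default_factory=lambda: ThresholdSpec("constant", (2.0,)))

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma_acc) or self.sigma_acc <= 0:
            raise ValueError("sigma_acc must be positive")
        for name in ("sigma_phi", "sigma_m", "pipeline_I"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be nonnegative")
        b = tuple(float(x) for x in np.atleast_1d(self.boundaries))
        if len(b) < 1:
            raise ValueError("need at least one boundary (>= 2 confidence categories)")
        if not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries", b)

    @property
    def n_categories(self) -> int:
        return len(self.boundaries) + 1

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DerivedStats:
    """Derived observer statistics (deterministic functions of stimulus + params)."""

    nu0: float
    sigma_nu: float
    s2: float
    K: float


def derived_stats(stim: StimulusSpec, params: ModelParams) -> DerivedStats:
    """nu0 = delta_mu/t_f, sigma_nu = nu0*sigma_phi, s2 = sigma_acc^2 + sigma_E^2/t_f,
    K = (s2 + sigma_nu^2) / (2 nu0)."""
    nu0 = stim.delta_mu / stim.t_f
    sigma_nu = nu0 * params.sigma_phi
    s2 = params.sigma_acc**2 + stim.sigma_E**2 / stim.t_f
    K = (s2 + sigma_nu**2) / (2.0 * nu0)
    return DerivedStats(nu0=nu0, sigma_nu=sigma_nu, s2=s2, K=K)


def theta(t, d: DerivedStats):
    """Time-dependent scaling theta(t) = (s2 + t*sigma_nu^2) / (s2 + sigma_nu^2).

    Nondecreasing in t; equals 1 at t = 1 and identically 1 when sigma_nu = 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    out = (d.s2 + t * d.sigma_nu**2) / (d.s2 + d.sigma_nu**2)
    return out if out.ndim else float(out)


def scaled_lpr(x, t, d: DerivedStats):
    """Scaled log-posterior ratio x_lp = x / theta(t).

    ``scaled_lpr(x, t, d) / d.K`` equals the observer's log-posterior odds
    log[p(S=2 | x, t) / p(S=1 | x, t)].
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be positive")
    x = np.asarray(x, dtype=float)
    out = x / theta(t, d)
    return out if out.ndim else float(out)


def prob_correct(x_lp, d: DerivedStats):
    """Probability the favoured option is correct: 1 / (1 + exp(-|x_lp| / K))."""
    x_lp = np.asarray(x_lp, dtype=float)
    out = expit(np.abs(x_lp) / d.K)
    return out if out.ndim else float(out)


def bin_confidence(x_c, R, boundaries: Sequence[float]):
    """Ordinal confidence category (0-based) for readout x_c after response R.

    For R = 2 the category is ``i`` with ``d_i <= x_c < d_{i+1}`` (implicit
    ``d_0 = -inf``, ``d_n = +inf``); for R = 1 the same rule is applied to
    ``-x_c``.  Ties on a boundary go to the upper category (left-closed bins).
    The extreme bins extend to infinity, so every readout is assigned a
    category even when metacognitive noise pushes x_c to oppose the choice.
    """
    b = np.asarray(boundaries, dtype=float)
    if b.ndim != 1 or b.size < 1 or not np.all(np.diff(b) > 0):
        raise ValueError("boundaries must be a strictly increasing 1-d sequence")
    x_c = np.asarray(x_c, dtype=float)
    R = np.asarray(R)
    z = np.where(R == 2, x_c, -x_c)
    out = np.searchsorted(b, z, side="right")
    return out if out.ndim else int(out)
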