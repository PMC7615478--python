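"""Trial-level maximum-likelihood fitting of the confidence model.

`ConfidenceModel` holds a table of trials (and, if needed, their frame
streams), evaluates the negative log-likelihood of the observed ordinal
confidence reports under the condition-appropriate closed forms, and `fit()`
maximises it over a chosen subset of the model parameters, returning a
`ConfidenceResults` object with estimates, numerical-Hessian standard errors
and a `summary()` table.

The stimulus statistics (delta_mu, sigma_E, t_f) are experiment-known
constants, never fitted; they anchor the evidence scale and make the remaining
parameters identifiable.  Free parameters are optimised on transformed scales
(log for standard deviations and the pipeline duration; first boundary plus
log-increments for the ordered confidence boundaries; log for positive
threshold parameters) with a derivative-free simplex search and jittered
restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .core import ModelParams, StimulusSpec, ThresholdSpec
from .free_response import InvalidTrialError, free_confidence_matrix
from .interrogation import interrogation_confidence_matrix
from .simulate import SimConfig, simulate_free, simulate_interrogation

__all__ = ["FitSpec", "ConfidenceModel", "ConfidenceResults", "recovery_study"]

_PROB_FLOOR = 1e-300
_SD_NAMES = ("sigma_acc", "sigma_phi", "sigma_m", "pipeline_I")


@dataclass(frozen=True)
class FitSpec:
    """Which parameters to fit and how.

    ``free`` is a subset of {"sigma_acc", "sigma_phi", "sigma_m", "pipeline_I",
    "boundaries", "threshold"}; everything else stays at its value in the
    starting parameters.  ``n_restarts`` simplex runs are started from the
    starting point jittered in transformed space; the best is returned.
    """

    free: tuple = ("sigma_acc", "sigma_m", "boundaries")
    n_restarts: int = 5
    seed: int = 0
    jitter: float = 0.3
    maxiter: int = 4000
    xatol: float = 1e-5
    fatol: float = 1e-7
    bounds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        valid = set(_SD_NAMES) | {"boundaries", "threshold"}
        unknown = set(self.free) - valid
        if unknown:
            raise ValueError(f"unknown free parameters: {sorted(unknown)}")
        if len(self.free) == 0 and self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


def _pack(params: ModelParams, free) -> np.ndarray:
    v = []
    for name in free:
        if name in _SD_NAMES:
            v.append(np.log(max(getattr(params, name), 1e-12)))
        elif name == "boundaries":
            b = np.asarray(params.boundaries)
            v.append(b[0])
            v.extend(np.log(np.diff(b)))
        elif name == "threshold":
            v.extend(np.log(np.maximum(params.threshold.params, 1e-12)))
    return np.asarray(v, dtype=float)


def _unpack(vec, params: ModelParams, free) -> ModelParams:
    kwargs = {}
    i = 0
    for name in free:
        if name in _SD_NAMES:
            kwargs[name] = float(np.exp(vec[i]))
            i += 1
        elif name == "boundaries":
            m = len(params.boundaries)
            d1 = vec[i]
            incs = np.exp(vec[i + 1 : i + m])
            kwargs["boundaries"] = tuple(d1 + np.concatenate(([0.0], np.cumsum(incs))))
            i += m
        elif name == "threshold":
            k = len(params.threshold.params)
            kwargs["threshold"] = ThresholdSpec(params.threshold.family, tuple(np.exp(vec[i : i + k])))
            i += k
    return params.replace(**kwargs)


class ConfidenceModel:
    """Likelihood of ordinal confidence reports given responses, timing and stimuli.

    Parameters
    ----------
    trials : pandas.DataFrame
        One row per trial with columns ``condition`` ("interrogation" or
        "free"), ``R`` (1 or 2), ``C`` (0-based category), timing (``t_e`` for
        interrogation; ``t_r`` for free response) and evidence summaries
        (``E`` for interrogation; ``E_bar`` and ``delta_E`` for free response,
        as produced by :func:`ddmconf.stimulus.sufficient_stats`).  A
        ``censored`` column, if present, excludes flagged trials.
    stim : StimulusSpec
        Experiment-known stimulus statistics (fixed, not fitted).
    """

    def __init__(self, trials: pd.DataFrame, stim: StimulusSpec):
        self.stim = stim
        t = trials.copy()
        if "censored" in t:
            self.n_censored = int(t["censored"].sum())
            t = t[~t["censored"].astype(bool)]
        else:
            self.n_censored = 0
        if len(t) == 0:
            raise InvalidTrialError("no valid (non-censored) trials")
        self.trials = t.reset_index(drop=True)
        is_free = self.trials["condition"] == "free"
        self._free = self.trials[is_free]
        self._inter = self.trials[~is_free]
        self.nobs = len(self.trials)
        self.n_floored_last = 0

    @classmethod
    def from_simulation(cls, trials: pd.DataFrame, stim: StimulusSpec) -> "ConfidenceModel":
        return cls(trials, stim)

    def predict(self, params: ModelParams) -> pd.DataFrame:
        """Per-trial predicted category probabilities (columns p_C0 ... p_Cn-1)."""
        n_cat = params.n_categories
        out = np.empty((self.nobs, n_cat))
        if len(self._inter):
            out[self._inter.index] = interrogation_confidence_matrix(
                self._inter["E"].to_numpy(), self._inter["t_e"].to_numpy(),
                self._inter["R"].to_numpy(), params, self.stim,
            )
        if len(self._free):
            out[self._free.index] = free_confidence_matrix(
                self._free["R"].to_numpy(), self._free["t_r"].to_numpy(),
                self._free["E_bar"].to_numpy(), self._free["delta_E"].to_numpy(),
                params, self.stim,
            )
        cols = {f"p_C{i}": out[:, i] for i in range(n_cat)}
        df = pd.DataFrame({"trial_id": self.trials["trial_id"], **cols})
        return df

    def nll(self, params: ModelParams) -> float:
        """Negative log-likelihood of the observed confidence categories.

        Probabilities are floored at 1e-300 before the log; the number of
        floored trials is kept in ``n_floored_last`` as a diagnostic.
        """
        probs = self.predict(params).iloc[:, 1:].to_numpy()
        C = self.trials["C"].to_numpy(dtype=int)
        if np.any((C < 0) | (C >= params.n_categories)):
            raise ValueError("confidence categories outside the model's range")
        p_obs = probs[np.arange(self.nobs), C]
        self.n_floored_last = int((p_obs < _PROB_FLOOR).sum())
        return float(-np.log(np.maximum(p_obs, _PROB_FLOOR)).sum())

    def fit(self, start: ModelParams, spec: FitSpec | None = None, **kwargs) -> "ConfidenceResults":
        """Maximise the likelihood over ``spec.free`` starting from ``start``.

        Any FitSpec field may be overridden by keyword (e.g. ``free=...``,
        ``n_restarts=...``).  With no free parameters the start point is
        returned with its NLL unchanged.
        """
        if spec is None:
            spec = FitSpec(**kwargs)
        elif kwargs:
            spec = FitSpec(**{**spec.__dict__, **kwargs})
        if "pipeline_I" in spec.free and len(self._inter) and not len(self._free):
            raise ValueError("the pipeline duration is not fittable from interrogation data")
        if len(spec.free) == 0:
            nll0 = self.nll(start)
            return ConfidenceResults(self, start, spec, nll0, True, [(start, nll0, True)])

        rng = np.random.default_rng(spec.seed)
        x0 = _pack(start, spec.free)

        def objective(vec):
            try:
                return self.nll(_unpack(vec, start, spec.free))
            except (InvalidTrialError, ValueError, FloatingPointError, OverflowError):
                return np.inf

        trace = []
        best = None
        for r in range(spec.n_restarts):
            xr = x0 if r == 0 else x0 + spec.jitter * rng.standard_normal(x0.size)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.minimize(
                    objective, xr, method="Nelder-Mead",
                    options={"maxiter": spec.maxiter, "xatol": spec.xatol,
                             "fatol": spec.fatol, "adaptive": x0.size > 4},
                )
            p_hat = _unpack(res.x, start, spec.free)
            trace.append((p_hat, float(res.fun), bool(res.success)))
            if best is None or res.fun < best[1]:
                best = (p_hat, float(res.fun), bool(res.success), res.x.copy())
        params_hat, nll_hat, converged, vec_hat = best
        if not converged:
            warnings.warn("best restart did not satisfy the simplex convergence test")
        return ConfidenceResults(self, params_hat, spec, nll_hat, converged, trace, vec_hat, start)


class ConfidenceResults:
    """Fit results: estimates, uncertainty, diagnostics."""

    def __init__(self, model, params, spec, nll, converged, trace, vec=None, start=None):
        self.model = model
        self.params = params
        self.spec = spec
        self.nll = nll
        self.converged = converged
        self.restart_trace = trace
        self._vec = vec
        self._start = start if start is not None else params

    @property
    def estimates(self) -> dict:
        out = {}
        for name in self.spec.free:
            if name == "boundaries":
                for i, b in enumerate(self.params.boundaries, start=1):
                    out[f"d_{i}"] = b
            elif name == "threshold":
                for i, p in enumerate(self.params.threshold.params):
                    out[f"threshold_{i}"] = p
            else:
                out[name] = getattr(self.params, name)
        return out

    def bse(self, step: float = 1e-4) -> dict:
        """Standard errors from the observed information (numerical Hessian in
        transformed space, delta method back to the natural scale)."""
        if self._vec is None or len(self.spec.free) == 0:
            return {}
        v = self._vec
        k = v.size

        def f(vec):
            return self.model.nll(_unpack(vec, self._start, self.spec.free))

        H = np.empty((k, k))
        f0 = f(v)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = step
                ej = np.zeros(k); ej[j] = step
                H[i, j] = H[j, i] = (
                    f(v + ei + ej) - f(v + ei) - f(v + ej) + f0
                ) / step**2
        try:
            cov = np.linalg.inv(H)
            se_t = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            se_t = np.full(k, np.nan)
        # delta method: d(natural)/d(transformed)
        jac = []
        i = 0
        for name in self.spec.free:
            if name in _SD_NAMES:
                jac.append(np.exp(v[i])); i += 1
            elif name == "boundaries":
                m = len(self.params.boundaries)
                jac.append(1.0)
                jac.extend(np.exp(v[i + 1 : i + m]))
                i += m
            elif name == "threshold":
                kk = len(self.params.threshold.params)
                jac.extend(np.exp(v[i : i + kk])); i += kk
        se_nat = se_t * np.asarray(jac)
        return dict(zip(self.estimates.keys(), se_nat))

    def summary(self) -> str:
        lines = [
            "Confidence model fit (trial-level maximum likelihood)",
            "=" * 56,
            f"n trials: {self.model.nobs}   (censored excluded: {self.model.n_censored})",
            f"negative log-likelihood: {self.nll:.4f}",
            f"converged: {self.converged}   restarts: {len(self.restart_trace)}",
            f"floored-probability trials at optimum: {self.model.n_floored_last}",
            "-" * 56,
            f"{'parameter':<16}{'estimate':>12}{'std err':>12}",
        ]
        se = self.bse() if self._vec is not None else {}
        for name, val in self.estimates.items():
            s = se.get(name)
            s_str = f"{s:>12.4f}" if s is not None and np.isfinite(s) else f"{'--':>12}"
            lines.append(f"{name:<16}{val:>12.4f}{s_str}")
        lines.append("-" * 56)
        fixed = [n for n in ("sigma_acc", "sigma_phi", "sigma_m", "pipeline_I")
                 if n not in self.spec.free]
        for name in fixed:
            lines.append(f"fixed {name} = {getattr(self.params, name)}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<ConfidenceResults nll={self.nll:.3f} params={self.estimates}>"


def recovery_study(
    true_params: ModelParams,
    stim: StimulusSpec,
    sim: SimConfig,
    spec: FitSpec,
    start: ModelParams | None = None,
    condition: str = "free",
    n_frames: int = 20,
) -> pd.DataFrame:
    """Simulate -> fit -> tabulate true vs estimated parameters.

    Returns one row per free scalar quantity with columns (name, true,
    estimated, abs_error, rel_error).  Reproducible given ``sim.seed`` and
    ``spec.seed``.
    """
    if condition == "free":
        trials, _ = simulate_free(true_params, stim, sim)
    else:
        trials, _ = simulate_interrogation(true_params, stim, n_frames, sim)
    model = ConfidenceModel(trials, stim)
    start = start if start is not None else true_params
    if len(spec.free) == 0:
        rows = []
    res = model.fit(start, spec)

    def scalars(p: ModelParams) -> dict:
        out = {}
        for name in spec.free:
            if name == "boundaries":
                for i, b in enumerate(p.boundaries, start=1):
                    out[f"d_{i}"] = b
            elif name == "threshold":
                for i, v in enumerate(p.threshold.params):
                    out[f"threshold_{i}"] = v
            else:
                out[name] = getattr(p, name)
        return out

    truth = scalars(true_params)
    est = scalars(res.params)
    rows = []
    for name, tv in truth.items():
        ev = est[name]
        rows.append({
            "name": name, "true": tv, "estimated": ev,
            "abs_error": abs(ev - tv),
            "rel_error": abs(ev - tv) / abs(tv) if tv != 0 else np.nan,
        })
    return pd.DataFrame(rows)
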