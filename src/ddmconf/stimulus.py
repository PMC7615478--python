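"""Frame-level evidence streams and per-trial evidence sufficient statistics.

A stimulus is a sequence of short frames of duration ``t_f``; the
difference-in-evidence ``E_i`` presented during frame ``i`` is drawn
independently from ``N(mu, sigma_E**2)`` where ``mu = +/- delta_mu`` is the
signed mean for the trial.  Within a frame, evidence is delivered uniformly in
time, so a frame overlapping a split point contributes proportionally to either
side.  The per-trial summaries used by the free-response predictions are the
total evidence E over (0, t_e], the pre-decision evidence E_pre over (0, t_d],
its time average E_bar = E_pre / t_d, and the pipeline evidence
delta_E = E - E_pre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import StimulusSpec

__all__ = ["FrameSequence", "SufficientStats", "generate_frames", "sufficient_stats"]


@dataclass(frozen=True)
class FrameSequence:
    """Per-trial stream of per-frame difference-in-evidence values."""

    trial_id: int
    evidence: np.ndarray
    t_f: float

    def __post_init__(self) -> None:
        ev = np.asarray(self.evidence, dtype=float)
        if ev.ndim != 1 or ev.size < 1:
            raise ValueError("evidence must be a 1-d sequence with at least one frame")
        if self.t_f <= 0:
            raise ValueError("t_f must be positive")
        object.__setattr__(self, "evidence", ev)

    @property
    def n_frames(self) -> int:
        return int(self.evidence.size)

    @property
    def duration(self) -> float:
        return self.n_frames * self.t_f


@dataclass(frozen=True)
class SufficientStats:
    """Evidence summaries split at decision time (E = E_pre + delta_E)."""

    E: float
    E_pre: float
    E_bar: float
    delta_E: float


def generate_frames(mu: float, stim: StimulusSpec, n_frames: int, rng) -> FrameSequence:
    """Draw ``n_frames`` i.i.d. frame evidence values from N(mu, sigma_E^2).

    Parameters
    ----------
    mu : float
        Signed mean difference-in-evidence (``+delta_mu`` or ``-delta_mu`` for a
        stimulus from the generative task, but any real is accepted).
    rng : int or numpy.random.Generator
        Seed or generator; the same seed yields identical sequences.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(rng)
    ev = mu + stim.sigma_E * rng.standard_normal(int(n_frames))
    return FrameSequence(trial_id=0, evidence=ev, t_f=stim.t_f)


def _cum_evidence(frames: FrameSequence, t: float) -> float:
    """Evidence delivered over (0, t], apportioning partial frames uniformly in time."""
    t_f = frames.t_f
    ev = frames.evidence
    n_full = int(np.floor(t / t_f + 1e-12))
    n_full = min(n_full, ev.size)
    total = float(ev[:n_full].sum())
    frac_t = t - n_full * t_f
    if frac_t > 1e-12 and n_full < ev.size:
        total += float(ev[n_full]) * frac_t / t_f
    return total


def sufficient_stats(frames: FrameSequence, t_d: float, t_e: float) -> SufficientStats:
    """Split the evidence stream at the decision time t_d and the end of processing t_e.

    Requires ``0 < t_d <= t_e <= n_frames * t_f`` (up to a one-step tolerance).
    A frame overlapping a split contributes ``E_i * overlap / t_f`` to each side.
    """
    if t_d <= 0:
        raise ValueError("t_d must be positive")
    if t_e < t_d - 1e-12:
        raise ValueError("t_e must be >= t_d")
    if t_e > frames.duration + frames.t_f * 1e-9 + 1e-12:
        raise ValueError(
            f"t_e = {t_e} exceeds available stimulus duration {frames.duration}"
        )
    t_e = min(t_e, frames.duration)
    t_d = min(t_d, t_e)
    E = _cum_evidence(frames, t_e)
    E_pre = _cum_evidence(frames, t_d)
    return SufficientStats(E=E, E_pre=E_pre, E_bar=E_pre / t_d, delta_E=E - E_pre)
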