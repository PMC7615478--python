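"""Fine time-step Monte-Carlo simulation of full trials.

This is the ground-truth generator against which the closed-form predictions
and their approximations are tested.  Interrogation trials are simulated by
sampling the final accumulator state exactly (the accumulation is linear and
unconstrained, so x(t_e) = phi * E + N(0, sigma_acc^2 t_e) is distributionally
identical to summing Euler increments).  Free-response trials are simulated by
explicit Euler stepping of

    dx = phi * E_i * dt / t_f + sigma_acc * sqrt(dt) * dW

against the time-dependent thresholds +/- f(t), with the stimulus generated
lazily frame by frame until the response.  After the first crossing the trial
continues for exactly the pipeline duration I; the readout is
x_c ~ N(x(t_e) / theta(t_e), sigma_m^2), binned into ordinal categories.

Threshold crossing is detected on the post-step state and, by default, also by
a Brownian-bridge test for within-step crossings ("bridge"), which removes the
O(sqrt(dt)) first-passage bias of naive post-step detection; "euler" disables
the bridge test.  The recorded x_d is the actual (slightly overshooting) state,
while the analytic predictions use +/- f(t_d) exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ModelParams, StimulusSpec, bin_confidence, derived_stats, theta

__all__ = ["SimConfig", "simulate_interrogation", "simulate_free"]

TRIAL_COLUMNS = [
    "trial_id", "condition", "S", "R", "C", "t_r", "t_e", "t_d", "censored",
    "E", "E_pre", "E_bar", "delta_E", "phi", "x_d", "x_final", "x_lp", "x_c",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    dt must divide the frame duration exactly; default 1 ms.  Free-response
    trials that have not crossed a threshold by ``t_max`` are flagged censored
    (never dropped).
    """

    n_trials: int
    seed: int = 0
    dt: float = 1e-3
    t_max: float = 10.0
    crossing: str = "bridge"
    keep_frames: bool = False

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.dt <= 0 or self.t_max <= 0:
            raise ValueError("dt and t_max must be positive")
        if self.crossing not in ("bridge", "euler"):
            raise ValueError("crossing must be 'bridge' or 'euler'")

    def steps_per_frame(self, stim: StimulusSpec) -> int:
        spf = round(stim.t_f / self.dt)
        if spf < 1 or abs(spf * self.dt - stim.t_f) > 1e-9 * stim.t_f:
            raise ValueError(f"dt = {self.dt} must divide the frame duration t_f = {stim.t_f}")
        return spf


def _frames_long(records) -> pd.DataFrame:
    if not records:
        return pd.DataFrame({"trial_id": [], "frame_index": [], "evidence": []})
    tid = np.concatenate([r[1] for r in records])
    fidx = np.concatenate([np.full(r[1].size, r[0]) for r in records])
    ev = np.concatenate([r[2] for r in records])
    df = pd.DataFrame({"trial_id": tid, "frame_index": fidx, "evidence": ev})
    return df.sort_values(["trial_id", "frame_index"], kind="stable").reset_index(drop=True)


def simulate_interrogation(
    params: ModelParams, stim: StimulusSpec, n_frames, sim: SimConfig
):
    """Simulate interrogation trials; returns (trials, frames) DataFrames.

    ``n_frames`` is an int (all trials share one duration) or a per-trial
    sequence of ints; t_e = n_frames * t_f.
    """
    rng = np.random.default_rng(sim.seed)
    n = sim.n_trials
    nf = np.broadcast_to(np.asarray(n_frames, dtype=int), (n,))
    if np.any(nf < 1):
        raise ValueError("n_frames must be >= 1")
    d = derived_stats(stim, params)

    S = rng.integers(1, 3, size=n)
    mu = np.where(S == 2, stim.delta_mu, -stim.delta_mu)
    phi = 1.0 + params.sigma_phi * rng.standard_normal(n)
    nmax = int(nf.max())
    frames = mu[:, None] + stim.sigma_E * rng.standard_normal((n, nmax))
    mask = np.arange(nmax)[None, :] < nf[:, None]
    E = np.where(mask, frames, 0.0).sum(axis=1)
    t_e = nf * stim.t_f
    x = phi * E + params.sigma_acc * np.sqrt(t_e) * rng.standard_normal(n)
    tie = x == 0.0
    if np.any(tie):
        x[tie] = np.where(rng.random(tie.sum()) < 0.5, -1e-300, 1e-300)
    R = np.where(x > 0, 2, 1)
    x_lp = x / theta(t_e, d)
    x_c = x_lp + params.sigma_m * rng.standard_normal(n)
    C = bin_confidence(x_c, R, params.boundaries)

    trials = pd.DataFrame({
        "trial_id": np.arange(n), "condition": "interrogation", "S": S, "R": R, "C": C,
        "t_r": t_e + params.pipeline_I, "t_e": t_e, "t_d": np.nan, "censored": False,
        "E": E, "E_pre": E, "E_bar": E / t_e, "delta_E": 0.0,
        "phi": phi, "x_d": np.nan, "x_final": x, "x_lp": x_lp, "x_c": x_c,
    })[TRIAL_COLUMNS]

    frames_df = None
    if sim.keep_frames:
        ids, fidx = np.nonzero(mask)
        frames_df = pd.DataFrame(
            {"trial_id": ids, "frame_index": fidx, "evidence": frames[ids, fidx]}
        )
    return trials, frames_df


def simulate_free(params: ModelParams, stim: StimulusSpec, sim: SimConfig):
    """Simulate free-response trials; returns (trials, frames) DataFrames.

    Censored trials (no crossing by t_max) carry R = 0, C = -1 and
    censored = True.
    """
    rng = np.random.default_rng(sim.seed)
    n = sim.n_trials
    dt = sim.dt
    spf = sim.steps_per_frame(stim)
    I_steps = round(params.pipeline_I / dt)
    if abs(I_steps * dt - params.pipeline_I) > 1e-9 * max(params.pipeline_I, dt):
        raise ValueError(f"dt = {dt} must divide the pipeline duration I = {params.pipeline_I}")
    deadline = math.ceil(sim.t_max / dt)
    d = derived_stats(stim, params)
    f = params.threshold
    s2dt = params.sigma_acc**2 * dt
    sqdt = params.sigma_acc * math.sqrt(dt)
    bridge = sim.crossing == "bridge" and params.sigma_acc > 0

    S = rng.integers(1, 3, size=n)
    mu = np.where(S == 2, stim.delta_mu, -stim.delta_mu)
    phi = 1.0 + params.sigma_phi * rng.standard_normal(n)

    x = np.zeros(n)
    E_cum = np.zeros(n)
    E_cur = np.zeros(n)
    phase = np.zeros(n, dtype=np.int8)  # 0 pre-decision, 1 pipeline, 2 done
    pipe_left = np.zeros(n, dtype=np.int64)
    R = np.zeros(n, dtype=np.int64)
    censored = np.zeros(n, dtype=bool)
    t_d = np.full(n, np.nan)
    t_e_arr = np.full(n, np.nan)
    x_d = np.full(n, np.nan)
    E_pre = np.full(n, np.nan)
    x_final = np.full(n, np.nan)

    frame_records = [] if sim.keep_frames else None
    active = np.arange(n)
    j = 0
    while active.size:
        t_prev = j * dt
        t_now = (j + 1) * dt
        if j % spf == 0:
            E_cur[active] = mu[active] + stim.sigma_E * rng.standard_normal(active.size)
            if frame_records is not None:
                frame_records.append((j // spf, active.copy(), E_cur[active].copy()))
        x_prev = x[active].copy()
        x[active] += phi[active] * E_cur[active] * (dt / stim.t_f)
        if sqdt > 0:
            x[active] += sqdt * rng.standard_normal(active.size)
        E_cum[active] += E_cur[active] * (dt / stim.t_f)

        pre_sel = phase[active] == 0
        pre = active[pre_sel]
        if pre.size:
            f_now = float(f(t_now))
            f_prev = float(f(t_prev))
            xp = x[pre]
            xq = x_prev[pre_sel]
            up = xp >= f_now
            lo = (xp <= -f_now) & ~up
            if bridge:
                interior = ~up & ~lo
                u = rng.random(pre.size)
                with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
                    pu = np.exp(-2.0 * np.maximum(f_prev - xq, 0.0) * np.maximum(f_now - xp, 0.0) / s2dt)
                    pl = np.exp(-2.0 * np.maximum(xq + f_prev, 0.0) * np.maximum(xp + f_now, 0.0) / s2dt)
                up_b = interior & (u < pu)
                lo_b = interior & ~up_b & (u < np.minimum(pu + pl, 1.0))
                up = up | up_b
                lo = lo | lo_b
            crossed = up | lo
            if np.any(crossed):
                idx = pre[crossed]
                R[idx] = np.where(up[crossed], 2, 1)
                t_d[idx] = t_now
                x_d[idx] = x[idx]
                E_pre[idx] = E_cum[idx]
                if I_steps == 0:
                    phase[idx] = 2
                    t_e_arr[idx] = t_now
                    x_final[idx] = x[idx]
                else:
                    phase[idx] = 1
                    pipe_left[idx] = I_steps

        pipe_sel = phase[active] == 1
        pipe = active[pipe_sel]
        if pipe.size:
            pipe_left[pipe] -= 1
            fin = pipe[pipe_left[pipe] == 0]
            if fin.size:
                phase[fin] = 2
                t_e_arr[fin] = t_now
                x_final[fin] = x[fin]

        if j + 1 >= deadline:
            cens = active[phase[active] == 0]
            if cens.size:
                censored[cens] = True
                phase[cens] = 2
        active = active[phase[active] != 2]
        j += 1

    ok = ~censored
    x_lp = np.full(n, np.nan)
    x_lp[ok] = x_final[ok] / theta(t_e_arr[ok], d)
    noise = params.sigma_m * rng.standard_normal(n)
    x_c = x_lp + noise
    C = np.full(n, -1, dtype=np.int64)
    if np.any(ok):
        C[ok] = bin_confidence(x_c[ok], R[ok], params.boundaries)

    trials = pd.DataFrame({
        "trial_id": np.arange(n), "condition": "free", "S": S, "R": R, "C": C,
        "t_r": t_e_arr, "t_e": t_e_arr, "t_d": t_d, "censored": censored,
        "E": E_cum, "E_pre": E_pre, "E_bar": E_pre / t_d, "delta_E": E_cum - E_pre,
        "phi": phi, "x_d": x_d, "x_final": x_final, "x_lp": x_lp, "x_c": x_c,
    })[TRIAL_COLUMNS]

    frames_df = _frames_long(frame_records) if sim.keep_frames else None
    return trials, frames_df
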