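# Methods

## Model

A trial presents one of two stimuli (`S = 1` or `2`, equiprobable).  The
difference-in-evidence per stimulus frame is `E_i ~ N(mu, sigma_E^2)` with
`mu = ±delta_mu`; frames last `t_f` seconds and evidence is delivered
uniformly in time within a frame.  The observer accumulates the noisy
difference of evidence measurements,

    delta x_j ~ N(phi * delta E_j, sigma_acc^2 * delta t),

with a per-trial drift-rate scaling `phi ~ N(1, sigma_phi^2)` (constant within
a trial).  From the observer's side the mean accumulation rate is
`nu ~ N(±nu0, sigma_nu^2)` with `nu0 = delta_mu / t_f`,
`sigma_nu = nu0 * sigma_phi`, and increments have variance
`s^2 = sigma_acc^2 + sigma_E^2 / t_f` per unit time.  The scaled log-posterior
ratio is `x_lp = x / theta(t)`,
`theta(t) = (s^2 + t * sigma_nu^2) / (s^2 + sigma_nu^2)`, and `x_lp / K` with
`K = (s^2 + sigma_nu^2) / (2 nu0)` is exactly the log-posterior odds
`2 nu0 x / (s^2 + t sigma_nu^2)`; this identity fixes the reading of the
scaling (division by `theta`) and is enforced by a quadrature oracle that
marginalises `nu` numerically.  Confidence reports are ordinal: the noisy
readout `x_c ~ N(x_lp, sigma_m^2)` is cut at boundaries `d_1 < ... < d_{n-1}`
(applied to `-x_c` after `R = 1`); bins are left-closed and the extreme bins
extend to infinity, so the categorical distribution always normalises even
when metacognitive noise pushes the readout against the choice.

**Interrogation.**  With `t_e` fixed by the experimenter and no thresholds,
`x_lp | E` is normal with mean `mu_lp = E / theta(t_e)` and variance
`sigma_lp^2 = (E^2 sigma_phi^2 + t_e sigma_acc^2) / theta(t_e)^2`; the
response truncates it to a half line.  Adding readout noise, the category
probabilities are differences of bivariate normal CDF values,

    p(C=i | R=2, E) = [ BvN(g~, e_{i+1}; rho) - BvN(g~, e_i; rho) ] / Phi(mu_lp/sigma_lp),

with `g~ = mu_lp / sigma_lp`, `h = sigma_lp / sigma_m`,
`rho = -h / sqrt(1+h^2)`, `e_i = (d_i - mu_lp) / sqrt(sigma_m^2 + sigma_lp^2)`
(boundary-extended to ±inf).  The `R = 1` case is computed by the exact mirror
map (`E -> -E`, `R -> 2`), which the L-signed form reduces to; this makes the
mirror-symmetry invariant exact to machine precision.  With `sigma_m = 0` the
distribution is the binned mass of the truncated normal itself, so categories
wholly opposing the choice receive exactly zero mass (the observer never
reports confidence below 50%).

**Free response.**  The observer responds when `|x|` first reaches a threshold
`f(t)`; three families are shipped (constant `a`; linear `max(a - b t, c)`;
exponential `c + (a-c) exp(-t/tau)`), covering flat and decreasing thresholds.
Stimulus information from the final `I` seconds (the pipeline) reaches
confidence only.  From `(R, t_r)`: `t_d = t_r - I`, `x_d = ±f(t_d)`.  The
drift-rate scaling posterior combines the `N(1, sigma_phi^2)` prior with the
first-passage kernel, approximating the pre-decision evidence stream by its
time average `E_bar`:

    m_phi = (sigma_acc^2 + x_d sigma_phi^2 E_bar) / (sigma_acc^2 + t_d sigma_phi^2 E_bar^2)
    v_phi = sigma_phi^2 sigma_acc^2 / (sigma_acc^2 + t_d sigma_phi^2 E_bar^2)

written division-free so `E_bar = 0` (posterior = prior) and tiny `t_d` are
safe.  Propagating the realized pipeline evidence `delta_E` gives

    mu_lf = (x_d + delta_E * m_phi) / theta(t_e),
    sigma_lf^2 = (delta_E^2 * v_phi + sigma_acc^2 * I) / theta(t_e)^2,

and the category probabilities are normal-CDF differences with total variance
`sigma_lf^2 + sigma_m^2` (point mass on the bin containing `mu_lf` if that
variance is zero).  At `sigma_phi = 0` these reduce exactly to the
no-variability conditionals (`mu_lf = (x_d + delta_E)/theta(t_e)`), and the
predictions are then exactly calibrated; with `sigma_phi > 0` the `E_bar`
approximation and the independence approximation `p(phi | E_bar) ≈ p(phi)`
introduce small discrepancies, most visibly an overestimate of report
variability at long response times.  Predictions depend on the frame stream
only through `(E_bar, delta_E, t_d, t_e)`.

## Parameters

| name | meaning | units | default |
|---|---|---|---|
| `delta_mu` | absolute mean difference-in-evidence per frame | evidence | 0.12 |
| `sigma_E` | SD of per-frame difference-in-evidence | evidence | 0.25 |
| `t_f` | frame duration | s | 0.025 |
| `sigma_acc` | accumulator noise SD | evidence / sqrt(s) | 1.0 |
| `sigma_phi` | drift-rate scaling SD | – | 0–0.5 by experiment |
| `sigma_m` | metacognitive noise SD | x_c units | 0.3 |
| `pipeline_I` | pipeline duration | s | 0.1 |
| `d_i` | confidence boundaries | x_c units | (0.5, 1.0, 1.5) |
| `f(t)` | decision threshold | evidence | constant 1.0 |

`delta_mu`, `sigma_E`, `t_f` are experiment-known constants, never fitted;
they anchor the evidence scale and make the remaining parameters identifiable.
Time is in seconds throughout; evidence units are whatever the frame table
provides.

The defaults are a stated world chosen once: 40 Hz frames, drift
`nu0 = 4.8 /s` against unit accumulator noise and stimulus-driven variance
`sigma_E^2/t_f = 2.5 /s`, flat unit threshold.  This produces accuracies near
90% and decision times of a few hundred milliseconds, and places the two
competing influences on error-trial confidence — the time-dependence of the
readout (through `theta`) and the corrective pipeline evidence — in the regime
where 100 ms of pipeline evidence reverses the sign of the
signal-strength/confidence relationship on errors, the qualitative phenomenon
the signal-strength experiment probes.  With frame noise much larger than the
frame signal (e.g. `sigma_E/delta_mu ≈ 5` at 20 Hz) a different mechanism
dominates instead: the frame that pushes the accumulator across the threshold
persists into the pipeline and favours the choice, and the reversal
disappears.  This sensitivity is a genuine property of the model, not of the
implementation.

## Simulator

Interrogation trials are sampled exactly: the accumulation is linear and
unconstrained, so `x(t_e) = phi E + N(0, sigma_acc^2 t_e)` is distributionally
identical to summing Euler increments.  Free-response trials use explicit
Euler stepping (default `dt = 1 ms`; `dt` must divide `t_f` and `I`), with the
stimulus generated lazily frame by frame until the response, and a censoring
horizon `t_max = 10 s` (censored trials are flagged, never dropped).

Threshold crossing is detected on the post-step state *and*, by default, by a
Brownian-bridge within-step test: given step endpoints below the barrier, the
path crossed within the step with probability
`exp(-2 (f - x_prev)(f - x_next) / (sigma_acc^2 dt))` (drift does not enter
the bridge crossing probability).  Naive post-step detection has an
`O(sqrt(dt))` first-passage bias — at `dt = 1 ms` it delays the mean decision
time by about 6 ms and shifts the recorded crossing state upward by about half
a step-noise SD, enough to spoil calibration tests against the continuous-time
closed forms.  The bridge test reduces the bias to `O(dt)`: the simulated mean
decision time matches the exact Wiener first-passage mean
`(a/nu) tanh(a nu / sigma_acc^2)` within Monte-Carlo error.  Naive detection
remains available (`crossing="euler"`).  The recorded `x_d` is the actual
(slightly overshooting) state; analytic predictions use `±f(t_d)` exactly, a
deliberate mismatch that vanishes as `dt -> 0`.  Calibration tests at
`sigma_phi = 0` use `dt = 0.25 ms` so the residual discretisation bias stays
well below the test tolerance.

One seeded NumPy generator drives each simulation batch (vectorised stepping
with active-set compaction); the reproducibility contract is at batch level —
the same seed and configuration give bit-identical tables.

## Numerical choices

* Bivariate normal CDF through Owen's T (`scipy.special.owens_t`), accurate to
  ~1e-14, vectorised, with explicit `|rho| -> 1` limits and infinite-limit
  handling; cross-checked against `scipy.stats.multivariate_normal` in tests.
* When the interrogation normaliser `Phi(L mu_lp / sigma_lp)` would underflow
  (`L mu_lp / sigma_lp < -7`, i.e. a response opposing strong evidence), the
  BvN route is replaced by Gauss–Legendre quadrature over the truncated
  normal's quantile function, which is stable arbitrarily far into the tail.
* Confidence-bin ties go to the upper bin (left-closed bins) — a measure-zero
  convention fixed for determinism.
* The oracle integrates the pre-closed-form integrals directly: the density of
  `x_lp` is built by numerically marginalising `phi` (160-node Gauss–Legendre
  over ±10 prior SDs), then category masses come from adaptive quadrature
  (`scipy.integrate.quad`, tolerances ≤ 1e-10) and are normalised by the
  numerically computed response probability.  Halving tolerances changes no
  category probability by more than 1e-8.  The oracle imports nothing from the
  closed-form modules.
* Calibration of conditional categorical predictions uses the randomized
  probability integral transform, `u = F(C-1) + V p(C)`, `V ~ U(0,1)`, KS-
  tested against uniformity: free-response conditioning `(R, t_r, E)` is
  continuous and never repeats, so per-condition frequency tests are
  unavailable.
* Likelihood probabilities are floored at 1e-300 before the log; the count of
  floored trials is reported as a diagnostic.  Fitting uses Nelder–Mead on
  transformed parameters (log scales for SDs and `I`; first boundary plus
  log-increments for the ordered boundaries) with jittered restarts;
  standard errors come from the numerical observed information with the delta
  method.

## Identifiability

With `sigma_phi = 0` and a fixed pipeline `I`, the free-response likelihood
depends on `(sigma_acc, sigma_m)` only through the total readout variance
`sigma_acc^2 I + sigma_m^2`: the two are not separately identifiable from
confidence reports alone (a flat likelihood ridge, covered by a test).  With
`sigma_phi > 0` fixed at a known value, `m_phi` and `v_phi` vary across trials
through `(E_bar, t_d, x_d)` and the two noise parameters decouple; the
parameter-recovery study therefore generates and fits with
`sigma_phi = 0.3` held at truth and recovers `sigma_acc`, `sigma_m` and three
boundaries from 1e4 trials to within a few percent.  `I` is fittable only from
free-response data.

## What the generator does and does not emulate

The synthetic world contains exactly the stated generative structure:
normally fluctuating frames, normal drift-rate scaling, Gaussian accumulation
noise, deterministic thresholds, a fixed-duration pipeline, Gaussian
metacognitive noise.  It contains no lapses, no start-point or pipeline-
duration variability, no perceptual (low-pass) integration stage, and no
non-normal evidence or inter-frame correlation.  A green calibration or
recovery test therefore establishes correctness of the expressions *under the
model's own assumptions*, not robustness to these unmodelled features.

## Limitations

* The response/response-time likelihood itself is out of scope; the package
  conditions on `(R, t_r)` and models confidence only.  Consequently the
  threshold shape and `I` cannot be inferred from response times alone, and
  censored trials contribute no likelihood.
* Free-response predictions with `sigma_phi > 0` are approximate (average-
  evidence and prior-independence approximations); binned mean confidence
  stays within ~0.03 category units of simulation in the stated world, but an
  approximation that works for one parameter regime may not for another.
* Interrogation-condition decision thresholds, multi-accumulator (race)
  architectures and continuous confidence scales are not modelled.
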