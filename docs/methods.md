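# Methods

`oculopharm` simulates a delayed oculomotor (memory-guided saccade) task
with a hybrid generative model: a discrete Markov decision process decides
*where to look and when*, and a continuous attractor filter implements *how
the eye gets there*. Four precision parameters act as synthetic
neuromodulators, and the package's experiments are parameter sweeps that
reproduce drug-like oculomotor syndromes.

## The discrete model

One trial has `T = 4` epochs of 250 ms — cue, delay, go, feedback (extra
delay epochs can be configured). Three hidden-state factors generate
outcomes:

* **fixation location** (5 states: central cross + up/down/left/right) —
  the only controllable factor; an action is simply the location saccaded
  to, so transitions are deterministic given the action;
* **target location** (4 states) — static in the generative process; the
  agent's transition belief keeps 0.9 of the mass on the diagonal (see
  "Base softness" below);
* **trial stage** (4 states) — advances deterministically, final stage
  absorbing.

Four outcome modalities: the **target cue** (4 directions + none; visible
only during the cue stage, 0.99 on the true direction), the **cross
colour** (red during the delay, blue otherwise), **feedback**
(null / correct / incorrect; 'incorrect' during the delay whenever fixation
has left the cross, and correct/incorrect at the go and feedback stages
according to whether fixation matches the target), and **proprioception**
(the fixation location, 0.95 on the true location). Log-preferences are
zero everywhere except feedback: +4 nats for 'correct', −4 for 'incorrect'.
The generative process additionally latches premature saccades: once
fixation leaves the cross during the delay, the trial is scored incorrect
even if the eye returns.

Policies are temporally deep: all `5^(T-1) = 125` action sequences are
enumerated and evaluated at every epoch; policies inconsistent with the
realised action history are not pruned but suppressed through their
variational free energy (their predicted proprioception mismatches the
observations). Keeping them in play is what gives the policy *prior*
(which only sees the future) and the policy *posterior* (which also sees
the past) different shapes, and hence non-trivial simulated dopamine
transients.

## Inference

State inference is structured variational smoothing: the posterior
factorises across hidden-state factors but keeps each factor's temporal
chain intact. One sweep updates a factor's whole chain by exact
forward–backward smoothing under the expected log-likelihood messages from
the other factors; sweeps repeat to convergence (max change < 1e-4, at most
16 sweeps; non-convergence is flagged and the last iterate returned). Each
sweep is an exact block-coordinate-descent step on the structured free
energy, so `F` is non-increasing across sweeps, and for a single-factor
model the result is exact Bayesian smoothing (we verify both against brute
force enumeration). A naive fully factorised mean field was rejected
because the strongly coupled target chain collapses to over-confident
one-hot beliefs, destroying the graded delay-period activity the
simulations are about.

Expected free energy per policy is risk plus ambiguity summed over future
epochs: the KL divergence from predicted outcomes to `softmax(C)` plus the
expected conditional entropy of the likelihood mapping. The policy prior is
`softmax(−γG)`, the posterior `softmax(−γG − F)`; both are shift-invariant
in `G` and `F`. The policy precision follows the fixed point
`β = β₀ + (π_post − π_prior)·G`, iterated with damped half-steps (16 per
epoch, clipped at 1/64, carried across epochs); the iteration-indexed
`γ = 1/β` is the simulated dopaminergic firing trace. Actions are sampled
from the policy-marginal action distribution (greedy and forced-uniform
modes exist for canonical rasters and the chance oracle).

All probabilities are floored at 1e-16 before logs; zero-temperature ties
resolve to the lowest index.

## The four precisions

| parameter | acts on | synthetic transmitter | default |
|---|---|---|---|
| `zeta` | all likelihood arrays (power + renormalise) | acetylcholine | 1.0 |
| `omega` | target-location transitions | noradrenaline | 4.0 |
| `beta` (`γ = 1/β`) | softmax over policies | dopamine | 0.5 |
| `pi_motor` | stationarity prior of the plant | GABA | 1.0 |

`omega` is applied to the target factor only: fixation transitions are the
agent's own efference and the stage clock is structural, and flattening
them would produce large kinematic and timing effects that contradict the
intended "physiology changes, behaviour preserved" phenomenology of the
noradrenaline manipulation.

**Base softness.** The precision operator is a pure inverse temperature, so
a strictly one-hot mapping is a fixed point at every positive precision.
Every mapping a precision parameter is meant to modulate therefore carries
a small base softness in the *agent's* model (cue 0.99, proprioception
0.95, feedback 0.995, target transitions 0.9 diagonal), while the
generative process stays exact. These four constants were calibrated
jointly so that, at defaults, ≥95% of trials are correct with a single
well-timed saccade; the cholinergic sweep saturates at the top of its grid;
delay-period persistence spans ~0.35–0.99 over the noradrenaline grid; and
the dopamine trace is flat (<5% excursion) at the highest policy precision
while showing bursts and dips at intermediate ones. The balance between cue
(0.99) and feedback (0.995) evidence matters for the last property:
policies whose imagined history misreads the response feedback must acquire
a clear (≈4 nat) expected-free-energy penalty, otherwise they retain prior
mass at high γ and leak into the precision update.

## The continuous plant

Each epoch launches a fresh second-order filter per axis toward the
attracting point η:

    mu_ddot = k_eff (η − mu) − λ_eff mu_dot,   eye_dot = (mu − eye)/τ_r
    k_eff = k·p_t/(p_t + Π),   λ_eff = λ₀ + c_λ·Π

with `k = 9·10⁴ s⁻²`, `p_t = 1`, `λ₀ = 174 s⁻¹`, `c_λ = 271 s⁻¹`,
`τ_r = 2 ms`. The motor-prior precision Π is the gain of a competing
stationarity (fixation) prior: raising it both weakens the attraction
(precision-weighted averaging of flows) and deepens the damping, so a
Π excess gives slow, hypometric, eventually *broken* saccades (more than
one 250 ms epoch to arrive), and Π depletion gives an underdamped
overshoot at higher peak velocity. The constants were calibrated for that
phenomenology with a damping ratio ≈0.45 at Π = 0.25, ≈1.05 at the default
Π = 1, and heavy overdamping at Π = 8; the velocity scale (~500 deg/s peaks
for 8° saccades) is in the physiological range but otherwise arbitrary —
only the ordering and shape carry meaning. The filter equations are a
declared reduction, not derived from a printed source: they reproduce the
stated precision phenomenology in the simplest linear form.

The linear system is discretised *exactly* with a matrix-exponential
propagator at `dt = 1 ms`, so integration is unconditionally stable and
refining `dt` only changes sampling resolution; a guard still rejects a
`dt` too coarse to resolve the dynamics. Belief state (`mu`, `mu_dot`)
re-initialises at the sensed eye position at each epoch boundary — each
discrete step launches a fresh continuous inference — which is what
separates a broken saccade into distinct velocity events.

Saccade events are maximal runs of speed above 5 deg/s that also pass
minimum-amplitude (0.5°) and minimum-duration (5 ms) filters. The
threshold is deliberately below the 30 deg/s convention for human data:
with a linear plant the second movement of a broken saccade peaks near
(remaining amplitude)/τ, which is bounded by ~12 deg/s once the first
movement has covered most of the 8° eccentricity, so a 30 deg/s threshold
cannot register broken saccades at all. The amplitude/duration filters
keep sub-degree corrective drift from being counted on clean trials.

## The bridge

Descending: the attracting point is the Bayesian model average of location
coordinates under the posterior-predictive proprioceptive distribution at
the next epoch, averaged over policies consistent with the selected action.
This is the lever by which a *categorical* precision changes a *continuous*
kinematic variable: flattening the likelihood mixes the commanded location
with its alternatives and pulls η toward the centre. Ascending: the
realised endpoint becomes categorical evidence through a squared-distance
softmax over locations (default sharpness 4 deg⁻²); the argmax is fed back
as the proprioceptive outcome, with the full distribution available for
diagnostics.

## Sweeps, rasters, chance and recovery

Sweeps vary one precision over a grid with the others at defaults,
aggregate per-trial metrics, and are reproducible bit-for-bit: each trial's
RNG is seeded by (master seed, grid index, trial index), so enlarging
`n_trials` never perturbs earlier trials. Default grids —
Π ∈ {0.25, 0.5, 1, 2, 4, 8}, ζ ∈ {0, 0.25, 0.5, 1, 2, 4},
β ∈ {64, 16, 4, 1, 0.25}, ω ∈ {0.5, 1, 2, 4} — straddle the qualitative
regimes of the respective manipulations. ω = 0 is deliberately excluded:
with no transition information the task is unlearnable and accuracy
necessarily collapses, whereas the noradrenaline phenomenology of interest
is graded physiology with preserved behaviour.

"Firing rates" are rate-coded posteriors: the raster rows are the
Bayesian-model-average probabilities of each target location at each
represented time, one column per observation epoch, extracted from a
deterministic canonical trial (greedy action selection), as in single-trial
raster figures. The **persistence index** is the belief in the true target
at the final represented time *as held at the last delay epoch*: read any
later and the response-stage feedback observation pins the target belief
regardless of ω, so the index would measure the feedback channel rather
than working-memory maintenance.

The chance level is computed empirically with a forced-uniform policy
posterior rather than assumed 1/4, because random deep policies must both
choose the right target and not break fixation during the delay (≈4%, not
25%). The ω×γ interaction experiment uses γ ∈ {0.25, 2} and ω ∈ {0.5, 4}:
at γ = 0.25 the high-ω condition retains partial performance, which is the
regime where the "noradrenergic blockade increases sensitivity to dopamine
depletion" prediction is expressible; at much lower γ both conditions sit
on the accuracy floor and the contrast vanishes into sampling noise.

Parameter recovery refits the policy precision by grid maximum likelihood
of the recorded action sequences. State inference does not depend on γ, so
the per-epoch (F, G) functionals are computed once per distinct trial
history (memoised) and the γ-dependent action likelihood is evaluated on
top for every candidate.

## What the simulations do and do not show

All inputs are generated internally; there is no empirical data path. The
generative process is noiseless (deterministic cue, colour and feedback;
deterministic plant), so all across-trial variability comes from action
sampling. Passing sweeps therefore demonstrate that the *precision
parameters reproduce the qualitative pharmacological phenomenology within
this model* — monotone dose-response directions, saturation, persistence,
interaction — not that the model quantitatively matches any printed
empirical velocity or accuracy value, and no such values are asserted.
Receptor subtypes, pharmacokinetics, multi-site drug action, blink-rate
physiology, anti-saccade variants and smooth pursuit are out of scope, as
is fitting to real eye-tracking recordings (parameter recovery is
synthetic-only). Problem sizes in the test suite and acceptance script
(8–48 trials per value for the deterministic kinematic sweeps, 200 per
value for the stochastic decision sweeps, 500 per interaction cell,
10–20 recovery replications of 200 trials) were chosen so that the
stochastic checks have 2-standard-error resolution well below the effect
sizes they test.
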