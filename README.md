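# oculopharm

Active-inference simulations of oculomotor pharmacology: a discrete
Markov-decision-process model of a delayed (memory-guided) saccade task
coupled to a continuous saccade generator, in which four precision
parameters play the role of neuromodulators. Sweeping them reproduces the
oculomotor syndromes associated with the corresponding drug classes — for
computational neuroscientists and psychopharmacology modellers who want a
compact, fully seeded sandbox for precision/neuromodulator hypotheses.

## The model in brief

A trial has four 250 ms epochs: **cue** (a peripheral target flashes while
the subject fixates a cross), **delay** (the cross turns red; moving is an
error), **go** (the cross turns blue; saccade to the remembered location)
and **feedback**. Hidden states factorise into fixation location
(controllable, 5 states), target location (static, 4 states) and trial
stage. The agent holds a categorical generative model `(A, B, C, D)` and
evaluates all 125 temporally deep policies π by their expected free energy

    G(π) = Σ_τ  KL[ Q(o_τ|π) ‖ softmax(C) ]  +  E_Q[ H[P(o_τ|s_τ)] ]

with policy posterior `softmax(−γG − F)`. Four precisions are the synthetic
pharmacology:

| precision | mechanism | transmitter | depletion → | excess → |
|---|---|---|---|---|
| ζ | likelihood sharpness (A^ζ) | acetylcholine | hypometric, slow, mistimed saccades | saturation at optimal kinematics |
| ω | transition sharpness (B^ω) | noradrenaline | delay-period activity fades (behaviour preserved) | persistent activity → 1 |
| γ = 1/β | policy softmax temperature | dopamine | random, mistimed choices; dopamine transients | flat, confident dopamine trace |
| Π | motor (fixation) prior gain | GABA | overshoot, faster saccades | slow, broken saccades |

The categorical level hands the continuous plant an attracting point — the
belief-weighted average of location coordinates — and the realised endpoint
returns as the next proprioceptive outcome. That closed loop is how a
categorical precision (ζ) ends up changing a continuous quantity (peak
velocity). See `docs/methods.md` for the full account.

## Worked example

```bash
python examples/run_single_trial.py
```

prints

```
target: up   actions (0=stay at cross, 1..4=saccade to up/down/left/right): [0, 1, 1]
fixation state per epoch (cue, delay, go, feedback): [0, 0, 1, 1]
correct: True   premature: False
peak velocity: 512.7 deg/s for an 7.44 deg saccade, endpoint error 0.50 deg
saccade events per 250 ms segment: [0, 0, 1, 0]
```

i.e. the synthetic subject stays on the cross through cue and delay
(action 0 twice), saccades to the remembered "up" location exactly at go (a
single ~513 deg/s movement in the third segment), lands half a degree from
the target and holds through feedback. The other scripts in `examples/`
walk through each capability: `gaba_dose_response.py` (peak velocity
1008 → 31 deg/s across the Π grid, overshoot only at the bottom, broken
saccades at the top), `ach_dose_response.py` (velocity rising and
saturating in ζ), `dopamine_firing.py` (accuracy 3% → 100% across γ with
the simulated dopamine traces), `noradrenaline_rasters.py` (persistence
0.35 → 0.99 across ω at unchanged accuracy) and `gamma_recovery.py`
(re-estimating γ from choices).

The same entry points exist as a CLI for scripted runs:

```bash
oculopharm run-trial --seed 1
oculopharm sweep --param gaba --trials 20 --seed 1 --outdir out/
oculopharm interaction --trials 500 --seed 1
oculopharm recover --beta-true 4 --trials 200
oculopharm plot
```

Every output directory receives the resolved configuration and master seed;
identical configuration + seed reproduces every CSV byte for byte.

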