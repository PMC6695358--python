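"""One delayed-saccade trial at default precisions.

Builds the task's generative model, runs the full hybrid loop (categorical
inference -> attracting point -> continuous saccade -> proprioceptive
feedback) and prints what the synthetic subject did.
"""
from oculopharm import Precisions, TaskConfig, build_model, run_trial

cfg = TaskConfig()
model = build_model(cfg)
r = run_trial(model, Precisions(), true_target=0, seed=1, config=cfg)

print(f"target: up   actions (0=stay at cross, 1..4=saccade to up/down/left/right): {r.actions}")
print(f"fixation state per epoch (cue, delay, go, feedback): {r.fix_states}")
print(f"correct: {r.correct}   premature: {r.premature}")
print(f"peak velocity: {r.metrics.peak_velocity:.1f} deg/s for an "
      f"{r.metrics.amplitude:.2f} deg saccade, endpoint error "
      f"{r.metrics.endpoint_error:.2f} deg")
print(f"saccade events per 250 ms segment: {[m.n_saccades for m in r.segment_metrics]}")
# A correct trial holds fixation through cue and delay, then a single
# saccade in the go segment lands within a degree of the remembered target.
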