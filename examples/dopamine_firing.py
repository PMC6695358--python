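"""Synthetic dopamine: policy precision and simulated dopaminergic firing.

gamma = 1/beta is the inverse temperature of the softmax over deep policies.
Sweeping it reproduces the behavioural signature (choices collapse to chance
as gamma -> 0) and the physiological one: the iteration-indexed expected
precision is the simulated dopamine trace, showing transients when the
posterior over policies shifts and staying flat when inference is already
confident.
"""
import numpy as np

from oculopharm import chance_level, sweep_dopamine

table, traces = sweep_dopamine(n_trials=60, seed=0)
print(table.frame[["gamma", "accuracy"]].to_string(index=False))
chance, se = chance_level(n_trials=100, seed=0)
print(f"\nuniform-policy chance level: {chance:.3f} +- {se:.3f}")
for gamma, tr in zip(table.frame["gamma"], traces):
    dev = np.abs(tr - gamma).max() / gamma * 100
    print(f"gamma={gamma:<8g} max trace excursion {dev:5.1f}% of baseline")
# accuracy is monotone in gamma and matches the chance oracle at the lowest
# value; the firing trace is flat at the highest gamma (confident inference
# from the first epoch) and shows bursts/dips at intermediate levels.
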