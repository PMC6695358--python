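"""Synthetic GABA (motor-prior precision) dose-response.

Sweeps the precision of the stationarity prior in the brainstem attractor:
high values (a benzodiazepine-like excess) make belief updating sluggish, so
saccades slow down and eventually break into multiple movements; low values
release the fixation prior and saccades overshoot at higher velocity.
"""
from oculopharm import sweep_gaba

table = sweep_gaba(n_trials=8, seed=0)
cols = ["value", "peak_velocity", "overshoot_rate", "saccades_to_arrival", "accuracy"]
print(table.frame[cols].to_string(index=False))
# peak_velocity falls monotonically with the motor prior precision (the
# inverse dose-response); overshoot appears only at the lowest value and the
# highest value needs >= 2 movements to reach the target (a broken saccade).
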