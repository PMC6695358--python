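"""Synthetic noradrenaline: transition precision and delay-period activity.

omega controls how confidently the agent propagates its belief about the
(static) target location through time. The raster of belief-derived firing
rates shows whether the cue percept survives the delay; behaviour is largely
preserved because deep policies, committed to after the cue, carry the plan
even when the memory trace fades.
"""
from oculopharm import sweep_noradrenaline

table, rasters = sweep_noradrenaline(n_trials=40, seed=0)
print(table.frame[["value", "accuracy", "persistence"]].to_string(index=False))
print()
for r in rasters:
    final_block = r.matrix[-4:, :]  # beliefs about the last represented time
    print(f"omega={r.omega:g}: persistence={r.persistence:.3f}  "
          f"P(true target at final time) per epoch = "
          f"{[round(float(x), 3) for x in final_block[r.true_target]]}")
# persistence (the delay-period belief in the true target at the final
# represented time) rises strictly with omega and approaches 1, while
# accuracy barely moves across the grid.
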