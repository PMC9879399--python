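"""A complete synthetic validation study, end to end.

Simulates 5 subjects x 2 repetitions of all four motor tasks, degrades
each reference recording into a sensor recording (default noise preset),
runs preprocessing, alignment and parameter extraction for both systems,
and prints the per-parameter accuracy table plus a signal-accuracy
summary for a few landmarks.
"""

import pandas as pd

from mocapval import RunConfig, SimulationBlock, Task, run_validation

config = RunConfig(
    simulation=SimulationBlock(
        n_subjects=5,
        repetitions={t: 2 for t in Task},
        noise_scale=1.0,
    ),
    seed=0,
)
result = run_validation(config)

pd.set_option("display.width", 140)
print("parameter accuracy (sensor vs reference, first repetition):")
cols = ["task", "parameter", "ref_mean", "sensor_mean", "mean_diff", "pearson_r", "icc_a1"]
print(result.report.accuracy[cols].round(3).to_string(index=False))
print()
print("signal accuracy (per landmark, mean over recordings):")
sig = result.signal_table.set_index("landmark")
sel = sig.loc[["head", "spine_base", "wrist_l", "knee_l", "ankle_l"]]
print(sel[["rmse_mm", "r_ap", "snr_ap_db", "snr_v_db"]].round(2).to_string())
print()
print(
    "RMSE grows from trunk to feet (the injected noise gradient); ICC(A,1)"
    " close to 1 marks parameters the simulated sensor measures"
    " interchangeably with the reference, while noise-dominated quiet-stance"
    " sway parameters collapse toward zero agreement."
)
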