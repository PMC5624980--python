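"""Contrast two feeding regimes by their pellet-concentration time courses.

Simulates two fed-batch scenarios — pellet load declining in favour of
dispersed growth vs a constant pellet load — runs the full pipeline per
timepoint and prints the per-class concentration series plus a Kendall
trend statistic on the pellet concentrations.
"""

import numpy as np
from scipy import stats

import pulsemorph as pm

timepoints = list(np.linspace(0.0, 140.0, 8))
scenarios = {
    "declining": pm.drifting_pellet_scenario("declining", timepoints, 0.30, 0.02),
    "constant": pm.drifting_pellet_scenario("constant", timepoints, 0.30, 0.30),
}

for name, scenario in scenarios.items():
    summaries = []
    for records, truth, meta in pm.simulate_timecourse(
        scenario, pm.SimParams(n=600, seed=23)
    ):
        table, counts = pm.classify_run(records)
        summaries.append(pm.summarize_run(table, meta))
    tc = pm.timecourse(summaries)
    pellets = tc[tc["class"] == "pellet"]
    tau, p = stats.kendalltau(pellets["timepoint"], pellets["concentration_per_ml"])
    print(f"scenario {name}:")
    print(pellets[["timepoint", "concentration_per_ml", "sws_fraction_pct"]]
          .round(1).to_string(index=False))
    print(f"  Kendall tau of pellet concentration vs time: {tau:+.2f} (p={p:.3f})")
    print()

print("A strongly negative tau marks the declining-pellet regime; the constant")
print("regime fluctuates around its level without a systematic trend (with only")
print("~200 pellets counted per measurement, individual series can still drift).")
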