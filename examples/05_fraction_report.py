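"""Per-fraction MLC performance monitoring, as used for treatment QA.

Simulates three fractions of a modulated plan, reconstructs each with the
optical method, and summarises executed-vs-planned LOTs per fraction —
the phantomless check that replaces pretreatment measurements in adaptive
workflows.
"""

import numpy as np

from tomolot import (
    DeliveryPlan,
    LeafMotionModel,
    compute_lots_optical,
    fraction_report,
    simulate_delivery,
)

rng = np.random.default_rng(0)
n_proj = 51
lot = np.zeros((64, n_proj))
for leaf in range(24, 40):  # a 16-leaf modulated field
    lot[leaf] = rng.uniform(60.0, 320.0, n_proj)
plan = DeliveryPlan("helical_demo", n_proj, 345.0, 2.5, lot, gantry_mode="static")

model = LeafMotionModel()
sinograms = []
for fraction in range(1, 4):
    delivery = simulate_delivery(plan, model, seed=100 + fraction)
    sinograms.append(compute_lots_optical(delivery.log, plan, tau_opt=0.57))

table = fraction_report(sinograms, plan)
cols = ["fraction", "mean_ms", "median_ms", "sd_ms", "min_ms", "max_ms",
        "pct_short", "pct_very_short", "mean_discrepancy_ms"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.1f}"))

print("\npct_short counts LOTs below 100 ms (harder for a pneumatic leaf to")
print("execute accurately); pct_very_short below 50 ms, where the leaf cannot")
print("fully close between openings.  mean_discrepancy_ms is executed minus")
print("planned, averaged over the plan's open cells: the simulated +1.8 ms")
print("systematic offset plus a small optical overestimate wherever short")
print("commanded gaps kept the leaf from closing fully.  The key QA signal is")
print("that all statistics are stable from fraction to fraction.")
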