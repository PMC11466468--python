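"""Simulate one delivery and reconstruct its LOTs with both methods.

A small 8-projection plan keeps this fast.  The simulator executes the plan
under a realistic leaf-motion model (finite transitions, +1.8 ms systematic
shift, 1 ms jitter, detector noise), then the MV-detector and optical-sensor
methods reconstruct what the leaves actually did.
"""

import numpy as np

from tomolot import (
    DeliveryPlan,
    LeafMotionModel,
    compute_lots_mv,
    compute_lots_optical,
    simulate_delivery,
    true_mean_lot,
)

lot = np.zeros((64, 8))
for leaf in (27, 39, 47):
    lot[leaf - 1] = 174.0  # 50% of the 348 ms projection
plan = DeliveryPlan("demo", 8, 348.0, 2.5, lot, lot_fraction_x=0.5)

model = LeafMotionModel()
delivery = simulate_delivery(plan, model, seed=7)

mv = compute_lots_mv(delivery.trace, plan, tau_mv=0.42)
opt = compute_lots_optical(delivery.log, plan, tau_opt=0.57)

print("mean LOT per leaf (ms) — planned 174.0, executed shift +1.8:\n")
print(f"{'leaf':>5}{'truth':>9}{'MV':>9}{'optical':>9}")
for leaf in (27, 39, 47):
    print(f"{leaf:>5}{true_mean_lot(delivery, leaf):>9.2f}"
          f"{mv.mean_lot(leaf):>9.2f}{opt.mean_lot(leaf):>9.2f}")

print("\nBoth reconstructions should sit within a few tenths of a ms of the")
print("fluence truth; the ~1.8 ms excess over the planned 174 ms is the")
print("simulated systematic executed-vs-planned offset.")
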