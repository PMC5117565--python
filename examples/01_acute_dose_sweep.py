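"""Acute steady-state dose sweep: which pathway collapses mitochondria first?

Holds the mitochondrial doxorubicin concentration constant, relaxes the model
to steady state for each pathway arm (ETC inhibition only, redox cycling
only, both), and locates the collapse threshold of each arm and the
concentration where ETC-driven ROS overtakes redox-cycling-driven ROS.
"""

import numpy as np

from mitotoxsim import DoxToxicityModel, acute_sweep

model = DoxToxicityModel()
grid = np.array([0.0, 30.0, 100.0, 160.0, 200.0])
res = acute_sweep(model, grid)

print("normalized steady-state indices (1 = drug-free baseline):")
print(f"{'arm':>5} {'dox uM':>7} {'dpsi':>6} {'atp':>6} {'superoxide':>10}")
for arm in ("etc", "rc", "both"):
    for i, d in enumerate(grid):
        idx = res.indices[arm]
        print(f"{arm:>5} {d:7.0f} {idx['dpsi'][i]:6.3f} "
              f"{idx['atp'][i]:6.3f} {idx['superoxide'][i]:10.3f}")

print("\ncollapse thresholds (uM):", {k: round(v, 1) for k, v in res.thresholds.items()})
print("ROS crossover (uM):", round(res.ros_crossover_um, 1))
print("""
Reading the numbers: redox cycling raises superoxide strongly while barely
touching membrane potential and ATP (its collapse threshold is far above the
clinical ~30 uM range), whereas ETC inhibition degrades function and becomes
lethal past ~200-270 uM; below the crossover concentration redox cycling is
the dominant ROS source, above it ETC inhibition takes over.""")
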