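"""Cavalieri volume estimation and the volume x density = total number step.

A synthetic series of cross-sectional areas (every third 80-um section) is
summed into a volume estimate; multiplying the whole-cortex density by the
volume converts it into a total count — the quantity in which the stress
effect appears even when densities are unchanged.
"""

import numpy as np

from stereosyn import cavalieri_volume, total_number
from stereosyn.morphometry import format_total
from stereosyn.study import simulate_area_series

rng = np.random.default_rng(7)
areas = simulate_area_series(0.211, n_sections=6, thickness_um=80.0, period=3, rng=rng)

total = cavalieri_volume(
    areas.groupby("section_index")["area_um2"].sum(), thickness=80.0, period=3
)
print(f"estimated IL volume: {total.volume:.3f} mm^3 (target 0.211)")

for label, density in [("asymmetric synapses", 5.46), ("myelinated axons", 0.47)]:
    n = total_number(density, total.volume)
    print(f"total {label}: {format_total(n)}  (density {density}/um^3)")
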