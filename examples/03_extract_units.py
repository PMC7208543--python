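"""Extract alternating motor units from a fine-grain series.

Two units with thresholds 0.3 mA apart are planted; the extraction chain
finds flickering voxels, clusters them by co-firing, groups frames into
void / no-void sets within each unit's alternation window, subtracts the
means and thresholds the map at 0.5 of its maximum.
"""

import numpy as np

from mumri import (
    MuscleMask,
    Phantom,
    extract_units,
    make_territory,
    plan_fine_schedule,
    simulate_series,
)

grid = (32, 32)
labels = np.zeros(grid, int)
labels[1:31, 1:31] = 1
mask = MuscleMask(labels, {1: "EDL"})

unit_a = make_territory("circular", (9, 9), {"radius_mm": 3.0}, grid, (1.5, 1.5),
                        threshold_mA=10.0, firing_width_mA=0.02)
unit_b = make_territory("ellipse", (22, 22), {"axes_mm": (10.0, 5.0), "angle_deg": 30.0},
                        grid, (1.5, 1.5), threshold_mA=10.3, firing_width_mA=0.02)
phantom = Phantom(mask, [unit_a, unit_b], 100.0, noise_sigma=0.03)
schedule = plan_fine_schedule(i_max_mA=10.45, step_mA=0.01, repeats=5, n_levels=70)
series, _ = simulate_series(phantom, schedule, seed=2)

detections = extract_units(series, mask, schedule)
print(f"detected {len(detections)} unit(s) in {series.n_dynamics} dynamics")
for det in detections:
    planted = unit_a if np.logical_and(det.territory, unit_a.territory).sum() else unit_b
    match = np.array_equal(det.territory, planted.territory)
    print(
        f"  unit {det.unit_id}: {int(det.territory.sum())} voxels, "
        f"activation threshold {det.stats.activation_threshold_mA:.2f} mA, "
        f"alternation range {det.stats.alternation_range_mA:.2f} mA, "
        f"territory equals planted map: {match}"
    )
print("The threshold estimates sit ~2x firing width below the planted logistic "
      "midpoints (10.0 / 10.3 mA): the lowest current with any firing.")
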