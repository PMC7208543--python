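"""Coarse-grain ramp: find the current at which muscle activity starts.

Simulates an ascending 0.1 mA ramp over a muscle with a pool of units whose
thresholds start at 10.2 mA, builds the ROI current-intensity profile, fits
the two-segment inflection and derives the fine-scan starting current
(five steps above the inflection).
"""

import numpy as np

from mumri import (
    MuscleMask,
    Phantom,
    compute_i_max,
    detect_inflection,
    make_territory,
    plan_coarse_schedule,
    roi_profile,
    simulate_series,
)

grid = (28, 28)
labels = np.zeros(grid, int)
labels[2:26, 2:26] = 1
mask = MuscleMask(labels, {1: "TA"})

units = [
    make_territory(
        "circular", (4 + 6 * (k // 5) + k % 2, 3 + 5 * (k % 5)), {"radius_mm": 1.7},
        grid, (1.5, 1.5), threshold_mA=10.2 + 0.1 * k, firing_width_mA=0.05,
    )
    for k in range(18)
]
phantom = Phantom(mask, units, 100.0, noise_sigma=0.02)
schedule = plan_coarse_schedule(start_mA=8.0, step_mA=0.1, n_dynamics=40)
series, _ = simulate_series(phantom, schedule, seed=1)

profile = roi_profile(series, mask, roi_label=1, schedule=schedule)
inflection = detect_inflection(profile)
i_max = compute_i_max(inflection, step_mA=0.1)

print(f"profile spans {profile.currents[0]:.1f}-{profile.currents[-1]:.1f} mA")
print(f"inflection (activity first visible): {inflection:.1f} mA "
      f"(lowest planted threshold 10.2 mA)")
print(f"fine-scan starting current I_max = inflection + 5 steps = {i_max:.1f} mA")
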