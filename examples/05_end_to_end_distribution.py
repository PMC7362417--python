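"""End-to-end distance distributions and their peaks.

The distance between the first phosphate at the DNA entry and at the exit
discriminates wrapped from unwrapped conformations: distinct unwrapping
states appear as distinct modes of its distribution.
"""

import numpy as np

from nucleowrap import (
    BreathingSpec,
    SuperhelixSpec,
    end_to_end_series,
    make_breathing_trajectory,
    summarize_distribution,
)

spec = SuperhelixSpec(n_bp=40, atoms_per_bp=1, core_bead_spacing=4.0)
traj = make_breathing_trajectory(
    spec, BreathingSpec(k_open=0.2, k_close=0.2, n_unwrap_open=12,
                        n_frames=4000, seed=7))
stat = end_to_end_series(traj)
print(f"end-to-end over {traj.n_frames} frames: "
      f"mean {stat.mean:.1f} +/- {stat.sd:.1f} A")

summary = summarize_distribution(stat.values, bin_width=2.0)
print(f"detected peaks (A): {np.round(summary.peaks, 1).tolist()}")
print("\nEach breathing state contributes its own mode: both ends open,")
print("both closed (the wrapped-state chord), and one end open, in that")
print("order; the peak finder reads them off the 2 A histogram after")
print("light smoothing.")
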