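"""The qualitative sterol dichotomy on synthetic membranes.

Cholesterol enrichment orders phospholipid tails; 7-ketocholesterol sits
more tilted in the bilayer and broadens its orientation distribution.
This script sweeps the generator's order target and the oxysterol tilt
mode and shows both trends in the recovered observables, with an unpaired
t-test comparing per-frame tilt means between the extreme conditions.
"""

import numpy as np

from cgsterol import compare_groups, sterol_tilt
from cgsterol.observables import tilt_angles
from cgsterol.recovery import recover_ground_truth
from cgsterol.synthetic import (
    default_ground_truth,
    generate_membrane,
    simulate_trajectory,
)

print("tail order rises with the order target (bond POPC/sn2/bond1):")
for scale in (0.7, 1.0, 1.3):
    gt = default_ground_truth(n_per_leaflet=48, n_frames=200, seed=5)
    targets = {
        sp: {t: tuple(scale * s for s in bonds) for t, bonds in tails.items()}
        for sp, tails in gt.order_targets.items()
    }
    gt = default_ground_truth(
        n_per_leaflet=48, n_frames=200, seed=5, order_targets=targets
    )
    rec = recover_ground_truth(simulate_trajectory(generate_membrane(gt), gt), gt)
    print(f"  target x{scale:.1f}: recovered P2 = "
          f"{rec.order['POPC/sn2/bond1']:+.3f}")

print("\n7KC tilt distribution widens as its tilt mode grows:")
frame_means = {}
for mode in (10.0, 30.0):
    gt = default_ground_truth(
        n_per_leaflet=48, n_frames=200, seed=11,
        tilt={"CHOL": (12.0, 15.0), "7KC": (mode, 15.0)},
    )
    traj = simulate_trajectory(generate_membrane(gt), gt)
    dist = sterol_tilt(traj, "7KC", ("K5", "KOH"))
    print(f"  mode {mode:4.0f}°: mean {dist.mean_deg:5.2f}°, "
          f"sd {dist.sd_deg:5.2f}°")
    angles = tilt_angles(traj, "7KC", ("K5", "KOH")).reshape(len(traj), -1)
    frame_means[mode] = angles.mean(axis=1)

res = compare_groups(frame_means[10.0], frame_means[30.0])
print(f"\nunpaired t-test on per-frame tilt means (10° vs 30° mode): "
      f"t = {res.t:.1f}, p = {res.p:.3g}"
      f"{' (significant at p < 0.05)' if res.significant else ''}")
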