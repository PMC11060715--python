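"""Tapered-beam slip metrics and string-pull kinematics.

Beam runs reduce to per-side slip counts and the distance to the first
slip; string-pull reaches to movement scaling (reach length vs peak
speed), path circuity (1 = perfectly direct) and the bimanual correlation
of detrended vertical paw positions.
"""

import numpy as np

from caim.behavior import (
    BeamEvent, BeamRun, beam_metrics, bimanual_correlation, movement_scaling,
    path_circuity, reach_path_stats,
)
from caim.synthetic import PawConfig, ReachSpec, generate_paw_trajectories

run = BeamRun(
    events=[
        BeamEvent(15.0, "right", "step"),
        BeamEvent(30.0, "left", "slip"),
        BeamEvent(50.0, "right", "slip"),
        BeamEvent(60.0, "left", "slip"),
    ],
    beam_length_cm=100.0,
)
left, right, first = beam_metrics(run)
print(f"beam: {left} left slips, {right} right slips, first slip at {first:.0f} cm")

segs = tuple(ReachSpec(80 * i + 10, 80 * i + 60, 10.0 * (i + 1), float(i + 1)) for i in range(3))
paw = generate_paw_trajectories(
    PawConfig(n_frames=300, left_segments=segs, mirror_right_from_left=True), seed=0
)
lengths, peaks, circ = reach_path_stats(paw.left_path, [(s.start, s.end) for s in segs])
print(f"reach path lengths {lengths} px, peak speeds {peaks} px/frame")
print(f"movement scaling r = {movement_scaling(lengths, peaks):.3f} "
      "(1 = longer reaches are reliably faster)")
print(f"path circuity per reach: {circ} (straight planted paths -> 1)")
r = bimanual_correlation(paw.left_path[:, 1], paw.right_path[:, 1] + np.linspace(0, 30, 300))
print(f"bimanual correlation (after detrending a postural ramp): {r:.3f}")
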