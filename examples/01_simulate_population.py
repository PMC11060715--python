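"""Generate a synthetic two-photon population recording with ground truth.

Plants 3 co-activating assemblies (one neuron shared between the first
two), background Poisson spiking, movement bouts, GCaMP6S-like kinetics
and neuropil contamination, then prints what was planted.
"""

import numpy as np

from caim.synthetic import GroundTruth, generate_population

gt = GroundTruth(
    n_neurons=50,
    duration_s=300.0,
    assembly_memberships=(
        frozenset(range(0, 10)),
        frozenset({5} | set(range(10, 19))),
        frozenset(range(20, 30)),
    ),
    movement_bouts=((60.0, 90.0), (180.0, 240.0)),
    seed=0,
)
rec = generate_population(gt)

print(f"recording: {rec.roi_fluorescence.shape[0]} neurons x {rec.roi_fluorescence.shape[1]} frames at {gt.frame_rate_hz} Hz")
print(f"planted spikes: {rec.true_spike_raster.sum()} "
      f"({rec.true_spike_raster.sum() / gt.n_neurons / gt.duration_s:.3f} Hz per neuron)")
for i, frames in enumerate(rec.assembly_event_frames):
    print(f"assembly {i}: {len(gt.assembly_memberships[i])} members, {frames.size} co-activation events")
print(f"fraction of time moving (ground truth): {rec.speed.moving_true.mean():.2f}")
print(f"mean ROI fluorescence {rec.roi_fluorescence.mean():.1f} a.u. "
      f"(baseline {gt.baseline_fluorescence} + neuropil contamination "
      f"{gt.neuropil_coefficient_true} x {gt.neuropil_baseline})")
# The spike raster and event frames are the ground truth every later
# analysis stage is checked against.
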