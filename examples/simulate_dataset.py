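"""Simulate a spike-LFP-behavior recording from a planted multiscale model.

Builds the default ground truth (a slow behavior-coupled mode at
1.1 s / 0.17 Hz among faster distractors), simulates 100 s of data, and
writes the canonical HDF5 dataset plus a ground-truth sidecar JSON.
"""

import numpy as np

import msmodes as mm

tb = mm.TimeBase(dt=0.01, k=5, T=0)
gt = mm.build_model(mm.default_mode_specs(), n_c=20, n_y=30, n_b=3,
                    timebase=tb, seed=0)
ds = mm.simulate(gt, T=10_000, seed=1)

mm.save_dataset(ds, "example_data.h5")
mm.save_ground_truth_json(gt, "example_truth.json")

rates = ds.spikes.mean(axis=0) / tb.dt
print(f"spikes: {ds.spikes.shape}  mean rate {rates.mean():.1f} spikes/s "
      f"(per-channel {rates.min():.1f}-{rates.max():.1f})")
print(f"lfp features: {ds.lfp.shape} at 50 ms steps; "
      f"behavior: {ds.behavior.shape} at 10 ms steps")
print("planted modes (decay s, frequency Hz):")
for s in gt.mode_specs:
    tag = " <- behavior-coupled" if s.behavior_coupled else ""
    print(f"  ({s.decay:g}, {s.frequency:g}){tag}")
# The behavior-coupled mode is the one the downstream pipeline should
# recover as the predictive mode.
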