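"""Fit the multiscale model and decode behavior from its latent state.

Learns the joint spike-LFP model (unsupervised, neural data only) with the
multiscale EM, runs the multiscale filter, regresses behavior on the
filtered states in the training half, and reports the test-half prediction
accuracy plus the learned modes.
"""

import numpy as np

import msmodes as mm
from msmodes.pipeline import filter_scale, slice_segments

tb = mm.TimeBase(dt=0.01, k=5, T=0)
gt = mm.build_model(mm.default_mode_specs(), n_c=20, n_y=30, n_b=3,
                    timebase=tb, seed=0)
ds = mm.simulate(gt, T=12_000, seed=2)

folds = mm.make_folds(ds, n_folds=2)
train = slice_segments(ds, folds[0].train_ranges)
test = slice_segments(ds, folds[0].test_ranges)

params, trace = mm.em_multiscale(train.spikes.astype(float), train.lfp,
                                 mm.EMOptions(n_x=7, max_iters=60, seed=0),
                                 train.timebase)
print(f"EM: {trace.iterations} iterations, converged={trace.converged}")

modes, _ = mm.extract_modes(params.A, tb.dt)
print("learned modes (decay s, frequency Hz):")
for m in sorted(modes, key=lambda m: -m.decay):
    print(f"  {m.kind:8s} decay {m.decay:6.3f}  freq {m.frequency:6.3f}")

fr_tr = filter_scale(train, params)
proj = mm.fit_projection(fr_tr.xf, train.behavior)
fr_te = filter_scale(test, params)
cc, mean_cc = mm.behavior_cc(test.behavior,
                             mm.predict_behavior(fr_te.xf, proj))
print(f"test behavior CC per dimension: {np.round(cc, 3)}")
print(f"mean CC {mean_cc:.3f} (chance level for this readout is 0)")

pp = mm.one_step_spike_pp(test.spikes, params, fr_te)
ccy = mm.one_step_lfp_cc(test.lfp, params, fr_te)
print(f"one-step neural prediction: spike PP {np.nanmean(pp):.3f}, "
      f"LFP CC {np.nanmean(ccy):.3f}")
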