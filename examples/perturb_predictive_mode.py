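"""Perturb the predictive mode's decay and frequency and watch CC fall.

Freezes the state transition matrix at a perturbed version of the learned
one (only the predictive mode's eigenvalue pair changes), refits all other
parameters with the constrained EM, and reports the cross-validated
behavior prediction accuracy per grid point.
"""

import numpy as np

import msmodes as mm
from msmodes.experiments import perturbation_experiment

tb = mm.TimeBase(dt=0.01, k=5, T=0)
gt = mm.build_model(mm.default_mode_specs(), n_c=20, n_y=30, n_b=3,
                    timebase=tb, seed=0)
ds = mm.simulate(gt, T=6000, seed=3)
ref = [m for m in mm.extract_modes(gt.params.A, tb.dt)[0]
       if abs(m.decay - 1.1) < 1e-9][0]

grid = perturbation_experiment(ds, ref,
                               decay_grid=np.geomspace(0.1, 10.0, 5),
                               freq_grid=np.geomspace(0.02, 3.0, 5),
                               n_x=7, seed=0, n_folds=2, eval_folds=1,
                               em_opts=mm.EMOptions(max_iters=30, seed=0))
print(f"baseline CC {grid.baseline_cc:.3f} at decay "
      f"{grid.baseline_decay:.2f} s, frequency "
      f"{grid.baseline_frequency:.3f} Hz")
print("decay sweep (s -> CC):")
for d, c in zip(grid.decay_grid, grid.decay_cc):
    print(f"  {d:6.2f} -> {c:.3f}")
print("frequency sweep (Hz -> CC):")
for f, c in zip(grid.freq_grid, grid.freq_cc):
    print(f"  {f:6.3f} -> {c:.3f}")
print("Shrinking the decay well below the planted 1.1 s degrades CC much "
      "more than growing it - the dynamics need to hold behavior-relevant "
      "information long enough, while extra memory is nearly harmless.")
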