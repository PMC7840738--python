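# Methods

## The model

`msmodes` analyzes simultaneous spiking and local field potential (LFP)
activity through latent linear dynamical models that share one state across
two time-scales. The latent state advances at the fast processing step
Δ = 10 ms:

    x_{t+1} = A x_t + w_t,          w_t ~ N(0, W)

Three observation models attach to this state:

* **Spikes** (every step): each channel's binary event N_t^c is a point
  process with conditional intensity λ_c = exp(α_c [1; x_t]); the per-step
  event probability is λ_c Δ, with Δ small enough that a bin holds at most
  one spike.
* **LFP features** (every k = 5 steps, i.e., 50 ms): a Gaussian linear
  readout y_t = C [1; x_t] + r_t, r_t ~ N(0, R), where y_t stacks band
  log-powers (theta 4–8, alpha 8–12, beta1 12–24, beta2 24–34, gamma1
  34–55, gamma2 65–95, gamma3 130–170 Hz) per channel.
* **Multiscale**: both streams jointly, conditionally independent given
  the state.

The constant is carried in the first column of `C` and `α`; the state never
includes it. Spike-channel and LFP-channel pools are disjoint so that no
electrode contributes to both streams.

Behavior (joint angles or end-point kinematics, sampled at the fast step)
never enters the likelihood: models are learned unsupervised from neural
activity, and behavior is read out afterwards by ordinary least squares on
the causally filtered states, `z_t ≈ L [1; x_{t|t}]`. The chance level of
the resulting Pearson correlation (CC) is 0, which the permutation control
verifies empirically.

### Modes

Eigendecomposing A = U E U⁻¹ turns the state equation into decoupled modal
coordinates. Each real eigenvalue, or complex-conjugate pair r·e^{±jθ},
is a **mode** with

    decay     = Δ / log(1/r)      [seconds; non-decaying if r ≥ 1]
    frequency = θ / (2πΔ)         [Hz; non-periodic if θ = 0]

Any linear readout F x_t decomposes exactly into per-mode contributions
col_i(FU)·row_i(U⁻¹x_t), with conjugate pairs summed (real-valued); the
contributions add back to F x_t to machine precision. This attribution is
how behavior prediction and one-step neural prediction are assigned to
individual modes.

## Estimation

One compiled kernel implements all three causal filters. The Kalman filter
updates only at slow-scale steps (pure prediction elsewhere); the
point-process filter applies the standard one-Newton-step Gaussian
approximation around the predicted mean (an iterated variant with up to
`pp_iters` Newton steps, tolerance 1e-8, is available and is used where a
posterior-mode oracle comparison needs it); the multiscale filter applies
the point-process update at every step and adds the Gaussian update at
slow-scale steps (point-process first — the order matters only at third
order and is fixed for reproducibility). Dropping a stream reduces the
multiscale filter to the corresponding single-scale filter bitwise, which
the tests assert. Covariances are symmetrized after every update, Joseph
form is used for the Gaussian update, and a 1e-9 jitter guards
ill-conditioned inversions. Smoothing is fixed-interval RTS on the
Gaussian approximations and returns the lag-one cross-covariances the EM
M-step needs.

### EM

* `em_lgssm` (LFP only) is exact EM for a linear Gaussian state-space model
  with a slow observation scale; its innovation-form log-likelihood is
  asserted non-decreasing (slack 1e-9) every iteration.
* `em_ppssm` (spikes only) and `em_multiscale` use the Gaussian-approximate
  E-step from the corresponding filter/smoother. A, W, x0, Λ0 (and C, R)
  have closed-form updates from the smoothed moments; each α_c row is
  updated by Newton ascent on the expected point-process log-likelihood
  under the Gaussian posterior (concave; diverging steps halved, up to 50
  times). Because the E-step is approximate, the monitored log-likelihood
  may dip transiently after initialization; a relative decrease beyond
  1e-4 stops the iteration only after a 10-iteration burn-in. We observed
  (and reproduce in tests at smaller scale) that the first M-step can
  lower the approximate likelihood by up to ~0.2 relative before a clean
  monotone recovery well above the starting value — aborting at the dip
  would return a near-initialization model.
* `em_constrained_A` freezes A (used by the perturbation experiment) and
  updates everything else.
* Convergence: relative log-likelihood change < 1e-6, max 500 iterations
  by default; experiments at desk scale cap iterations lower (noted per
  experiment below).

**Initialization** (`data_driven`, default): PCA of standardized
[Gaussian-smoothed spike counts ‖ LFP features held at the fast step],
lag-one least squares for A (shrunk to spectral radius ≤ 0.999), residual
covariance for W, OLS for C, and a few Newton steps of the point-process
GLM on the proxy states for α. This is cheaper than a preliminary
Gaussian-EM fit and equally reproducible. `random` draws block-rotation
transition matrices with eigenvalue magnitudes ~ U(0.90, 0.995).

With observations only every k steps, A is identified only up to k-th
roots of A^k; the data-driven initialization selects the principal branch,
which is the physically meaningful one for modes far below the slow-scale
Nyquist. The same ambiguity explains why fits to temporally shuffled
(white) LFP features produce spurious eigenvalues near 0.9^(1/k) ≈ 0.65 —
they are k-th roots of ≈ 0 dynamics and land far outside the eigenvalue
region where slow cortical modes live, which is why region membership is
part of the principal-mode criterion (below).

## Modal analysis pipeline

**Eigenvalue-dimension diagram.** Models are fitted at a sweep of latent
dimensions (1–25 in full runs; a subset at desk scale) on each
cross-validation fold's training set; every model contributes its modes
(θ ≥ 0 representatives) to the diagram, with per-mode cross-validated
behavior CC and one-step neural prediction metrics attached.

**Clustering.** Complex and real modes are clustered separately by K-means
with 50 restarts and a fixed seed. The number of complex clusters is the
median per-model complex-mode count over dimensions above 10 (over the
upper half of the fitted dimensions when none exceed 10); real modes get 4
clusters. Complex modes are clustered on standardized
(log decay, log frequency) coordinates rather than raw eigenvalue-plane
coordinates: near |e| = 1 the plane metric compresses order-of-magnitude
decay differences into tiny distances, and a K-means centroid placed
between two tight groups would lose all members to the deviation rule
below. Cluster centroids are reported in the eigenvalue plane (mean of
member eigenvalues); distances and all statistics remain eigenvalue-plane
Euclidean. A member whose relative decay or frequency deviation from its
centroid exceeds 50% is discarded as noise; if a centroid loses every
member this way, one centroid is added and clustering repeats (up to 3).

**Chance level and vertical clusters.** The chance-level distance is the
Monte Carlo mean distance between two points placed uniformly in a
reference rectangle of the eigenvalue plane. The reference region is a
configuration parameter; analyses here use (Re 0.85–1.01, Im 0–0.1), the
neighborhood of the unit circle where slow cortical modes live, and the
default otherwise is the 10%-padded bounding box of the diagram. A cluster
is **vertical** (principal) when its member-to-centroid distances are
significantly below half the chance level (one-sided Wilcoxon signed-rank,
BH-FDR corrected across clusters, ≥ 5 members), its median spread is below
half chance, and — when the region is caller-fixed — its centroid lies
inside the region.

**Predictive mode.** Among complex clusters with at least 3 members, the
one with the highest mean member behavior CC wins; it is flagged
predictive only if every one-sided rank-sum comparison against the other
candidate clusters is significant after BH-FDR, and it is itself vertical.

## Synthetic ground truth

The generator plants a block-diagonal A (2×2 scaled rotations for complex
modes, scalars for real ones) with state noise scaled so each modal
coordinate has stationary variance equal to its `variance_weight`. The
default planted structure mirrors the kind of configuration the method is
meant to resolve: a slow behavior-coupled mode (decay 1.1 s, frequency
0.17 Hz, weight 1.0), a faster distractor (0.3 s, 0.05 Hz, weight 0.5), a
high-frequency distractor (0.1 s, 1.0 Hz, weight 0.5), and one fast real
mode (0.1 s, weight 0.3) — latent dimension 7. Per-channel baseline rates
are drawn uniformly in 5–30 spikes/s with state loadings of norm 0.2–0.5
in units of latent SD (keeping λΔ in the at-most-one-spike regime; the
Bernoulli probability is clipped at 1 − 1e-6). LFP features get noise
floors at SNR 3 and behavior at SNR 4. The behavior readout touches only
the coupled mode's coordinates, so ground truth about which mode is
predictive is exact.

Controls: `shuffle_control` permutes each neural channel independently in
time; `simulate_behavior_representation` drives spikes (log-linearly) and
LFP (linearly) from behavior plus independent AR(1) nuisance processes
(coefficient 0.98), the surrogate for "neural activity merely represents
behavior".

What the generator does **not** emulate: nonstationarity, spike-sorting
errors, cross-channel correlated noise, 1/f LFP spectra, behavioral
condition structure, or nonlinear encoding. Passing tests therefore show
the pipeline recovers planted linear-Gaussian/point-process structure and
rejects its absence — not that cortical data satisfy those assumptions.

## Experiments and problem sizes

Desk-scale runs are sized so the whole suite fits comfortably on one CPU;
each experiment notes its sizes:

* **EM recovery**: LGSSM n_x=2 at T=20,000; multiscale n_x=7 at T=60,000
  with 20 spike + 30 LFP channels (eigenvalue errors ≲ 0.002–0.005).
* **Shared-mode pipeline**: T=20,000, dimensions {5,7,9,11}, one
  train/test split; predictive centroids of the three scales agree within
  0.01.
* **Channel sets**: 20 draws of 5 baseline channels (+25 of the other
  scale for the combined fit), T=6,000, n_x=7, 25 EM iterations. The
  median distance-to-truth comparison is the endpoint; at a 2-fold split
  the corrected resampled t-test's variance inflation (1/n + n_test/n_train)
  makes the paired test powerless by design, so it is reported, not relied
  on.
* **Identification battery**: 20 simulated sessions, LFP-only diagrams at
  dimensions {2,4,6,8,10,12}, T=7,500, 40 EM iterations; the coupled
  cluster is flagged dominant in ≥ 18/20; shuffled data yield no vertical
  complex cluster.
* **Perturbation**: 8 log-spaced decays in 0.1–10 s and frequencies in
  0.02–3 Hz, T=8,000, n_x=7, constrained EM ≤ 50 iterations. CC peaks in
  the grid cell containing the planted (decay, frequency); shrinking the
  decay 10× costs far more CC than growing it 10× — the asymmetry the
  perturbation analysis is designed to expose.

## Numerical choices and degenerate inputs

* Fold boundaries snap down to multiples of k; folds are contiguous
  temporal blocks by default (avoids leakage in autocorrelated series); a
  trailing partial block joins the last fold.
* Rates with λΔ > 10 abort filtering with the offending step/channel; an
  all-zero spike channel is rejected before EM ("degenerate channel").
* Rank-deficient OLS readouts fall back to a logged 1e-8 ridge; a
  zero-variance behavior dimension gets CC = missing and is excluded from
  means (the zero-variance test uses a relative tolerance, since a
  numerically constant series has std ~ machine-eps · |mean|).
* AUC uses the midrank Mann-Whitney formulation; channels with no events
  (or all events) are reported missing rather than 0.
* Negative real eigenvalues are real modes flagged "alternating" (decay
  from |e|), excluded from complex clustering. Near-defective A
  (eigenvector condition > 1e8) is rejected; the diagram skips that
  dimension with a warning.
* Behavior modal analysis runs with k=1 (behavior observed every step);
  measurement noise produces sub-step transient modes, so its summaries
  use principal modes with decay ≥ 0.1 s.
* All randomness flows through seeded `numpy` generators; every fit,
  simulation, and experiment is deterministic given (data, options, seed).

## Known limitations

* The approximate-E-step EMs carry no monotonicity guarantee; the burn-in
  guard is a heuristic, and strongly misspecified models can still stop
  early at the guard.
* With slow-scale-only observations the k-th-root branch ambiguity in A is
  resolved by initialization, not by the likelihood.
* K-means with the deviation discard is a pragmatic grouping device;
  cluster counts at low latent dimensions are noisy, and the merge-wipe
  guard is a safeguard, not a fix, for pathological geometries.
* The perturbation experiment perturbs one conjugate pair in the learned
  eigenbasis; if the learned A is far from the truth the "planted cell"
  interpretation degrades with it.
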