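"""Synthetic spike-LFP-behavior datasets from planted multiscale models.

The generator builds a latent linear-Gaussian state whose transition matrix
is block-diagonal with known (decay, frequency) modes, then emits

* Bernoulli spikes with log-linear rates at the fast (10 ms) step,
* Gaussian LFP log-power-like features at the slow (50 ms) step,
* behavior as a noisy linear readout of the latent state that touches only
  the modal coordinates of modes flagged ``behavior_coupled``.

It also provides the negative/positive controls used downstream: per-channel
time shuffling, and a "neural activity represents behavior" surrogate in
which spikes and LFP are driven directly by behavior plus nuisance AR(1)
processes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .datasets import NeuralDataset, TimeBase
from .preprocessing import DEFAULT_BANDS
from .ssm import ModelParams

__all__ = [
    "ModeSpec",
    "GroundTruth",
    "build_model",
    "simulate",
    "simulate_behavior_representation",
    "shuffle_control",
    "default_mode_specs",
    "default_ground_truth",
    "save_ground_truth_json",
]

PROB_CLIP = 1.0 - 1e-6   # Bernoulli probability cap (<=1 spike per bin)


@dataclass(frozen=True)
class ModeSpec:
    """A planted mode: decay tau (seconds), frequency f (Hz).

    ``f > 0`` implies a 2x2 rotation block with eigenvalues
    ``r exp(+-j theta)``, ``r = exp(-dt/tau)``, ``theta = 2 pi f dt``;
    ``f = 0`` implies a scalar block ``r``.  ``tau = inf`` plants a
    non-decaying mode (r = 1).
    """

    decay: float
    frequency: float = 0.0
    behavior_coupled: bool = False
    variance_weight: float = 1.0

    def block_size(self) -> int:
        return 2 if self.frequency > 0 else 1

    def eigenvalue(self, dt: float) -> complex:
        r = 1.0 if np.isinf(self.decay) else np.exp(-dt / self.decay)
        theta = 2.0 * np.pi * self.frequency * dt
        return r * np.exp(1j * theta)


@dataclass
class GroundTruth:
    """A planted model plus the behavior readout used to generate behavior."""

    params: ModelParams
    readout: np.ndarray           # (n_b, n_x+1), bias first
    mode_specs: list[ModeSpec]
    seed: int
    behavior_noise_sd: np.ndarray = field(default_factory=lambda: np.zeros(0))
    coupled_columns: tuple[int, ...] = ()

    @property
    def n_x(self) -> int:
        return self.params.n_x


def default_mode_specs() -> list[ModeSpec]:
    """The default planted structure: one slow behavior-coupled mode among
    faster distractors, plus one fast real mode (latent dimension 7)."""
    return [
        ModeSpec(decay=1.1, frequency=0.17, behavior_coupled=True,
                 variance_weight=1.0),
        ModeSpec(decay=0.3, frequency=0.05, variance_weight=0.5),
        ModeSpec(decay=0.1, frequency=1.0, variance_weight=0.5),
        ModeSpec(decay=0.1, frequency=0.0, variance_weight=0.3),
    ]


def build_model(mode_specs: list[ModeSpec], n_c: int, n_y: int, n_b: int,
                timebase: TimeBase, seed: int, *,
                rate_range: tuple[float, float] = (5.0, 30.0),
                alpha_norm_range: tuple[float, float] = (0.2, 0.5),
                lfp_snr: float = 3.0,
                behavior_snr: float = 4.0) -> GroundTruth:
    """Construct a ground-truth multiscale model with the planted modes.

    The state transition matrix is block-diagonal: a 2x2 scaled rotation per
    complex spec, a scalar per real spec.  State noise per block is scaled so
    each modal coordinate has stationary variance ~= its spec's
    ``variance_weight``.  Per-channel baseline rates land in ``rate_range``
    spikes/s; LFP features and behavior get noise floors set by their SNR.
    """
    dt = timebase.dt
    rng = np.random.default_rng(seed)
    blocks, wblocks, coupled_cols = [], [], []
    col = 0
    for spec in mode_specs:
        if spec.decay <= 0:
            raise ValueError(f"decay must be positive, got {spec.decay}")
        if spec.frequency < 0 or spec.frequency >= timebase.nyquist:
            raise ValueError(
                f"frequency {spec.frequency} Hz outside [0, Nyquist="
                f"{timebase.nyquist} Hz)")
        r = 1.0 if np.isinf(spec.decay) else np.exp(-dt / spec.decay)
        if spec.frequency > 0:
            th = 2.0 * np.pi * spec.frequency * dt
            blocks.append(r * np.array([[np.cos(th), -np.sin(th)],
                                        [np.sin(th), np.cos(th)]]))
        else:
            blocks.append(np.array([[r]]))
        q = spec.variance_weight * ((1.0 - r * r) if r < 1 else 1e-4)
        wblocks.append(q * np.eye(blocks[-1].shape[0]))
        if spec.behavior_coupled:
            coupled_cols.extend(range(col, col + blocks[-1].shape[0]))
        col += blocks[-1].shape[0]
    n_x = col
    if n_x > 25:
        raise ValueError(f"implied state dimension {n_x} exceeds 25")
    from scipy.linalg import block_diag
    A = block_diag(*blocks)
    W = block_diag(*wblocks)

    # stationary covariance (diagonal by construction of the blocks)
    P = _stationary_cov(A, W)
    x0 = np.zeros(n_x)

    # point-process coefficients: baseline log-rates + bounded state loading
    base_rates = rng.uniform(*rate_range, size=n_c)
    alpha = np.zeros((n_c, n_x + 1))
    alpha[:, 0] = np.log(base_rates)
    dirs = rng.standard_normal((n_c, n_x))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    # scale by the stationary sd so the loading norm is in units of latent sd
    scale = rng.uniform(*alpha_norm_range, size=n_c)
    sd = np.sqrt(np.diag(P))
    alpha[:, 1:] = dirs * (scale / np.linalg.norm(dirs * sd, axis=1))[:, None]

    # LFP observation matrix and noise
    C = np.zeros((n_y, n_x + 1))
    C[:, 0] = rng.standard_normal(n_y)
    C[:, 1:] = rng.standard_normal((n_y, n_x))
    sig_var = np.einsum("ij,jk,ik->i", C[:, 1:], P, C[:, 1:])
    R = np.diag(np.maximum(sig_var / lfp_snr, 1e-6))

    # behavior readout touches only coupled modal coordinates
    readout = np.zeros((n_b, n_x + 1))
    if coupled_cols:
        readout[:, 1 + np.array(coupled_cols)] = rng.standard_normal(
            (n_b, len(coupled_cols)))
    beh_var = np.einsum("ij,jk,ik->i", readout[:, 1:], P, readout[:, 1:])
    noise_sd = np.sqrt(np.maximum(beh_var / behavior_snr, 1e-12))

    params = ModelParams(A=A, W=W, x0=x0, Lambda0=P, C=C, R=R, alpha=alpha,
                         timebase=timebase, scale_tag="multiscale")
    return GroundTruth(params=params, readout=readout,
                       mode_specs=list(mode_specs), seed=seed,
                       behavior_noise_sd=noise_sd,
                       coupled_columns=tuple(coupled_cols))


def _stationary_cov(A: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Solve P = A P A' + W; falls back to W when A has unit-modulus modes."""
    n = A.shape[0]
    M = np.eye(n * n) - np.kron(A, A)
    try:
        p = np.linalg.solve(M, W.ravel())
        P = p.reshape(n, n)
    except np.linalg.LinAlgError:
        P = W.copy()
    if not np.all(np.isfinite(P)) or np.any(np.diag(P) <= 0):
        P = np.maximum(W, 1e-6 * np.eye(n))
    return 0.5 * (P + P.T)


def simulate(gt: GroundTruth, T: int, seed: int, *,
             return_latents: bool = False):
    """Simulate a dataset of ``T`` fast steps from a ground-truth model.

    Spikes are Bernoulli(min(lambda_c * dt, 1 - 1e-6)); LFP features are
    emitted at slow-scale steps; behavior is the readout plus Gaussian noise
    at every step.  Deterministic given (gt, T, seed).
    """
    import warnings

    p = gt.params
    tb = TimeBase(dt=p.timebase.dt, k=p.timebase.k, T=T)
    if T < 10 * tb.k:
        raise ValueError(f"T={T} too small (need >= {10 * tb.k})")
    rng = np.random.default_rng(seed)
    n_x, n_c, n_y = p.n_x, p.n_c, p.n_y
    n_b = gt.readout.shape[0]

    Lw = np.linalg.cholesky(p.W + 1e-12 * np.eye(n_x))
    L0 = np.linalg.cholesky(p.Lambda0 + 1e-12 * np.eye(n_x))
    x = np.empty((T, n_x))
    x[0] = p.x0 + L0 @ rng.standard_normal(n_x)
    noise = rng.standard_normal((T - 1, n_x)) @ Lw.T
    for t in range(1, T):
        x[t] = p.A @ x[t - 1] + noise[t - 1]

    ds_kwargs = {}
    if n_c:
        eta = p.alpha[:, 0] + x @ p.alpha[:, 1:].T
        if eta.max() > 700:
            bad = np.unravel_index(np.argmax(eta), eta.shape)[1]
            raise FloatingPointError(
                f"numeric overflow in exp for channel {bad}; "
                f"alpha row: {p.alpha[bad]}")
        prob = np.minimum(np.exp(eta) * tb.dt, PROB_CLIP)
        spikes = (rng.uniform(size=prob.shape) < prob).astype(np.uint8)
        mean_rate = spikes.mean(axis=0)
        if np.any(mean_rate > 0.5):
            warnings.warn(
                "channel mean rate above 0.5 spikes/step: point-process "
                "regime violated", RuntimeWarning)
    else:
        spikes = np.zeros((T, 0), dtype=np.uint8)
    if n_y:
        steps = tb.lfp_steps
        Lr = np.linalg.cholesky(p.R + 1e-12 * np.eye(n_y))
        lfp = (p.C[:, 0] + x[steps] @ p.C[:, 1:].T
               + rng.standard_normal((steps.size, n_y)) @ Lr.T)
        bands = [DEFAULT_BANDS[i % len(DEFAULT_BANDS)].name for i in range(n_y)]
        ds_kwargs["band_labels"] = bands
    else:
        lfp = np.zeros((tb.n_lfp_steps, 0))
    behavior = (gt.readout[:, 0] + x @ gt.readout[:, 1:].T
                + rng.standard_normal((T, n_b)) * gt.behavior_noise_sd)

    ds = NeuralDataset(spikes=spikes, lfp=lfp, behavior=behavior,
                       timebase=tb, **ds_kwargs)
    return (ds, x) if return_latents else ds


def default_ground_truth(n_c: int = 20, n_y: int = 30, n_b: int = 3,
                         seed: int = 0, *,
                         timebase: TimeBase | None = None) -> GroundTruth:
    """Ground truth at the default study conditions (desk scale)."""
    tb = timebase or TimeBase(dt=0.01, k=5, T=0)
    return build_model(default_mode_specs(), n_c=n_c, n_y=n_y, n_b=n_b,
                       timebase=tb, seed=seed)


def simulate_behavior_representation(behavior: np.ndarray, n_c: int, n_y: int,
                                     noise_scale: float, seed: int, *,
                                     timebase: TimeBase | None = None,
                                     n_nuisance: int = 2,
                                     nuisance_ar: float = 0.98,
                                     lfp_mixing: np.ndarray | None = None,
                                     base_rate_hz: float = 15.0,
                                     ) -> NeuralDataset:
    """Surrogate in which neural activity directly represents behavior.

    Spike rates are log-linear and LFP features linear in (behavior +
    independent nuisance AR(1) processes).  Modal analysis on this surrogate
    should recover behavior's own modes — the control for the claim that
    neural modes are not mere behavior representations.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be nonnegative")
    Z = np.asarray(behavior, dtype=float)
    if not np.isfinite(Z).all():
        raise ValueError("behavior must be finite")
    T, n_b = Z.shape
    tb = timebase or TimeBase(dt=0.01, k=5, T=T)
    rng = np.random.default_rng(seed)

    nuis = np.zeros((T, n_nuisance))
    if n_nuisance:
        innov_sd = np.sqrt(1.0 - nuisance_ar ** 2)
        e = rng.standard_normal((T, n_nuisance)) * innov_sd
        nuis[0] = rng.standard_normal(n_nuisance)
        for t in range(1, T):
            nuis[t] = nuisance_ar * nuis[t - 1] + e[t]
    drivers = np.hstack([Z, nuis])
    zs = drivers.std(axis=0)
    zs[zs == 0] = 1.0
    drivers_std = (drivers - drivers.mean(axis=0)) / zs

    # spikes: log-linear in the drivers
    Ms = rng.standard_normal((n_c, drivers.shape[1]))
    Ms /= np.maximum(np.linalg.norm(Ms, axis=1, keepdims=True), 1e-12)
    eta = np.log(base_rate_hz) + 0.4 * drivers_std @ Ms.T
    prob = np.minimum(np.exp(eta) * tb.dt, PROB_CLIP)
    spikes = (rng.uniform(size=prob.shape) < prob).astype(np.uint8)

    # LFP: linear in the (raw) drivers, sampled at the slow steps
    if lfp_mixing is None:
        Ml = rng.standard_normal((n_y, drivers.shape[1]))
    else:
        Ml = np.asarray(lfp_mixing, dtype=float)
    steps = tb.lfp_steps
    lfp = drivers[steps] @ Ml.T
    if noise_scale > 0:
        lfp = lfp + noise_scale * lfp.std(axis=0) * rng.standard_normal(lfp.shape)

    bands = [DEFAULT_BANDS[i % len(DEFAULT_BANDS)].name for i in range(n_y)]
    return NeuralDataset(spikes=spikes, lfp=lfp, behavior=Z, timebase=tb,
                         band_labels=bands if n_y else [])


def shuffle_control(ds: NeuralDataset, seed: int) -> NeuralDataset:
    """Independently permute each neural channel's time series (behavior
    untouched).  Destroys temporal structure while preserving per-channel
    marginals."""
    rng = np.random.default_rng(seed)
    spikes = ds.spikes.copy()
    for c in range(ds.n_c):
        spikes[:, c] = spikes[rng.permutation(ds.T), c]
    lfp = ds.lfp.copy()
    for j in range(ds.n_y):
        lfp[:, j] = lfp[rng.permutation(lfp.shape[0]), j]
    return NeuralDataset(spikes=spikes, lfp=lfp, behavior=ds.behavior.copy(),
                         timebase=ds.timebase,
                         spike_channel_ids=list(ds.spike_channel_ids),
                         lfp_channel_ids=list(ds.lfp_channel_ids),
                         band_labels=list(ds.band_labels),
                         behavior_labels=list(ds.behavior_labels))


def save_ground_truth_json(gt: GroundTruth, path) -> None:
    """Sidecar JSON with planted eigenvalues and the behavior readout, for
    test harnesses that need ground truth without the full model file."""
    dt = gt.params.timebase.dt
    eigs = [gt_spec.eigenvalue(dt) for gt_spec in gt.mode_specs]
    payload = {
        "seed": gt.seed,
        "dt": dt,
        "eigenvalues": [[e.real, e.imag] for e in eigs],
        "mode_specs": [
            {"decay": s.decay, "frequency": s.frequency,
             "behavior_coupled": s.behavior_coupled,
             "variance_weight": s.variance_weight}
            for s in gt.mode_specs
        ],
        "readout": gt.readout.tolist(),
        "coupled_columns": list(gt.coupled_columns),
    }
    with open(path, "w") as f:
        json.dump(payload, f, indent=1)
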