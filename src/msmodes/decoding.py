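"""Behavior readout from latent states and one-step-ahead neural metrics.

The dynamical model is learned unsupervised from neural activity; behavior
enters only afterwards, through an ordinary-least-squares projection
``z_t ~= L [1; x_{t|t}]`` fitted on training-fold filtered (causal) states.
Prediction accuracy is Pearson's correlation coefficient (CC) per behavior
dimension.  One-step-ahead prediction of spikes is scored by prediction
power PP = 2*AUC - 1 of the predicted spike probabilities; one-step-ahead
prediction of LFP features by Pearson CC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .ssm import FilterResult, ModelParams

__all__ = [
    "BehaviorProjection",
    "PredictionMetrics",
    "fit_projection",
    "predict_behavior",
    "behavior_cc",
    "one_step_spike_pp",
    "one_step_lfp_cc",
    "permutation_chance",
    "time_shift_control",
    "auc_rank",
]


@dataclass
class BehaviorProjection:
    """OLS readout L (n_b x (n_x+1)); the first column is the bias."""

    L: np.ndarray

    @property
    def bias(self) -> np.ndarray:
        return self.L[:, 0]

    @property
    def weights(self) -> np.ndarray:
        return self.L[:, 1:]


@dataclass
class PredictionMetrics:
    behavior_cc: np.ndarray      # per behavior dimension (nan = undefined)
    pp_spike: np.ndarray         # per spike channel
    cc_lfp: np.ndarray           # per LFP feature

    @property
    def mean_behavior_cc(self) -> float:
        return _nanmean(self.behavior_cc)

    @property
    def mean_pp_spike(self) -> float:
        return _nanmean(self.pp_spike)

    @property
    def mean_cc_lfp(self) -> float:
        return _nanmean(self.cc_lfp)


def _nanmean(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    good = np.isfinite(x)
    return float(x[good].mean()) if good.any() else np.nan


def fit_projection(states: np.ndarray, Z: np.ndarray) -> BehaviorProjection:
    """L = Z X~' (X~ X~')^-1 with X~ rows [1; x_{t|t}]; training folds only.

    Falls back to a ridge solve (1e-8 regularizer on the state block) when
    the Gram matrix is rank-deficient (e.g., constant states)."""
    X = np.column_stack([np.ones(len(states)), np.asarray(states, dtype=float)])
    Z = np.atleast_2d(np.asarray(Z, dtype=float).T).T
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more training steps than n_x + 1")
    G = X.T @ X
    B = X.T @ Z
    try:
        cond = np.linalg.cond(G)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError
        L = np.linalg.solve(G, B).T
    except np.linalg.LinAlgError:
        import logging
        logging.getLogger(__name__).warning(
            "rank-deficient projection fit; using ridge fallback (1e-8)")
        reg = 1e-8 * np.eye(G.shape[0])
        reg[0, 0] = 0.0
        L = np.linalg.solve(G + reg * max(np.trace(G), 1.0), B).T
    return BehaviorProjection(L=L)


def predict_behavior(states: np.ndarray, proj: BehaviorProjection) -> np.ndarray:
    """z_hat_t = L [1; x_{t|t}]."""
    states = np.asarray(states, dtype=float)
    if states.shape[1] != proj.L.shape[1] - 1:
        raise ValueError("state dimension does not match the projection")
    return proj.bias + states @ proj.weights.T


def behavior_cc(Z: np.ndarray, Zhat: np.ndarray) -> tuple[np.ndarray, float]:
    """Pearson CC per behavior dimension and the unweighted mean across
    dimensions; a zero-variance truth dimension is reported nan and excluded
    from the mean."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float).T).T
    Zhat = np.atleast_2d(np.asarray(Zhat, dtype=float).T).T
    if Z.shape != Zhat.shape:
        raise ValueError("shape mismatch between truth and prediction")
    cc = np.full(Z.shape[1], np.nan)
    for j in range(Z.shape[1]):
        z, zh = Z[:, j], Zhat[:, j]
        # zero-variance guard with a relative tolerance (a numerically
        # constant series has std ~ eps * |mean|, not exactly 0)
        if z.std() <= 1e-12 * max(1.0, np.abs(z).max()) \
                or zh.std() <= 1e-12 * max(1.0, np.abs(zh).max()):
            continue
        cc[j] = np.corrcoef(z, zh)[0, 1]
    return cc, _nanmean(cc)


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney) formulation with midrank ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def one_step_spike_pp(N: np.ndarray, params: ModelParams, fr: FilterResult,
                      ) -> np.ndarray:
    """PP = 2*AUC - 1 of the one-step-ahead spike probabilities
    lambda_c([1; x_{t|t-1}]) * dt against the observed events, per channel.
    Channels with no spikes or all spikes are reported nan."""
    N = np.asarray(N)
    dt = params.timebase.dt
    eta = params.alpha[:, 0] + fr.xp @ params.alpha[:, 1:].T
    prob = np.exp(np.minimum(eta, 50)) * dt
    pp = np.full(N.shape[1], np.nan)
    for c in range(N.shape[1]):
        auc = auc_rank(prob[:, c], N[:, c])
        if np.isfinite(auc):
            pp[c] = 2.0 * auc - 1.0
    return pp


def one_step_lfp_cc(Y: np.ndarray, params: ModelParams, fr: FilterResult,
                    ) -> np.ndarray:
    """Pearson CC between each LFP feature and its one-step-ahead prediction
    C [1; x_{t|t-1}] at slow-scale steps."""
    Y = np.asarray(Y, dtype=float)
    k = params.timebase.k
    steps = k * np.arange(1, Y.shape[0] + 1) - 1
    if steps.size and steps[-1] >= fr.xp.shape[0]:
        raise ValueError("filter result shorter than the LFP stream")
    yhat = params.C[:, 0] + fr.xp[steps] @ params.C[:, 1:].T
    cc, _ = behavior_cc(Y, yhat)
    return cc


def permutation_chance(train_states: np.ndarray, train_Z: np.ndarray,
                       test_states: np.ndarray, test_Z: np.ndarray,
                       n_perm: int = 1000, seed: int = 0,
                       block: int | None = None) -> dict:
    """Empirical chance level of the behavior CC under label permutation.

    For each permutation the behavior series is permuted in time
    (consistently re-indexed in train and test), the readout refitted on the
    permuted training labels, and the test CC recorded.  ``block`` switches
    to block permutation for autocorrelation-preserving nulls.  The
    theoretical chance level of the CC in linear regression is 0.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    train_Z = np.atleast_2d(np.asarray(train_Z, dtype=float).T).T
    test_Z = np.atleast_2d(np.asarray(test_Z, dtype=float).T).T
    ccs = np.empty(n_perm)
    for i in range(n_perm):
        p_tr = _permutation(train_Z.shape[0], rng, block)
        p_te = _permutation(test_Z.shape[0], rng, block)
        proj = fit_projection(train_states, train_Z[p_tr])
        zhat = predict_behavior(test_states, proj)
        _, ccs[i] = behavior_cc(test_Z[p_te], zhat)
    return {"cc": ccs, "mean": float(np.nanmean(ccs)),
            "sd": float(np.nanstd(ccs, ddof=1)),
            "sem": float(np.nanstd(ccs, ddof=1) / np.sqrt(n_perm))}


def _permutation(n: int, rng, block: int | None) -> np.ndarray:
    if block is None:
        return rng.permutation(n)
    n_blocks = int(np.ceil(n / block))
    order = rng.permutation(n_blocks)
    idx = np.concatenate([np.arange(b * block, min((b + 1) * block, n))
                          for b in order])
    return idx


def time_shift_control(prediction: np.ndarray, Z: np.ndarray,
                       shifts: list[int]) -> dict[int, float]:
    """CC between behavior and the circularly time-shifted prediction of the
    predictive mode, for each step offset."""
    prediction = np.asarray(prediction, dtype=float)
    T = prediction.shape[0]
    for s in shifts:
        if abs(s) > T // 4:
            raise ValueError(f"shift {s} exceeds T/4={T // 4}")
    out = {}
    for s in shifts:
        _, out[s] = behavior_cc(Z, np.roll(prediction, s, axis=0))
    return out
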