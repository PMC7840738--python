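"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's recursive filter/smoother code
paths: the Gaussian oracle solves the full joint posterior over the whole
state trajectory in information form; the point-process oracle maximizes
the exact one-step posterior on a grid refined by scalar Newton steps.
"""

import numpy as np


def batch_gaussian_posterior(A, W, x0, L0, C, R, Y, obs_steps, T):
    """Exact joint posterior over x_{0:T-1} for a linear-Gaussian model with
    observations y_t = C[:,0] + C[:,1:] x_t + r_t at the given steps.

    Returns (mean trajectory (T, n_x), marginal covariances (T, n_x, n_x),
    lag-one cross-covariances cov(x_{t+1}, x_t)).
    """
    n_x = A.shape[0]
    Wi = np.linalg.inv(W)
    L0i = np.linalg.inv(L0)
    J = np.zeros((T * n_x, T * n_x))
    h = np.zeros(T * n_x)

    def blk(t):
        return slice(t * n_x, (t + 1) * n_x)

    J[blk(0), blk(0)] += L0i
    h[blk(0)] += L0i @ x0
    for t in range(T - 1):
        J[blk(t), blk(t)] += A.T @ Wi @ A
        J[blk(t + 1), blk(t + 1)] += Wi
        J[blk(t), blk(t + 1)] += -A.T @ Wi
        J[blk(t + 1), blk(t)] += -Wi @ A
    if C.shape[0]:
        c0, Cs = C[:, 0], C[:, 1:]
        Ri = np.linalg.inv(R)
        for i, t in enumerate(obs_steps):
            J[blk(t), blk(t)] += Cs.T @ Ri @ Cs
            h[blk(t)] += Cs.T @ Ri @ (Y[i] - c0)
    Sigma = np.linalg.inv(J)
    mean = (Sigma @ h).reshape(T, n_x)
    margs = np.array([Sigma[blk(t), blk(t)] for t in range(T)])
    lags = np.array([Sigma[blk(t + 1), blk(t)] for t in range(T - 1)])
    return mean, margs, lags


def batch_filtered_mean(A, W, x0, L0, C, R, Y, obs_steps, t):
    """Filtered estimate x_{t|t} from a causal batch solve (data up to t)."""
    obs = [s for s in obs_steps if s <= t]
    Yc = Y[: len(obs)]
    mean, _, _ = batch_gaussian_posterior(A, W, x0, L0, C, R, Yc, obs, t + 1)
    return mean[t]


def pp_single_step_map(x_prior, P_prior, alpha, n_obs, dt, *,
                       grid_half_width=5.0, grid_points=20001):
    """1-D MAP of Gaussian prior x point-process likelihood for one channel,
    by dense grid search refined with scalar Newton iterations."""
    a0, a1 = alpha
    sd = np.sqrt(P_prior)
    xs = np.linspace(x_prior - grid_half_width * sd,
                     x_prior + grid_half_width * sd, grid_points)

    def logpost(x):
        lam = np.exp(a0 + a1 * x)
        return (-0.5 * (x - x_prior) ** 2 / P_prior
                + n_obs * np.log(lam * dt) - lam * dt)

    x = xs[np.argmax(logpost(xs))]
    for _ in range(60):
        lam = np.exp(a0 + a1 * x)
        g = -(x - x_prior) / P_prior + a1 * (n_obs - lam * dt)
        H = -1.0 / P_prior - a1 ** 2 * lam * dt
        step = g / H
        x = x - step
        if abs(step) < 1e-14:
            break
    return x


def auc_pair_counting(scores, labels):
    """AUC by brute force over all (event, non-event) pairs; ties count 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))
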