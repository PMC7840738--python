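"""EM algorithms for the three dynamical model classes.

* ``em_lgssm`` — linear Gaussian state-space model for LFP features alone
  (exact E-step, exact monotone log-likelihood).
* ``em_ppssm`` — point-process state-space model for spikes alone
  (Gaussian-approximate E-step; closed-form M-step for A, W, x0, Lambda0;
  Newton ascent on the expected point-process log-likelihood for alpha).
* ``em_multiscale`` — joint model for combined spike-LFP activity, sharing
  one latent state across the two time-scales.
* ``em_constrained_A`` — the multiscale EM with the transition matrix held
  fixed, used by the mode-perturbation experiment.

All variants run the latent state at the fast (10 ms) step; LFP features
enter only at slow-scale steps.  The model is learned from neural activity
alone — behavior never enters the likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datasets import TimeBase
from .ssm import (FilterError, FilterResult, ModelParams, SmootherResult,
                  _run_filter, _run_smoother)

__all__ = ["EMOptions", "EMTrace", "em_lgssm", "em_ppssm", "em_multiscale",
           "em_constrained_A"]

_JIT = 1e-9


@dataclass
class EMOptions:
    """Configuration of an EM fit.

    ``tol`` is the relative change in (approximate) data log-likelihood that
    stops the iteration; ``init`` picks data-driven (PCA + lag-one
    regression) or random initialization; ``A_fixed`` freezes the transition
    matrix for the perturbation experiment.
    """

    n_x: int = 5
    max_iters: int = 500
    tol: float = 1e-6
    init: str = "data_driven"
    seed: int = 0
    A_fixed: np.ndarray | None = None
    pp_iters: int = 1
    newton_iters: int = 10

    def __post_init__(self) -> None:
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not (1 <= self.n_x <= 25):
            raise ValueError("n_x must be in [1, 25]")
        if self.init not in ("data_driven", "random"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class EMTrace:
    loglik: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

def em_lgssm(Y: np.ndarray, opts: EMOptions, timebase: TimeBase,
             ) -> tuple[ModelParams, EMTrace]:
    """Fit the LFP-only linear Gaussian model.  The log-likelihood is exact
    and non-decreasing across iterations."""
    Y = np.asarray(Y, dtype=float)
    if Y.shape[0] < 10 * opts.n_x:
        raise ValueError(f"need at least {10 * opts.n_x} LFP steps for n_x={opts.n_x}")
    return _em(None, Y, opts, timebase, "lfp")


def em_ppssm(N: np.ndarray, opts: EMOptions, timebase: TimeBase,
             ) -> tuple[ModelParams, EMTrace]:
    """Fit the spike-only point-process model (approximate E-step)."""
    N = np.asarray(N, dtype=float)
    _check_spikes(N, opts.n_x)
    return _em(N, None, opts, timebase, "spike")


def em_multiscale(N: np.ndarray, Y: np.ndarray, opts: EMOptions,
                  timebase: TimeBase) -> tuple[ModelParams, EMTrace]:
    """Fit the multiscale model to combined spike-LFP activity.  Degenerates
    to ``em_ppssm`` when ``Y`` is empty and to ``em_lgssm`` when ``N`` is
    empty."""
    N = None if N is None or np.size(N) == 0 else np.asarray(N, dtype=float)
    Y = None if Y is None or np.size(Y) == 0 else np.asarray(Y, dtype=float)
    if N is None and Y is None:
        raise ValueError("both streams empty")
    if N is None:
        return em_lgssm(Y, opts, timebase)
    if Y is None:
        return em_ppssm(N, opts, timebase)
    _check_spikes(N, opts.n_x)
    return _em(N, Y, opts, timebase, "multiscale")


def em_constrained_A(N: np.ndarray | None, Y: np.ndarray | None,
                     A_fixed: np.ndarray, opts: EMOptions,
                     timebase: TimeBase) -> tuple[ModelParams, EMTrace]:
    """EM with the state transition matrix frozen at ``A_fixed``; only the
    other parameters are updated in the M-step."""
    A_fixed = np.asarray(A_fixed, dtype=float)
    if A_fixed.shape != (opts.n_x, opts.n_x):
        raise ValueError("A_fixed must be n_x x n_x")
    opts2 = EMOptions(**{**opts.__dict__, "A_fixed": A_fixed})
    return em_multiscale(N, Y, opts2, timebase)


def _check_spikes(N: np.ndarray, n_x: int) -> None:
    if N.shape[1] and N.sum() < 50 * n_x:
        raise ValueError(f"too few spikes ({int(N.sum())}) for n_x={n_x}")
    dead = np.flatnonzero(N.sum(axis=0) == 0)
    if dead.size:
        raise ValueError(f"degenerate channel (no spikes): {dead.tolist()}")


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------

def _em(N, Y, opts: EMOptions, timebase: TimeBase, scale_tag: str,
        ) -> tuple[ModelParams, EMTrace]:
    T = N.shape[0] if N is not None else Y.shape[0] * timebase.k
    tb = TimeBase(dt=timebase.dt, k=timebase.k, T=T)
    params = _initialize(N, Y, opts, tb, scale_tag)
    trace = EMTrace()
    prev_ll = -np.inf
    prev_params = params
    exact = scale_tag == "lfp"
    for it in range(opts.max_iters):
        try:
            fr = _run_filter(params, N, Y, opts.pp_iters)
        except FilterError:
            if it == 0:
                raise
            warnings.warn(
                f"E-step diverged at iteration {it}; reverting to the last "
                "stable parameters", RuntimeWarning)
            return prev_params, trace
        ll = fr.total_loglik
        trace.loglik.append(ll)
        trace.iterations = it + 1
        if it > 0:
            rel = (ll - prev_ll) / max(abs(prev_ll), 1e-12)
            if exact and rel < -1e-9:
                raise RuntimeError(
                    f"log-likelihood decreased in exact EM at iteration {it}: "
                    f"{prev_ll} -> {ll}")
            # approximate E-steps can transiently lower the innovation-form
            # log-likelihood right after initialization; treat a decrease as
            # divergence only past a short burn-in
            if not exact and rel < -1e-4 and it > 10:
                warnings.warn(
                    f"approximate EM log-likelihood decreased by {-rel:.2e} "
                    f"(relative) at iteration {it}; stopping", RuntimeWarning)
                break
            if abs(rel) < opts.tol:
                trace.converged = True
                break
        prev_ll = ll
        sm = _run_smoother(fr, params)
        prev_params = params
        params = _m_step(params, N, Y, fr, sm, opts, tb)
    return params, trace


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def _initialize(N, Y, opts: EMOptions, tb: TimeBase, scale_tag: str,
                ) -> ModelParams:
    n_x = opts.n_x
    rng = np.random.default_rng(opts.seed)
    if opts.init == "random":
        A = _random_stable_A(n_x, rng)
        x_hat = None
    else:
        x_hat = _data_driven_states(N, Y, n_x, tb, rng)
        A = _lag_regression(x_hat)
    if opts.A_fixed is not None:
        A = np.array(opts.A_fixed, dtype=float)
    if x_hat is not None:
        resid = x_hat[1:] - x_hat[:-1] @ A.T
        W = np.cov(resid.T).reshape(n_x, n_x) + 1e-3 * np.eye(n_x)
    else:
        W = 0.1 * np.eye(n_x)
    x0 = np.zeros(n_x)
    L0 = np.eye(n_x)

    C = np.zeros((0, n_x + 1))
    R = np.zeros((0, 0))
    if Y is not None and Y.shape[1]:
        n_y = Y.shape[1]
        if x_hat is not None:
            steps = tb.k * np.arange(1, Y.shape[0] + 1) - 1
            Xa = np.column_stack([np.ones(steps.size), x_hat[steps]])
            C, *_ = np.linalg.lstsq(Xa, Y, rcond=None)
            C = C.T
            res = Y - Xa @ C.T
            R = np.diag(np.maximum(res.var(axis=0), 1e-6))
        else:
            C = np.column_stack([Y.mean(axis=0),
                                 0.1 * rng.standard_normal((n_y, n_x))])
            R = np.diag(np.maximum(Y.var(axis=0), 1e-6))

    alpha = np.zeros((0, n_x + 1))
    if N is not None and N.shape[1]:
        n_c = N.shape[1]
        alpha = np.zeros((n_c, n_x + 1))
        alpha[:, 0] = np.log(np.maximum(N.mean(axis=0), 1e-8) / tb.dt)
        if x_hat is not None:
            # a couple of Newton steps of the point-process GLM on the
            # observed proxy states (no posterior covariance at init)
            Pzero = np.zeros((x_hat.shape[0], n_x, n_x))
            for c in range(n_c):
                alpha[c] = _newton_alpha(alpha[c], N[:, c], x_hat, Pzero,
                                         tb.dt, max_iters=3)
    return ModelParams(A=A, W=W, x0=x0, Lambda0=L0, C=C, R=R, alpha=alpha,
                       timebase=tb, scale_tag=scale_tag)


def _random_stable_A(n_x: int, rng) -> np.ndarray:
    """Block-diagonal rotations with eigenvalue magnitudes ~ U(0.90, 0.995),
    conjugated by a random orthogonal matrix."""
    from scipy.linalg import block_diag
    from scipy.stats import ortho_group
    blocks = []
    left = n_x
    while left >= 2:
        r = rng.uniform(0.90, 0.995)
        th = rng.uniform(0.0, 0.2)
        blocks.append(r * np.array([[np.cos(th), -np.sin(th)],
                                    [np.sin(th), np.cos(th)]]))
        left -= 2
    if left:
        blocks.append(np.array([[rng.uniform(0.90, 0.995)]]))
    A = block_diag(*blocks)
    if n_x > 1:
        Q = ortho_group.rvs(n_x, random_state=rng)
        A = Q @ A @ Q.T
    return A


def _data_driven_states(N, Y, n_x: int, tb: TimeBase, rng) -> np.ndarray:
    """Proxy latent series: PCA of [Gaussian-smoothed spike counts || LFP
    features held at the fast step], standardized, top n_x components."""
    from scipy.ndimage import gaussian_filter1d

    feats = []
    if N is not None and N.shape[1]:
        feats.append(gaussian_filter1d(N, sigma=5.0, axis=0))
    if Y is not None and Y.shape[1]:
        up = np.repeat(Y, tb.k, axis=0)[:tb.T]
        if up.shape[0] < tb.T:
            up = np.vstack([up, np.repeat(up[-1:], tb.T - up.shape[0], axis=0)])
        feats.append(up)
    F = np.hstack(feats)
    F = F - F.mean(axis=0)
    sd = F.std(axis=0)
    sd[sd == 0] = 1.0
    F = F / sd
    # top principal components via SVD (deterministic)
    _, s, Vt = np.linalg.svd(F, full_matrices=False)
    comps = min(n_x, Vt.shape[0])
    X = F @ Vt[:comps].T
    X = X / np.maximum(X.std(axis=0), 1e-12)
    if comps < n_x:  # degenerate feature rank: pad with small noise
        X = np.column_stack([X, 1e-3 * rng.standard_normal((X.shape[0],
                                                            n_x - comps))])
    return X


def _lag_regression(x: np.ndarray) -> np.ndarray:
    A, *_ = np.linalg.lstsq(x[:-1], x[1:], rcond=None)
    A = A.T
    # shrink toward stability if the spectral radius is >= 1
    rho = np.max(np.abs(np.linalg.eigvals(A)))
    if rho >= 0.999:
        A = A * (0.999 / rho)
    return A


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------

def _m_step(params: ModelParams, N, Y, fr: FilterResult, sm: SmootherResult,
            opts: EMOptions, tb: TimeBase) -> ModelParams:
    xs, Ps, Plag = sm.xs, sm.Ps, sm.Plag
    T, n_x = xs.shape
    eye = np.eye(n_x)

    S00 = (Ps[:-1].sum(axis=0) + xs[:-1].T @ xs[:-1])
    S10 = (Plag.sum(axis=0) + xs[1:].T @ xs[:-1])
    S11 = (Ps[1:].sum(axis=0) + xs[1:].T @ xs[1:])
    if opts.A_fixed is not None:
        A = np.array(opts.A_fixed, dtype=float)
    else:
        try:
            A = np.linalg.solve(S00.T, S10.T).T
        except np.linalg.LinAlgError as e:
            raise RuntimeError(
                "rank-deficient M-step solve for A; try a smaller n_x") from e
    W = (S11 - A @ S10.T - S10 @ A.T + A @ S00 @ A.T) / (T - 1)
    W = 0.5 * (W + W.T) + _JIT * eye
    x0 = xs[0].copy()
    L0 = 0.5 * (Ps[0] + Ps[0].T) + _JIT * eye

    C, R = params.C, params.R
    if Y is not None and Y.shape[1]:
        steps = tb.k * np.arange(1, Y.shape[0] + 1) - 1
        m = xs[steps]
        P = Ps[steps]
        nf = steps.size
        Mxx = np.zeros((n_x + 1, n_x + 1))
        Mxx[0, 0] = nf
        Mxx[0, 1:] = m.sum(axis=0)
        Mxx[1:, 0] = Mxx[0, 1:]
        Mxx[1:, 1:] = P.sum(axis=0) + m.T @ m
        Syx = np.column_stack([Y.sum(axis=0), Y.T @ m])
        try:
            C = np.linalg.solve(Mxx.T, Syx.T).T
        except np.linalg.LinAlgError as e:
            raise RuntimeError(
                "rank-deficient M-step solve for C; try a smaller n_x") from e
        Syy = Y.T @ Y
        R = (Syy - C @ Syx.T - Syx @ C.T + C @ Mxx @ C.T) / nf
        R = 0.5 * (R + R.T) + _JIT * np.eye(R.shape[0])

    alpha = params.alpha
    if N is not None and N.shape[1]:
        alpha = alpha.copy()
        for c in range(alpha.shape[0]):
            alpha[c] = _newton_alpha(alpha[c], N[:, c], xs, Ps, tb.dt,
                                     max_iters=opts.newton_iters)

    return ModelParams(A=A, W=W, x0=x0, Lambda0=L0, C=C, R=R, alpha=alpha,
                       timebase=tb, scale_tag=params.scale_tag)


def _newton_alpha(alpha_c: np.ndarray, n: np.ndarray, m: np.ndarray,
                  P: np.ndarray, dt: float, *, max_iters: int = 10,
                  tol: float = 1e-8) -> np.ndarray:
    """Newton ascent on the expected point-process log-likelihood of one
    channel, with the expectation over the Gaussian posterior moments:

        Q(a) = sum_t [ n_t * a'u_t - dt * exp(a0 + a_s'm_t + a_s'P_t a_s/2) ]

    The objective is concave; diverging steps are halved (up to 50 times).
    """
    a = alpha_c.copy()
    n_x = m.shape[1]
    sum_nu = np.concatenate([[n.sum()], n @ m])
    has_cov = np.any(P)

    def _parts(a_vec):
        a_s = a_vec[1:]
        if has_cov:
            Pa = np.einsum("tij,j->ti", P, a_s)
            quad = Pa @ a_s
        else:
            Pa = np.zeros_like(m)
            quad = np.zeros(m.shape[0])
        expo = a_vec[0] + m @ a_s + 0.5 * quad
        if expo.max() > 50:  # rate out of the model regime
            return None, None, None
        e = np.exp(expo)
        return e, Pa, quad

    e, Pa, _ = _parts(a)
    if e is None:
        raise RuntimeError("Newton ascent diverged: rate overflow at start")
    q_prev = sum_nu @ a - dt * e.sum()
    for _ in range(max_iters):
        v = np.column_stack([np.ones(m.shape[0]), m + Pa])
        grad = sum_nu - dt * (e @ v)
        H = -dt * (v * e[:, None]).T @ v
        if has_cov:
            H[1:, 1:] -= dt * np.einsum("t,tij->ij", e, P)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad / (np.abs(np.diag(H)).max() + 1e-12)
        # trust region: near-separable channels can request huge steps whose
        # expected objective looks fine but whose filtered rates explode
        norm = np.linalg.norm(step)
        if norm > 5.0:
            step = step * (5.0 / norm)
        # step-halving line search on Q
        ok = False
        for _h in range(50):
            a_new = a - step
            e_new, Pa_new, _ = _parts(a_new)
            if e_new is not None:
                q_new = sum_nu @ a_new - dt * e_new.sum()
                if q_new >= q_prev - 1e-10 * max(abs(q_prev), 1.0):
                    ok = True
                    break
            step = 0.5 * step
        if not ok:
            raise RuntimeError(
                "Newton ascent for alpha failed after 50 step halvings")
        delta = np.linalg.norm(a_new - a)
        a, e, Pa, q_prev = a_new, e_new, Pa_new, q_new
        if delta < tol:
            break
    return a
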