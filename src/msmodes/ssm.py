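"""Latent-state estimation for the three model classes.

A single latent linear-Gaussian state ``x_{t+1} = A x_t + w_t`` drives up to
two observation streams:

* binary spike events at every step, modeled as a point process with
  log-linear rates ``lambda_c = exp(alpha_c @ [1; x])``;
* Gaussian LFP band log-power features ``y = C @ [1; x] + r`` available only
  every ``k`` steps (the slow time-scale).

The Kalman filter (LFP only), point-process filter (spikes only) and
multiscale filter (both) all run through one compiled kernel; dropping a
stream reduces the multiscale filter to the corresponding single-scale
filter bitwise.  The point-process update is the standard one-Newton-step
Gaussian approximation around the predicted mean; an iterated variant
(<= ``pp_iters`` Newton steps) is available.

Smoothing is fixed-interval Rauch-Tung-Striebel on the Gaussian
approximations, returning the lag-one cross-covariances needed by the EM
M-step.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from numba import njit

from .datasets import TimeBase

__all__ = [
    "ModelParams",
    "FilterResult",
    "SmootherResult",
    "FilterError",
    "kalman_filter",
    "kalman_smoother",
    "point_process_filter",
    "point_process_smoother",
    "multiscale_filter",
    "multiscale_smoother",
    "save_params",
    "load_params",
]

RATE_DIVERGENCE = 10.0  # lambda*dt above this aborts filtering
JITTER = 1e-9


class FilterError(RuntimeError):
    pass


@dataclass
class ModelParams:
    """Full parameter set of a single-scale or multiscale model.

    ``C`` and ``alpha`` carry the constant (baseline) term in their first
    column; the latent state never includes the constant.  ``scale_tag`` is
    one of ``{"spike", "lfp", "multiscale"}`` and fixes which streams the
    model observes.
    """

    A: np.ndarray
    W: np.ndarray
    x0: np.ndarray
    Lambda0: np.ndarray
    C: np.ndarray        # (n_y, n_x+1); empty for spike-only models
    R: np.ndarray        # (n_y, n_y)
    alpha: np.ndarray    # (n_c, n_x+1); empty for LFP-only models
    timebase: TimeBase
    scale_tag: str = "multiscale"

    def __post_init__(self) -> None:
        self.A = np.ascontiguousarray(self.A, dtype=float)
        self.W = np.ascontiguousarray(self.W, dtype=float)
        self.x0 = np.ascontiguousarray(np.atleast_1d(self.x0), dtype=float)
        self.Lambda0 = np.ascontiguousarray(self.Lambda0, dtype=float)
        n_x = self.A.shape[0]
        self.C = np.ascontiguousarray(
            np.zeros((0, n_x + 1)) if self.C is None or np.size(self.C) == 0
            else self.C, dtype=float)
        self.R = np.ascontiguousarray(
            np.zeros((0, 0)) if self.R is None or np.size(self.R) == 0
            else self.R, dtype=float)
        self.alpha = np.ascontiguousarray(
            np.zeros((0, n_x + 1)) if self.alpha is None or np.size(self.alpha) == 0
            else self.alpha, dtype=float)
        self.validate()

    @property
    def n_x(self) -> int:
        return self.A.shape[0]

    @property
    def n_y(self) -> int:
        return self.C.shape[0]

    @property
    def n_c(self) -> int:
        return self.alpha.shape[0]

    def validate(self) -> None:
        n_x = self.n_x
        if self.A.shape != (n_x, n_x) or self.W.shape != (n_x, n_x):
            raise ValueError("A and W must be square with matching shape")
        if self.x0.shape != (n_x,) or self.Lambda0.shape != (n_x, n_x):
            raise ValueError("x0/Lambda0 dimension mismatch")
        if self.C.size and self.C.shape[1] != n_x + 1:
            raise ValueError("C must have n_x+1 columns (first = baseline)")
        if self.alpha.size and self.alpha.shape[1] != n_x + 1:
            raise ValueError("alpha must have n_x+1 columns (first = baseline)")
        if self.R.shape != (self.n_y, self.n_y):
            raise ValueError("R must be n_y x n_y")
        if not np.allclose(self.W, self.W.T, atol=1e-8):
            raise ValueError("W must be symmetric")
        if not np.allclose(self.R, self.R.T, atol=1e-8):
            raise ValueError("R must be symmetric")
        if self.scale_tag not in ("spike", "lfp", "multiscale"):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.scale_tag == "lfp" and self.n_c:
            raise ValueError("scale_tag='lfp' requires empty alpha")
        if self.scale_tag == "spike" and self.n_y:
            raise ValueError("scale_tag='spike' requires empty C/R")


@dataclass
class FilterResult:
    """Causal filter output: filtered/predicted means and covariances.

    ``loglik`` holds per-step log-likelihood contributions: the Gaussian
    (innovation-form) part is exact; the point-process part is the model
    likelihood evaluated at the predicted state estimate.
    """

    xf: np.ndarray   # (T, n_x) filtered means x_{t|t}
    Pf: np.ndarray   # (T, n_x, n_x)
    xp: np.ndarray   # (T, n_x) one-step-predicted means x_{t|t-1}
    Pp: np.ndarray   # (T, n_x, n_x)
    loglik: np.ndarray  # (T,)

    @property
    def total_loglik(self) -> float:
        return float(self.loglik.sum())


@dataclass
class SmootherResult:
    xs: np.ndarray    # (T, n_x) smoothed means
    Ps: np.ndarray    # (T, n_x, n_x)
    Plag: np.ndarray  # (T-1, n_x, n_x), cov(x_{t+1}, x_t | all data)


# ---------------------------------------------------------------------------
# Compiled kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _filter_core(A, W, x0, L0, alpha, dt, C, R, N, Y, obs_mask, pp_iters):
    T = N.shape[0]
    n_x = A.shape[0]
    n_c = alpha.shape[0]
    n_y = C.shape[0]
    a0 = alpha[:, 0].copy() if n_c else np.zeros(0)
    aS = alpha[:, 1:].copy() if n_c else np.zeros((0, n_x))
    c0 = C[:, 0].copy() if n_y else np.zeros(0)
    Cs = C[:, 1:].copy() if n_y else np.zeros((0, n_x))

    xf = np.zeros((T, n_x))
    Pf = np.zeros((T, n_x, n_x))
    xp = np.zeros((T, n_x))
    Pp = np.zeros((T, n_x, n_x))
    ll = np.zeros(T)
    eye = np.eye(n_x)
    ln2pi = 1.8378770664093453

    x = x0.copy()
    P = L0.copy()
    err_step = -1
    err_chan = -1
    for t in range(T):
        if t > 0:
            x = A @ x
            P = A @ P @ A.T + W
            P = 0.5 * (P + P.T)
        xp[t] = x
        Pp[t] = P

        # -- point-process update (every step) --------------------------
        if n_c > 0:
            lam = np.exp(a0 + aS @ x)
            for c in range(n_c):
                if lam[c] * dt > RATE_DIVERGENCE:
                    err_step = t
                    err_chan = c
                    return xf, Pf, xp, Pp, ll, err_step, err_chan
                ll[t] += N[t, c] * np.log(lam[c] * dt + 1e-300) - lam[c] * dt
            Pinv = np.linalg.inv(P + JITTER * eye)
            xm = x
            for _ in range(pp_iters):
                lam_i = np.exp(a0 + aS @ xm)
                S = Pinv.copy()
                g = Pinv @ (x - xm)
                for c in range(n_c):
                    ld = lam_i[c] * dt
                    for i in range(n_x):
                        g[i] += aS[c, i] * (N[t, c] - ld)
                        for j in range(n_x):
                            S[i, j] += ld * aS[c, i] * aS[c, j]
                Pnew = np.linalg.inv(S)
                step = Pnew @ g
                xm = xm + step
                P = 0.5 * (Pnew + Pnew.T)
                if np.sqrt(np.sum(step * step)) < 1e-8:
                    break
            x = xm

        # -- Gaussian update (slow-scale steps only) --------------------
        if n_y > 0 and obs_mask[t]:
            innov = Y[t] - c0 - Cs @ x
            S = Cs @ P @ Cs.T + R
            S = 0.5 * (S + S.T)
            sign, logdet = np.linalg.slogdet(S)
            if sign <= 0:
                err_step = t
                err_chan = -2
                return xf, Pf, xp, Pp, ll, err_step, err_chan
            Sinv_innov = np.linalg.solve(S, innov)
            K = P @ Cs.T @ np.linalg.inv(S)
            x = x + K @ innov
            IKC = eye - K @ Cs
            P = IKC @ P @ IKC.T + K @ R @ K.T  # Joseph form
            P = 0.5 * (P + P.T)
            ll[t] += -0.5 * (n_y * ln2pi + logdet + innov @ Sinv_innov)

        xf[t] = x
        Pf[t] = P
    return xf, Pf, xp, Pp, ll, err_step, err_chan


@njit(cache=True)
def _smoother_core(A, xf, Pf, xp, Pp):
    T, n_x = xf.shape
    xs = np.zeros_like(xf)
    Ps = np.zeros_like(Pf)
    Plag = np.zeros((max(T - 1, 0), n_x, n_x))
    xs[T - 1] = xf[T - 1]
    Ps[T - 1] = Pf[T - 1]
    for t in range(T - 2, -1, -1):
        J = Pf[t] @ A.T @ np.linalg.inv(Pp[t + 1] + JITTER * np.eye(n_x))
        xs[t] = xf[t] + J @ (xs[t + 1] - xp[t + 1])
        Pst = Pf[t] + J @ (Ps[t + 1] - Pp[t + 1]) @ J.T
        Ps[t] = 0.5 * (Pst + Pst.T)
        Plag[t] = Ps[t + 1] @ J.T
    return xs, Ps, Plag


# ---------------------------------------------------------------------------
# Public filters / smoothers
# ---------------------------------------------------------------------------

def _run_filter(params: ModelParams, N: np.ndarray | None,
                Y: np.ndarray | None, pp_iters: int) -> FilterResult:
    """Run the shared kernel.  The segment length is taken from the data
    (spike rows, or LFP rows * k), so filters run on fold segments of any
    length; the params' timebase supplies only dt and k."""
    tb = params.timebase
    n_x = params.n_x
    if N is not None:
        N = np.asarray(N, dtype=float)
        T = N.shape[0]
    elif Y is not None and np.asarray(Y).shape[0] > 0:
        T = np.asarray(Y).shape[0] * tb.k
    else:
        T = tb.T  # no data rows: pure prediction over the timebase
    if N is None or params.n_c == 0:
        Nfull = np.zeros((T, 0))
        alpha = np.zeros((0, n_x + 1))
    else:
        Nfull, alpha = np.ascontiguousarray(N), params.alpha
    obs_mask = np.zeros(T, dtype=np.bool_)
    if Y is None or params.n_y == 0:
        Yfull = np.zeros((T, 0))
        C, R = np.zeros((0, n_x + 1)), np.zeros((0, 0))
    else:
        Y = np.asarray(Y, dtype=float)
        steps = tb.k * np.arange(1, T // tb.k + 1) - 1
        if Y.shape[0] != steps.size:
            raise ValueError(f"lfp has {Y.shape[0]} rows, expected {steps.size}")
        Yfull = np.zeros((T, params.n_y))
        Yfull[steps] = Y
        obs_mask[steps] = True
        C, R = params.C, params.R
    out = _filter_core(params.A, params.W, params.x0, params.Lambda0,
                       np.ascontiguousarray(alpha), tb.dt,
                       np.ascontiguousarray(C), np.ascontiguousarray(R),
                       np.ascontiguousarray(Nfull), np.ascontiguousarray(Yfull),
                       obs_mask, pp_iters)
    xf, Pf, xp, Pp, ll, err_step, err_chan = out
    if err_step >= 0:
        if err_chan == -2:
            raise FilterError(f"singular innovation covariance at step {err_step}")
        raise FilterError(
            f"divergent rate (lambda*dt > {RATE_DIVERGENCE}) at step {err_step}, "
            f"channel {err_chan}; offending alpha row: {params.alpha[err_chan]}")
    return FilterResult(xf=xf, Pf=Pf, xp=xp, Pp=Pp, loglik=ll)


def kalman_filter(Y: np.ndarray, params: ModelParams,
                  ) -> FilterResult:
    """Kalman filter for the LFP-only model; updates only at slow-scale steps."""
    if params.scale_tag != "lfp":
        raise ValueError("kalman_filter requires scale_tag='lfp'")
    return _run_filter(params, None, Y, pp_iters=1)


def point_process_filter(N: np.ndarray, params: ModelParams, *,
                         pp_iters: int = 1) -> FilterResult:
    """Point-process filter for the spike-only model (Gaussian approximation)."""
    if params.scale_tag != "spike":
        raise ValueError("point_process_filter requires scale_tag='spike'")
    return _run_filter(params, N, None, pp_iters=pp_iters)


def multiscale_filter(N: np.ndarray, Y: np.ndarray, params: ModelParams, *,
                      pp_iters: int = 1) -> FilterResult:
    """Multiscale filter: point-process update every step, Gaussian update at
    slow-scale steps (spike and LFP streams are conditionally independent
    given the state)."""
    if params.scale_tag != "multiscale":
        raise ValueError("multiscale_filter requires scale_tag='multiscale'")
    return _run_filter(params, N, Y, pp_iters=pp_iters)


def _run_smoother(fr: FilterResult, params: ModelParams) -> SmootherResult:
    xs, Ps, Plag = _smoother_core(params.A, fr.xf, fr.Pf, fr.xp, fr.Pp)
    return SmootherResult(xs=xs, Ps=Ps, Plag=Plag)


def kalman_smoother(fr: FilterResult, params: ModelParams) -> SmootherResult:
    """Fixed-interval RTS smoother with lag-one cross-covariances."""
    return _run_smoother(fr, params)


def point_process_smoother(fr: FilterResult, params: ModelParams) -> SmootherResult:
    return _run_smoother(fr, params)


def multiscale_smoother(fr: FilterResult, params: ModelParams) -> SmootherResult:
    return _run_smoother(fr, params)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_params(params: ModelParams, path) -> None:
    with h5py.File(path, "w") as f:
        for name in ("A", "W", "x0", "Lambda0", "C", "R", "alpha"):
            f.create_dataset(name, data=getattr(params, name))
        f.attrs["dt"] = params.timebase.dt
        f.attrs["k"] = params.timebase.k
        f.attrs["T"] = params.timebase.T
        f.attrs["scale_tag"] = params.scale_tag


def load_params(path) -> ModelParams:
    with h5py.File(path, "r") as f:
        kw = {name: f[name][()] for name in
              ("A", "W", "x0", "Lambda0", "C", "R", "alpha")}
        tb = TimeBase(dt=float(f.attrs["dt"]), k=int(f.attrs["k"]),
                      T=int(f.attrs["T"]))
        return ModelParams(timebase=tb, scale_tag=str(f.attrs["scale_tag"]), **kw)
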