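"""Mid-level plumbing: fold slicing, per-scale fitting and state estimation,
fold evaluation, and the eigenvalue-dimension diagram builder."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .datasets import FoldSplit, NeuralDataset, TimeBase
from .decoding import (behavior_cc, fit_projection, one_step_lfp_cc,
                       one_step_spike_pp, predict_behavior)
from .learning import EMOptions, EMTrace, em_lgssm, em_multiscale, em_ppssm
from .modes import EigDimDiagram, Mode, extract_modes, mode_contribution
from .ssm import (FilterResult, ModelParams, kalman_filter, multiscale_filter,
                  point_process_filter)

logger = logging.getLogger(__name__)

__all__ = ["SegmentData", "slice_segments", "fit_scale", "filter_scale",
           "evaluate_fold", "build_diagram"]

SCALES = ("spike", "lfp", "multiscale")


@dataclass
class SegmentData:
    """Arrays for a union of step ranges (train or test side of a fold)."""

    spikes: np.ndarray
    lfp: np.ndarray
    behavior: np.ndarray
    timebase: TimeBase


def slice_segments(ds: NeuralDataset, ranges) -> SegmentData:
    """Concatenate the given half-open step ranges.  Ranges are expected to
    be snapped to multiples of k (make_folds guarantees this), so the LFP
    rows of each range concatenate consistently."""
    k = ds.timebase.k
    sp, lf, bh = [], [], []
    for a, b in ranges:
        sp.append(ds.spikes[a:b])
        bh.append(ds.behavior[a:b])
        lf.append(ds.lfp[a // k: b // k])
    spikes = np.vstack(sp) if sp else ds.spikes[:0]
    behavior = np.vstack(bh) if bh else ds.behavior[:0]
    lfp = np.vstack(lf) if lf else ds.lfp[:0]
    tb = TimeBase(dt=ds.timebase.dt, k=k, T=spikes.shape[0])
    return SegmentData(spikes=spikes, lfp=lfp, behavior=behavior, timebase=tb)


def fit_scale(seg: SegmentData, scale: str, opts: EMOptions,
              ) -> tuple[ModelParams, EMTrace]:
    """Fit the model of one scale to a training segment."""
    if scale == "lfp":
        return em_lgssm(seg.lfp, opts, seg.timebase)
    if scale == "spike":
        return em_ppssm(seg.spikes, opts, seg.timebase)
    if scale == "multiscale":
        return em_multiscale(seg.spikes, seg.lfp, opts, seg.timebase)
    raise ValueError(f"unknown scale {scale!r}")


def filter_scale(seg: SegmentData, params: ModelParams) -> FilterResult:
    """Run the filter matching the params' scale on a segment."""
    if params.scale_tag == "lfp":
        return kalman_filter(seg.lfp, params)
    if params.scale_tag == "spike":
        return point_process_filter(seg.spikes, params)
    return multiscale_filter(seg.spikes, seg.lfp, params)


@dataclass
class FoldEvaluation:
    params: ModelParams
    modes: list[Mode]
    overall_cc: float
    mode_cc: list[float]        # per-mode behavior CC (mean over behavior dims)
    mode_neural: list[float]    # per-mode one-step neural metric
    pp_spike: np.ndarray
    cc_lfp: np.ndarray


def evaluate_fold(ds: NeuralDataset, fold: FoldSplit, scale: str,
                  opts: EMOptions) -> FoldEvaluation:
    """Fit on the training side of one fold, decode on the test side, and
    attribute behavior/neural prediction to each mode via the modal
    decomposition (Eq.-9-style linear attribution)."""
    train = slice_segments(ds, fold.train_ranges)
    test = slice_segments(ds, fold.test_ranges)
    params, _ = fit_scale(train, scale, opts)
    modes, decomp = extract_modes(params.A, params.timebase.dt)

    fr_train = filter_scale(train, params)
    proj = fit_projection(fr_train.xf, train.behavior)
    fr_test = filter_scale(test, params)
    zhat = predict_behavior(fr_test.xf, proj)
    _, overall = behavior_cc(test.behavior, zhat)

    pp = one_step_spike_pp(test.spikes, params, fr_test) \
        if scale in ("spike", "multiscale") else np.zeros(0)
    cl = one_step_lfp_cc(test.lfp, params, fr_test) \
        if scale in ("lfp", "multiscale") else np.zeros(0)

    mode_cc, mode_neural = [], []
    k = params.timebase.k
    lfp_steps = k * np.arange(1, test.lfp.shape[0] + 1) - 1
    for m in modes:
        contrib = mode_contribution(decomp, proj.weights, fr_test.xf, m)
        ccs, mcc = behavior_cc(test.behavior, contrib + proj.bias)
        mode_cc.append(mcc)
        if scale == "spike":
            eta_i = mode_contribution(decomp, params.alpha[:, 1:], fr_test.xp, m)
            prob = np.exp(np.minimum(params.alpha[:, 0] + eta_i, 50)) \
                * params.timebase.dt
            from .decoding import auc_rank
            aucs = [auc_rank(prob[:, c], test.spikes[:, c])
                    for c in range(test.spikes.shape[1])]
            aucs = [2 * a - 1 for a in aucs if np.isfinite(a)]
            mode_neural.append(float(np.mean(aucs)) if aucs else np.nan)
        else:
            yci = mode_contribution(decomp, params.C[:, 1:],
                                    fr_test.xp[lfp_steps], m)
            ccs_y, mccy = behavior_cc(test.lfp, yci + params.C[:, 0])
            mode_neural.append(mccy)
    return FoldEvaluation(params=params, modes=modes, overall_cc=overall,
                          mode_cc=mode_cc, mode_neural=mode_neural,
                          pp_spike=pp, cc_lfp=cl)


def build_diagram(ds: NeuralDataset, scale: str, dims, folds: list[FoldSplit],
                  opts: EMOptions | None = None) -> EigDimDiagram:
    """Fit models at each latent dimension on every fold's training set and
    collect their modes with cross-validated per-mode metrics.

    A dimension where EM fails is skipped with a warning; the diagram
    remains valid without it.
    """
    dims = sorted(int(d) for d in dims)
    if any(d < 1 or d > 25 for d in dims):
        raise ValueError("dims must lie in [1, 25]")
    opts = opts or EMOptions()
    modes_by_dim: dict[int, list[Mode]] = {}
    cc_map: dict[tuple[int, int], float] = {}
    nm_map: dict[tuple[int, int], float] = {}
    kept_dims = []
    for d in dims:
        o = EMOptions(**{**opts.__dict__, "n_x": d})
        dim_modes: list[Mode] = []
        try:
            for fold in folds:
                ev = evaluate_fold(ds, fold, scale, o)
                for m, mcc, mnm in zip(ev.modes, ev.mode_cc, ev.mode_neural):
                    idx = len(dim_modes)
                    dim_modes.append(m)
                    cc_map[(d, idx)] = mcc
                    nm_map[(d, idx)] = mnm
        except (RuntimeError, ValueError, np.linalg.LinAlgError) as e:
            warnings.warn(f"EM failed at dimension {d} ({e}); skipping")
            continue
        modes_by_dim[d] = dim_modes
        kept_dims.append(d)
    return EigDimDiagram(dims=kept_dims, modes_by_dim=modes_by_dim,
                         dt=ds.timebase.dt, behavior_cc=cc_map,
                         neural_metric=nm_map,
                         models_per_dim={d: len(folds) for d in kept_dims})
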