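"""Orchestrated experiments on multiscale modal structure.

Each function reproduces one analysis at desk scale on synthetic (or
user-supplied) data: the cross-validated modal pipeline over scales, the
channel-set Monte Carlo comparison of single-scale versus combined fits, the
decay/frequency perturbation of the predictive mode, behavior modal
analysis, PSD peak analysis, and the LFP frequency-band subset analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .datasets import NeuralDataset, make_folds
from .learning import EMOptions, em_constrained_A, em_lgssm
from .modes import (EigDimDiagram, Mode, ModeCluster, chance_level_distance,
                    cluster_modes, extract_modes, identify_predictive_mode,
                    mode_distance, mode_region, vertical_test)
from .pipeline import build_diagram, evaluate_fold, filter_scale, fit_scale, \
    slice_segments
from .decoding import behavior_cc, fit_projection, predict_behavior
from .stats import bh_fdr, corrected_resampled_ttest
from .datasets import TimeBase

logger = logging.getLogger(__name__)

__all__ = [
    "ScaleReport", "PipelineReport", "run_pipeline",
    "ChannelSet", "channel_set_experiment",
    "PerturbationGrid", "perturbation_experiment",
    "MVLRResult", "mvlr_decay_frequency",
    "behavior_modal_analysis", "psd_peaks", "band_subset_experiment",
]


# ---------------------------------------------------------------------------
# Full modal pipeline
# ---------------------------------------------------------------------------

@dataclass
class ScaleReport:
    scale: str
    diagram: EigDimDiagram
    clusters: list[ModeCluster]
    chance: float
    predictive_index: int | None
    dominance_p: dict[int, float]

    @property
    def predictive_cluster(self) -> ModeCluster | None:
        if self.predictive_index is None:
            return None
        return self.clusters[self.predictive_index]


@dataclass
class PipelineReport:
    scales: dict[str, ScaleReport]
    cross_scale_distances: dict[tuple[str, str], float] = field(
        default_factory=dict)


def analyze_diagram(diag: EigDimDiagram, seed: int = 0, *,
                    chance_region=None, alpha: float = 0.05,
                    min_compare_members: int = 3,
                    ) -> tuple[list[ModeCluster], float, int | None, dict]:
    """Cluster a diagram, run FDR-corrected vertical tests, and identify the
    predictive cluster.

    Dominance is tested among the complex clusters with at least
    ``min_compare_members`` members (a rank-sum against a one-member noise
    cluster is powerless); the winner is flagged predictive only if it also
    passes the vertical (principal-mode) test.
    """
    clusters = cluster_modes(diag, seed=seed)
    entries = [m for _, _, m in diag.all_modes()]
    explicit_region = chance_region is not None
    region = chance_region if explicit_region else mode_region(entries)
    chance = chance_level_distance(region, n_samples=200_000, seed=seed)

    def _in_region(c):
        # with a caller-fixed reference region, only clusters inside it can
        # qualify as principal: the chance-level comparison is meaningful
        # only for modes in the region of interest
        if not explicit_region:
            return True
        re0, re1, im0, im1 = region
        return (re0 <= c.centroid.real <= re1
                and im0 <= c.centroid.imag <= im1)

    testable = [c for c in clusters if len(c.members) >= 5]
    pvals = []
    for c in testable:
        p, _ = vertical_test(c, chance)
        pvals.append(p if p is not None else 1.0)
    if pvals:
        rejected, _ = bh_fdr(np.array(pvals), alpha=alpha)
        for c, rej in zip(testable, rejected):
            c.vertical = bool(rej) and c.vertical_p is not None \
                and float(np.median(c.member_distances())) < chance / 2 \
                and _in_region(c)
    candidates = [c for c in clusters if c.kind == "complex"
                  and len(c.members) >= min_compare_members]
    pred_idx, dom_p = identify_predictive_mode(candidates, alpha=alpha)
    if pred_idx is not None:
        target = candidates[pred_idx]
        target.predictive = target.predictive and target.vertical
        pred_idx = next(i for i, c in enumerate(clusters) if c is target)
    return clusters, chance, pred_idx, dom_p


def run_pipeline(ds: NeuralDataset, scales=("spike", "lfp", "multiscale"),
                 dims=range(1, 26), seed: int = 0, *, n_folds: int = 5,
                 eval_folds: int | None = None,
                 em_opts: EMOptions | None = None,
                 chance_region=None) -> PipelineReport:
    """Per scale: eigenvalue-dimension diagram -> K-means clusters ->
    FDR-corrected vertical tests -> predictive-mode identification; then
    cross-scale distances between predictive centroids."""
    folds = make_folds(ds, n_folds=n_folds)
    if eval_folds is not None:
        folds = folds[:eval_folds]
    reports: dict[str, ScaleReport] = {}
    for scale in scales:
        diag = build_diagram(ds, scale, dims, folds, em_opts)
        clusters, chance, pred_idx, dom_p = analyze_diagram(
            diag, seed=seed, chance_region=chance_region)
        reports[scale] = ScaleReport(scale=scale, diagram=diag,
                                     clusters=clusters, chance=chance,
                                     predictive_index=pred_idx,
                                     dominance_p=dom_p)
    dist: dict[tuple[str, str], float] = {}
    names = list(reports)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ca, cb = reports[a].predictive_cluster, reports[b].predictive_cluster
            if ca is not None and cb is not None:
                dist[(a, b)] = float(abs(ca.centroid - cb.centroid))
    return PipelineReport(scales=reports, cross_scale_distances=dist)


# ---------------------------------------------------------------------------
# Channel-set Monte Carlo experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelSet:
    draw: int
    baseline_scale: str                 # "spike" or "lfp"
    baseline_ids: tuple[int, ...]
    added_ids: tuple[int, ...]


@dataclass
class ChannelSetResult:
    sets: list[ChannelSet]
    single_distance: np.ndarray
    combined_distance: np.ndarray
    single_cc: np.ndarray
    combined_cc: np.ndarray
    distance_improvement_t: float = np.nan
    distance_improvement_p: float = np.nan
    corr_improvement: float = np.nan
    corr_p: float = np.nan


def _closest_mode(modes: list[Mode], reference: Mode | complex,
                  kind: str = "complex") -> tuple[int, float]:
    cands = [(i, mode_distance(m, reference)) for i, m in enumerate(modes)
             if kind is None or m.kind == kind]
    if not cands:
        cands = [(i, mode_distance(m, reference)) for i, m in enumerate(modes)]
    i, d = min(cands, key=lambda t: t[1])
    return i, d


def channel_set_experiment(ds: NeuralDataset, reference_mode: Mode | complex,
                           n_base: int = 5, n_add: int = 25,
                           n_sets: int = 20, n_x: int = 15, seed: int = 0, *,
                           n_folds: int = 2, eval_folds: int | None = None,
                           em_opts: EMOptions | None = None,
                           ) -> ChannelSetResult:
    """Monte Carlo channel sets: a few baseline channels of one scale versus
    those plus added channels of the other scale, fitted single-scale and
    multiscale respectively.

    For each set we record the distance of the closest estimated mode to the
    reference (multiscale predictive) mode and that mode's cross-validated
    behavior prediction accuracy, then test the paired improvement with the
    corrected resampled t-test.
    """
    rng = np.random.default_rng(seed)
    if ds.n_c < n_base or ds.n_y < n_add:
        if ds.n_y < n_base or ds.n_c < n_add:
            raise ValueError("not enough channels for the requested set sizes")
    base_opts = em_opts or EMOptions()
    folds = make_folds(ds, n_folds=n_folds)
    if eval_folds is not None:  # evaluate a subset of folds to bound runtime
        folds = folds[:eval_folds]
    sets: list[ChannelSet] = []
    sd, cd, scc, ccc = [], [], [], []
    for i in range(n_sets):
        baseline_scale = "spike" if i % 2 == 0 else "lfp"
        if baseline_scale == "spike" and ds.n_c >= n_base and ds.n_y >= n_add:
            bids = tuple(rng.choice(ds.n_c, n_base, replace=False))
            aids = tuple(rng.choice(ds.n_y, min(n_add, ds.n_y), replace=False))
        else:
            baseline_scale = "lfp"
            bids = tuple(rng.choice(ds.n_y, n_base, replace=False))
            aids = tuple(rng.choice(ds.n_c, min(n_add, ds.n_c), replace=False))
        cs = ChannelSet(draw=i, baseline_scale=baseline_scale,
                        baseline_ids=bids, added_ids=aids)
        sets.append(cs)
        sub_single = _subset_dataset(ds, cs, combined=False)
        sub_comb = _subset_dataset(ds, cs, combined=True)
        o = EMOptions(**{**base_opts.__dict__, "n_x": n_x,
                         "seed": base_opts.seed + i})
        try:
            d1, c1 = _closest_mode_cv(sub_single, baseline_scale, folds, o,
                                      reference_mode)
            d2, c2 = _closest_mode_cv(sub_comb, "multiscale", folds, o,
                                      reference_mode)
        except (RuntimeError, ValueError, np.linalg.LinAlgError) as e:
            warnings.warn(f"channel set {i} failed ({e}); draw skipped")
            sets.pop()
            continue
        sd.append(d1), cd.append(d2), scc.append(c1), ccc.append(c2)
    res = ChannelSetResult(sets=sets, single_distance=np.array(sd),
                           combined_distance=np.array(cd),
                           single_cc=np.array(scc), combined_cc=np.array(ccc))
    if n_sets >= 2:
        ddiff = res.single_distance - res.combined_distance  # >0 = improved
        n_test = ds.T // n_folds
        n_train = ds.T - n_test
        t, p = corrected_resampled_ttest(ddiff, n_train, n_test,
                                         alternative="greater")
        res.distance_improvement_t, res.distance_improvement_p = t, p
        cc_impr = res.combined_cc - res.single_cc
        zd = _zscore(ddiff)
        zc = _zscore(cc_impr)
        if np.std(zd) > 0 and np.std(zc) > 0:
            r, pr = sp_stats.pearsonr(zd, zc)
            res.corr_improvement, res.corr_p = float(r), float(pr)
    else:
        logger.info("n_sets=1: significance not evaluable")
    return res


def _zscore(x: np.ndarray) -> np.ndarray:
    s = x.std(ddof=1) if x.size > 1 else 0.0
    return (x - x.mean()) / s if s > 0 else x - x.mean()


def _subset_dataset(ds: NeuralDataset, cs: ChannelSet, combined: bool,
                    ) -> NeuralDataset:
    if cs.baseline_scale == "spike":
        sids = list(cs.baseline_ids)
        lids = list(cs.added_ids) if combined else []
    else:
        lids = list(cs.baseline_ids)
        sids = list(cs.added_ids) if combined else []
    return NeuralDataset(
        spikes=ds.spikes[:, sids] if sids else ds.spikes[:, :0],
        lfp=ds.lfp[:, lids] if lids else ds.lfp[:, :0],
        behavior=ds.behavior, timebase=ds.timebase,
        spike_channel_ids=[ds.spike_channel_ids[i] for i in sids],
        lfp_channel_ids=[ds.lfp_channel_ids[i] for i in lids] if lids else [],
        band_labels=[ds.band_labels[i] for i in lids] if lids else [])


def _closest_mode_cv(sub: NeuralDataset, scale: str, folds, opts: EMOptions,
                     reference) -> tuple[float, float]:
    """Mean over folds of (closest-mode distance, that mode's behavior CC)."""
    dists, ccs = [], []
    for fold in folds:
        ev = evaluate_fold(sub, fold, scale, opts)
        i, d = _closest_mode(ev.modes, reference)
        dists.append(d)
        ccs.append(ev.mode_cc[i])
    return float(np.mean(dists)), float(np.nanmean(ccs))


# ---------------------------------------------------------------------------
# Perturbation of the predictive mode
# ---------------------------------------------------------------------------

@dataclass
class PerturbationGrid:
    decay_grid: np.ndarray
    freq_grid: np.ndarray
    decay_cc: np.ndarray        # mean CV CC per decay grid point (nan = skipped)
    freq_cc: np.ndarray
    baseline_cc: float
    baseline_decay: float
    baseline_frequency: float
    decay_p: np.ndarray = field(default_factory=lambda: np.zeros(0))
    freq_p: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _perturb_A(A: np.ndarray, mode: Mode, decay: float, freq: float,
               dt: float) -> np.ndarray:
    """Replace one mode's eigenvalue pair in A with the perturbed
    (decay, frequency) values, keeping all other modes and the eigenvector
    basis intact."""
    E, U = np.linalg.eig(A)
    r = np.exp(-dt / decay)
    th = 2 * np.pi * freq * dt
    e_new = r * np.exp(1j * th)
    target = mode.eigenvalue
    idx = np.argsort(np.abs(E - target))[:1]
    E2 = E.copy()
    E2[idx[0]] = e_new
    conj_idx = np.argsort(np.abs(E - np.conj(target)))[:1]
    if conj_idx[0] != idx[0]:
        E2[conj_idx[0]] = np.conj(e_new)
    A2 = (U @ np.diag(E2) @ np.linalg.inv(U)).real
    return A2


def perturbation_experiment(ds: NeuralDataset, reference_mode: Mode,
                            decay_grid=None, freq_grid=None, n_x: int = 15,
                            seed: int = 0, *, n_folds: int = 2,
                            eval_folds: int | None = None,
                            em_opts: EMOptions | None = None,
                            ) -> PerturbationGrid:
    """Perturb the predictive mode's decay (frequency fixed) and frequency
    (decay fixed), refit all other parameters with the transition matrix
    frozen, and record the cross-validated behavior CC per grid point.

    Grid points implying a non-decaying eigenvalue (r >= 1) are skipped.
    """
    if reference_mode.kind != "complex":
        raise ValueError("reference mode must be complex")
    dt = ds.timebase.dt
    decay_grid = np.asarray(decay_grid if decay_grid is not None
                            else np.geomspace(0.1, 10.0, 8))
    freq_grid = np.asarray(freq_grid if freq_grid is not None
                           else np.geomspace(0.02, 3.0, 8))
    if np.any(decay_grid <= 0) or np.any(freq_grid <= 0):
        raise ValueError("grids must be positive")
    base_opts = em_opts or EMOptions()
    opts = EMOptions(**{**base_opts.__dict__, "n_x": n_x, "seed": seed})
    folds = make_folds(ds, n_folds=n_folds)
    if eval_folds is not None:
        folds = folds[:eval_folds]

    # baseline fit per fold; locate the mode closest to the reference
    base_ccs, fold_ctx = [], []
    for fold in folds:
        train = slice_segments(ds, fold.train_ranges)
        test = slice_segments(ds, fold.test_ranges)
        params, _ = fit_scale(train, "multiscale", opts)
        modes, _ = extract_modes(params.A, dt)
        mi, _ = _closest_mode(modes, reference_mode)
        cc = _decode_cc(train, test, params)
        base_ccs.append(cc)
        fold_ctx.append((train, test, params, modes[mi]))
    baseline_cc = float(np.mean(base_ccs))
    ref_decay = float(np.mean([m.decay for *_, m in fold_ctx]))
    ref_freq = float(np.mean([m.frequency for *_, m in fold_ctx]))

    def _sweep(values, vary):
        ccs = np.full(len(values), np.nan)
        fold_cc = np.full((len(values), len(folds)), np.nan)
        for gi, v in enumerate(values):
            decay = v if vary == "decay" else ref_decay
            freq = v if vary == "freq" else ref_freq
            if np.exp(-dt / decay) >= 1.0:
                warnings.warn(f"grid point decay={decay} implies r >= 1; skipped")
                continue
            pts = []
            for fi, (train, test, params, mode) in enumerate(fold_ctx):
                A2 = _perturb_A(params.A, mode, decay, freq, dt)
                o2 = EMOptions(**{**opts.__dict__, "A_fixed": A2,
                                  "max_iters": min(opts.max_iters, 50)})
                p2, _ = em_constrained_A(train.spikes, train.lfp, A2, o2,
                                         train.timebase)
                cc = _decode_cc(train, test, p2)
                pts.append(cc)
                fold_cc[gi, fi] = cc
            ccs[gi] = float(np.mean(pts))
        return ccs, fold_cc

    decay_cc, _ = _sweep(decay_grid, "decay")
    freq_cc, _ = _sweep(freq_grid, "freq")
    grid = PerturbationGrid(decay_grid=decay_grid, freq_grid=freq_grid,
                            decay_cc=decay_cc, freq_cc=freq_cc,
                            baseline_cc=baseline_cc,
                            baseline_decay=ref_decay,
                            baseline_frequency=ref_freq)
    return grid


def _decode_cc(train, test, params) -> float:
    fr_tr = filter_scale(train, params)
    proj = fit_projection(fr_tr.xf, train.behavior)
    fr_te = filter_scale(test, params)
    _, cc = behavior_cc(test.behavior, predict_behavior(fr_te.xf, proj))
    return cc


# ---------------------------------------------------------------------------
# MVLR of CC versus decay/frequency deviation
# ---------------------------------------------------------------------------

@dataclass
class MVLRResult:
    a0: float
    a1: float            # frequency-deviation coefficient
    b1: float            # decay-deviation coefficient
    p_a1: float
    p_b1: float
    r2: float
    vif: float
    n_removed: int
    conf_int: np.ndarray


def mvlr_decay_frequency(modes_cc, reference: Mode, *,
                         mad_threshold: float = 3.0) -> MVLRResult:
    """Multivariable linear regression of behavior CC on the absolute decay
    and frequency deviations from the reference (predictive) mode.

    Outliers (any variable > ``mad_threshold`` scaled MADs from its median)
    are removed before the fit; the variance inflation factor between the
    two deviations is reported and must not indicate severe collinearity.
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    modes_cc = list(modes_cc)
    if len(modes_cc) < 10:
        raise ValueError("need at least 10 (mode, CC) pairs")
    ddev = np.array([abs(m.decay - reference.decay) for m, _ in modes_cc])
    fdev = np.array([abs(m.frequency - reference.frequency)
                     for m, _ in modes_cc])
    cc = np.array([c for _, c in modes_cc], dtype=float)

    keep = np.ones(cc.size, dtype=bool)
    removed = 0
    for v in (cc, ddev, fdev):
        med = np.median(v)
        mad = 1.4826 * np.median(np.abs(v - med))
        if mad > 0:
            keep &= np.abs(v - med) <= mad_threshold * mad
    removed = int((~keep).sum())
    X = np.column_stack([fdev[keep], ddev[keep]])
    Xc = sm.add_constant(X)
    vif = max(variance_inflation_factor(Xc, 1),
              variance_inflation_factor(Xc, 2))
    if vif > 100:
        raise ValueError(f"collinear regressors: VIF={vif:.1f}")
    fit = sm.OLS(cc[keep], Xc).fit()
    return MVLRResult(
        a0=float(fit.params[0]), a1=float(fit.params[1]),
        b1=float(fit.params[2]),
        p_a1=float(fit.pvalues[1]), p_b1=float(fit.pvalues[2]),
        r2=float(fit.rsquared), vif=float(vif),
        n_removed=removed, conf_int=np.asarray(fit.conf_int()))


# ---------------------------------------------------------------------------
# Behavior modal analysis and PSD peaks
# ---------------------------------------------------------------------------

def behavior_modal_analysis(Z: np.ndarray, dims, dt: float = 0.01, *,
                            em_opts: EMOptions | None = None, seed: int = 0,
                            neural_modes: list[Mode] | None = None,
                            min_decay: float = 0.1) -> dict:
    """Fit linear Gaussian models directly to behavior trajectories across
    latent dimensions, extract and cluster behavior's own modes, and
    (optionally) compare their decays/frequency spread with neural modes.

    Behavior is observed at every step, so the model runs with k=1.
    Measurement noise produces sub-step transient modes (decays of a few
    ms); summaries and comparisons use the principal modes, defined as
    those with decay >= ``min_decay`` seconds.
    """
    Z = np.asarray(Z, dtype=float)
    if not np.isfinite(Z).all():
        raise ValueError("behavior must be finite")
    base = em_opts or EMOptions()
    tb = TimeBase(dt=dt, k=1, T=Z.shape[0])
    modes_by_dim: dict[int, list[Mode]] = {}
    kept = []
    for d in sorted(dims):
        o = EMOptions(**{**base.__dict__, "n_x": d})
        try:
            params, _ = em_lgssm(Z, o, tb)
            modes, _ = extract_modes(params.A, dt)
        except (RuntimeError, ValueError, np.linalg.LinAlgError) as e:
            warnings.warn(f"behavior EM failed at dimension {d}: {e}")
            continue
        modes_by_dim[d] = modes
        kept.append(d)
    diag = EigDimDiagram(dims=kept, modes_by_dim=modes_by_dim, dt=dt)
    clusters = cluster_modes(diag, seed=seed)
    p_modes = [m for _, _, m in diag.all_modes() if m.decay >= min_decay]
    decays = np.array([m.decay for m in p_modes if np.isfinite(m.decay)])
    freqs = np.array([m.frequency for m in p_modes if m.kind == "complex"])
    out = {"diagram": diag, "clusters": clusters,
           "principal_modes": p_modes,
           "decay_range": (float(decays.min()), float(decays.max()))
           if decays.size else (np.nan, np.nan),
           "frequency_range": (float(freqs.min()), float(freqs.max()))
           if freqs.size else (np.nan, np.nan)}
    if neural_modes:
        nd = [m.decay for m in neural_modes if np.isfinite(m.decay)]
        bd = decays.tolist()
        out["decay_ranksum_p"] = float(
            sp_stats.ranksums(bd, nd, alternative="greater").pvalue) \
            if nd and bd else np.nan
        all_freqs = np.array([m.frequency for _, _, m in diag.all_modes()
                              if m.kind == "complex"])
        nf = [m.frequency for m in neural_modes if m.kind == "complex"]
        if len(nf) > 1 and all_freqs.size > 1 and np.var(nf, ddof=1) > 0:
            F = np.var(all_freqs, ddof=1) / np.var(nf, ddof=1)
            dfn, dfd = all_freqs.size - 1, len(nf) - 1
            p = 2 * min(sp_stats.f.sf(F, dfn, dfd),
                        sp_stats.f.cdf(F, dfn, dfd))
            out["frequency_var_F"] = float(F)
            out["frequency_var_p"] = float(p)
    return out


def psd_peaks(signals: np.ndarray, dt: float) -> np.ndarray:
    """Averaged-periodogram (Welch) PSD peak frequency per signal column;
    nan for constant signals.  The DC bin is excluded."""
    X = np.atleast_2d(np.asarray(signals, dtype=float).T).T
    if X.shape[0] < 256:
        raise ValueError("need at least 256 steps for the PSD")
    fs = 1.0 / dt
    peaks = np.full(X.shape[1], np.nan)
    nper = min(1024, X.shape[0])
    for j in range(X.shape[1]):
        if X[:, j].std() == 0:
            continue
        f, p = sp_signal.welch(X[:, j], fs=fs, nperseg=nper)
        peaks[j] = f[1:][np.argmax(p[1:])]
    return peaks


# ---------------------------------------------------------------------------
# LFP frequency-band subset analysis
# ---------------------------------------------------------------------------

def band_subset_experiment(ds: NeuralDataset, combos, reference: Mode,
                           dims, *, seed: int = 0, n_folds: int = 2,
                           em_opts: EMOptions | None = None) -> dict:
    """Restrict LFP features to each band combination, rebuild the diagram,
    and record the closest cluster's distance to the reference mode and its
    cross-validated CC; then correlate distance with CC across combos
    (z-scored within the session before pooling)."""
    folds = make_folds(ds, n_folds=n_folds)
    rows = []
    for combo in combos:
        combo = set(combo)
        cols = [j for j, b in enumerate(ds.band_labels) if b in combo]
        if not cols:
            warnings.warn(f"combo {sorted(combo)} has no features; skipped")
            continue
        sub = NeuralDataset(
            spikes=ds.spikes[:, :0], lfp=ds.lfp[:, cols],
            behavior=ds.behavior, timebase=ds.timebase,
            lfp_channel_ids=[ds.lfp_channel_ids[j] for j in cols],
            band_labels=[ds.band_labels[j] for j in cols])
        diag = build_diagram(sub, "lfp", dims, folds, em_opts)
        clusters = cluster_modes(diag, seed=seed)
        cplx = [c for c in clusters if c.kind == "complex"]
        if not cplx:
            continue
        best = min(cplx, key=lambda c: abs(c.centroid - reference.eigenvalue))
        rows.append({"combo": tuple(sorted(combo)),
                     "distance": float(abs(best.centroid
                                           - reference.eigenvalue)),
                     "cc": best.mean_cc})
    out = {"per_combo": rows}
    if len(rows) >= 3:
        d = _zscore(np.array([r["distance"] for r in rows]))
        c = _zscore(np.array([r["cc"] for r in rows]))
        if d.std() > 0 and c.std() > 0:
            r, p = sp_stats.pearsonr(d, c)
            out["pooled_corr"] = float(r)
            out["pooled_corr_p"] = float(p)
    return out
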