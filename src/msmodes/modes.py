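"""Dynamical modes of learned state transition matrices.

A mode is a real eigenvalue or a complex-conjugate eigenvalue pair of the
state transition matrix A, summarized by a decay (seconds) and a frequency
(Hz).  For an eigenvalue r*exp(+-j*theta) with step dt:

* decay = dt / log(1/r)      (non-decaying, "ND", when r >= 1)
* frequency = theta / (2*pi*dt)   (non-periodic, "NP", when theta == 0)

Modes of models fitted at latent dimensions 1..n form the
eigenvalue-dimension diagram; dimension-robust ("principal") modes appear as
condensed vertical clusters, found by K-means in the eigenvalue plane and
tested against half of the chance-level distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "Mode",
    "ModalDecomposition",
    "EigDimDiagram",
    "ModeCluster",
    "extract_modes",
    "mode_distance",
    "chance_level_distance",
    "vertical_test",
    "cluster_modes",
    "mode_contribution",
    "identify_predictive_mode",
    "mode_region",
]


@dataclass(frozen=True)
class Mode:
    """One dynamical mode: the theta>=0 representative eigenvalue of a real
    eigenvalue or a conjugate pair, with its decay-frequency characteristic."""

    eigenvalue: complex
    decay: float              # seconds; inf when non-decaying
    frequency: float          # Hz; 0 when non-periodic
    kind: str                 # "real" | "complex"
    non_decaying: bool = False
    non_periodic: bool = False
    alternating: bool = False  # negative real eigenvalue
    source_dimension: int = 0  # n_x of the model it came from
    coord_indices: tuple[int, ...] = ()  # rows of the modal state it owns

    @property
    def r(self) -> float:
        return abs(self.eigenvalue)

    @property
    def theta(self) -> float:
        return float(np.angle(self.eigenvalue))


@dataclass
class ModalDecomposition:
    """Eigendecomposition A = U E U^-1 with the modal state x_modal = U^-1 x."""

    E: np.ndarray        # (n_x,) eigenvalues (diagonal of E)
    U: np.ndarray        # (n_x, n_x) eigenvectors as columns
    U_inv: np.ndarray
    modes: list[Mode] = field(default_factory=list)

    def modal_states(self, x: np.ndarray) -> np.ndarray:
        """Transform a (T, n_x) latent series to modal coordinates (T, n_x)."""
        return x @ self.U_inv.T


def _decay_frequency(e: complex, dt: float) -> tuple[float, float, bool, bool]:
    r = abs(e)
    theta = abs(np.angle(e))
    non_decaying = r >= 1.0
    decay = np.inf if non_decaying else dt / np.log(1.0 / r)
    non_periodic = theta == 0.0
    frequency = theta / (2.0 * np.pi * dt)
    return decay, frequency, non_decaying, non_periodic


def extract_modes(A: np.ndarray, dt: float, *,
                  cond_limit: float = 1e8,
                  source_dimension: int | None = None,
                  ) -> tuple[list[Mode], ModalDecomposition]:
    """Eigendecompose A and return its modes (conjugate pairs collapsed to
    the theta >= 0 representative).

    Negative real eigenvalues are classified as real modes using |e| for the
    decay and flagged ``alternating``.  A near-defective A (eigenvector
    condition number above ``cond_limit``) is rejected.
    """
    A = np.asarray(A, dtype=float)
    n_x = A.shape[0]
    E, U = np.linalg.eig(A)
    cond = np.linalg.cond(U)
    if not np.isfinite(cond) or cond > cond_limit:
        raise np.linalg.LinAlgError(
            f"defective or near-defective A: eigenvector condition number "
            f"{cond:.3g} exceeds {cond_limit:.3g}")
    U_inv = np.linalg.inv(U)
    decomp = ModalDecomposition(E=E, U=U, U_inv=U_inv)
    src = n_x if source_dimension is None else source_dimension

    modes: list[Mode] = []
    used = np.zeros(n_x, dtype=bool)
    order = np.argsort(-E.imag)  # positive-imag representatives first
    for i in order:
        if used[i]:
            continue
        e = E[i]
        if abs(e.imag) < 1e-12:  # real eigenvalue
            e_r = float(e.real)
            decay, freq, nd, npd = _decay_frequency(abs(e_r), dt)
            modes.append(Mode(
                eigenvalue=complex(e_r), decay=decay, frequency=0.0,
                kind="real", non_decaying=nd, non_periodic=True,
                alternating=e_r < 0, source_dimension=src,
                coord_indices=(int(i),)))
            used[i] = True
            continue
        if e.imag < 0:
            e = np.conj(e)
        # find the conjugate partner
        partner = -1
        for j in range(n_x):
            if not used[j] and j != i and abs(E[j] - np.conj(e)) < 1e-8 * max(1.0, abs(e)):
                partner = j
                break
        decay, freq, nd, npd = _decay_frequency(e, dt)
        idx = (int(i),) if partner < 0 else (int(i), int(partner))
        modes.append(Mode(
            eigenvalue=complex(e), decay=decay, frequency=freq,
            kind="complex", non_decaying=nd, non_periodic=npd,
            source_dimension=src, coord_indices=idx))
        used[i] = True
        if partner >= 0:
            used[partner] = True
    decomp.modes = modes
    return modes, decomp


def mode_distance(a: Mode | complex, b: Mode | complex) -> float:
    """Euclidean distance between two modes in the complex eigenvalue plane
    (theta >= 0 representatives)."""
    ea = a.eigenvalue if isinstance(a, Mode) else a
    eb = b.eigenvalue if isinstance(b, Mode) else b
    return float(abs(ea - eb))


def chance_level_distance(region: tuple[float, float, float, float],
                          n_samples: int = 1_000_000,
                          seed: int = 0) -> float:
    """Monte Carlo mean distance between two eigenvalues placed uniformly at
    random in a rectangle ``(re_min, re_max, im_min, im_max)``."""
    re0, re1, im0, im1 = region
    w, h = re1 - re0, im1 - im0
    if w <= 0 or h <= 0:
        return 0.0
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=(n_samples, 2)) * (w, h)
    q = rng.uniform(size=(n_samples, 2)) * (w, h)
    return float(np.hypot(*(p - q).T).mean())


def mode_region(modes: list[Mode], pad: float = 0.1,
                ) -> tuple[float, float, float, float]:
    """Bounding box of a set of modes in the eigenvalue plane, padded by a
    fraction of each side (default reference region for the chance level)."""
    re = np.array([m.eigenvalue.real for m in modes])
    im = np.array([m.eigenvalue.imag for m in modes])
    dre = max(np.ptp(re), 1e-6) * pad
    dim = max(np.ptp(im), 1e-6) * pad
    return (float(re.min() - dre), float(re.max() + dre),
            float(im.min() - dim), float(im.max() + dim))


@dataclass
class EigDimDiagram:
    """Modes of models fitted at latent dimensions dims[0] < dims[1] < ...,
    with optional per-mode cross-validated metrics."""

    dims: list[int]
    modes_by_dim: dict[int, list[Mode]]
    dt: float
    behavior_cc: dict[tuple[int, int], float] = field(default_factory=dict)
    neural_metric: dict[tuple[int, int], float] = field(default_factory=dict)
    models_per_dim: dict[int, int] = field(default_factory=dict)

    def all_modes(self) -> list[tuple[int, int, Mode]]:
        """(dim, index-within-dim, Mode) for every mode in the diagram."""
        out = []
        for d in self.dims:
            for i, m in enumerate(self.modes_by_dim[d]):
                out.append((d, i, m))
        return out


@dataclass
class ModeCluster:
    centroid: complex
    kind: str                        # "real" | "complex"
    members: list[tuple[int, int, Mode]]   # (dim, index, Mode)
    member_cc: list[float] = field(default_factory=list)
    member_neural: list[float] = field(default_factory=list)
    vertical: bool = False
    vertical_p: float | None = None
    predictive: bool = False

    def member_distances(self) -> np.ndarray:
        return np.array([abs(m.eigenvalue - self.centroid)
                         for _, _, m in self.members])

    @property
    def mean_cc(self) -> float:
        vals = [c for c in self.member_cc if np.isfinite(c)]
        return float(np.mean(vals)) if vals else np.nan


def _relative_dev(a: float, b: float) -> float:
    if not np.isfinite(a) or not np.isfinite(b):
        return 0.0 if (not np.isfinite(a) and not np.isfinite(b)) else np.inf
    if b == 0:
        return 0.0 if a == 0 else np.inf
    return abs(a - b) / abs(b)


def cluster_modes(diag: EigDimDiagram, seed: int = 0, *,
                  k_real: int = 4, dim_threshold: int = 10,
                  n_restarts: int = 50,
                  discard_rel_dev: float = 0.5) -> list[ModeCluster]:
    """K-means clustering of diagram modes in the eigenvalue plane.

    Complex and real modes are clustered separately.  The number of complex
    clusters is the median count of complex modes over dimensions above
    ``dim_threshold`` (all dimensions, if none exceed it); the number of
    real clusters is fixed.  After assignment to the nearest centroid, a
    member whose relative decay or frequency deviation from its centroid
    exceeds ``discard_rel_dev`` is discarded as noise.
    """
    entries = diag.all_modes()
    cplx = [(d, i, m) for d, i, m in entries
            if m.kind == "complex" and not m.alternating]
    real = [(d, i, m) for d, i, m in entries if m.kind == "real"]
    clusters: list[ModeCluster] = []

    if cplx:
        # the complex-mode count converges only at high latent dimensions;
        # below the threshold fall back to the upper half of the fitted dims
        high_dims = [d for d in diag.dims if d > dim_threshold]
        if not high_dims:
            high_dims = diag.dims[(len(diag.dims) - 1) // 2:]
        # count complex modes per fitted model (a dimension may hold the
        # modes of several cross-validation fits)
        counts = [sum(1 for dd, _, m in cplx if dd == d)
                  / max(diag.models_per_dim.get(d, 1), 1)
                  for d in high_dims]
        k_cplx = max(1, int(round(np.median(counts))))
        # cluster in standardized (log decay, log frequency) space: near the
        # unit circle the eigenvalue-plane metric collapses dynamically very
        # different decays onto nearby points, and a centroid placed between
        # two tight groups would lose its members to the deviation rule
        pts = np.array([[np.log(min(m.decay, 100.0)),
                         np.log(max(m.frequency, 1e-4))]
                        for _, _, m in cplx])
        pts = (pts - pts.mean(axis=0)) / np.maximum(pts.std(axis=0), 1e-12)
        # if a centroid still loses every member, add one and re-cluster
        for k_try in range(min(k_cplx, len(cplx)), min(k_cplx + 4, len(cplx) + 1)):
            cand, wiped = _kmeans_clusters(pts, cplx, k_try, "complex", seed,
                                           n_restarts, discard_rel_dev,
                                           diag.dt)
            if not wiped:
                break
        clusters += cand
    if real:
        pts = np.array([[m.eigenvalue.real] for _, _, m in real])
        clusters += _kmeans_clusters(pts, real, min(k_real, len(real)),
                                     "real", seed, n_restarts,
                                     discard_rel_dev, diag.dt)[0]
    # attach per-member metrics if the diagram has them
    for cl in clusters:
        cl.member_cc = [diag.behavior_cc.get((d, i), np.nan)
                        for d, i, _ in cl.members]
        cl.member_neural = [diag.neural_metric.get((d, i), np.nan)
                            for d, i, _ in cl.members]
    return clusters


def _kmeans_clusters(pts, entries, k, kind, seed, n_restarts, discard, dt):
    if k < 1:
        return [], False
    if len(entries) < k:
        warnings.warn(f"fewer {kind} modes ({len(entries)}) than clusters; "
                      f"reducing K to {len(entries)}")
        k = len(entries)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    km.fit(pts)
    cents = km.cluster_centers_
    clusters = []
    wiped = False
    for ci in range(k):
        assigned = []
        for (entry, p) in zip(entries, pts):
            # assign each mode to its nearest centroid (ties to lower frequency)
            d2 = ((cents - p) ** 2).sum(axis=1)
            best = np.flatnonzero(d2 == d2.min())
            if len(best) > 1 and kind == "complex":
                best = [best[int(np.argmin(cents[best][:, 1]))]]
            if best[0] == ci:
                assigned.append(entry)
        if not assigned:
            continue
        # centroid in the eigenvalue plane = mean of the assigned members
        centroid = complex(np.mean([m.eigenvalue for _, _, m in assigned]))
        c_decay, c_freq, _, _ = _decay_frequency(centroid if kind == "complex"
                                                 else abs(centroid.real), dt)
        members = []
        for entry in assigned:
            m = entry[2]
            if (_relative_dev(m.decay, c_decay) > discard
                    or (kind == "complex"
                        and _relative_dev(m.frequency, c_freq) > discard)):
                continue
            members.append(entry)
        if members:
            centroid = complex(np.mean([m.eigenvalue for _, _, m in members]))
            clusters.append(ModeCluster(centroid=centroid, kind=kind,
                                        members=members))
        else:
            wiped = True
    return clusters, wiped


def vertical_test(cluster: ModeCluster, chance: float, *,
                  min_members: int = 5) -> tuple[float | None, bool]:
    """One-sided Wilcoxon signed-rank test of member-to-centroid distances
    against half the chance-level distance.  Sets and returns
    (p-value, flag); flag is a raw p < 0.05 decision — callers doing many
    clusters should re-flag after FDR correction."""
    d = cluster.member_distances()
    if d.size < min_members:
        cluster.vertical, cluster.vertical_p = False, None
        return None, False
    diffs = d - chance / 2.0
    if np.all(diffs == 0):
        p = 0.5 ** d.size
    else:
        try:
            _, p = stats.wilcoxon(diffs, alternative="less")
        except ValueError:
            p = 1.0
    flag = bool(p < 0.05) and float(np.median(d)) < chance / 2.0
    cluster.vertical, cluster.vertical_p = flag, float(p)
    return float(p), flag


def mode_contribution(decomp: ModalDecomposition, F: np.ndarray,
                      states: np.ndarray, mode: Mode | int) -> np.ndarray:
    """Contribution of one mode to a linear readout F @ x_t.

    F x_t = F U x_modal = sum_i col_i(FU) row_i(x_modal); the contribution of
    a conjugate pair is the sum over its two coordinates and is real.  F
    excludes any bias column (a bias is offset-only and attributed to no
    mode).  Returns a (T, F.shape[0]) real array.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    n_x = decomp.U.shape[0]
    if F.shape[1] != n_x:
        raise ValueError(f"F has {F.shape[1]} columns, expected n_x={n_x}")
    if isinstance(mode, int):
        mode = decomp.modes[mode]
    xm = decomp.modal_states(np.asarray(states))       # (T, n_x) complex
    FU = F @ decomp.U                                  # (n_b, n_x) complex
    contrib = np.zeros((xm.shape[0], F.shape[0]), dtype=complex)
    for i in mode.coord_indices:
        contrib += np.outer(xm[:, i], FU[:, i])
    if np.abs(contrib.imag).max(initial=0.0) > 1e-6 * max(1.0, np.abs(contrib.real).max(initial=0.0)):
        warnings.warn("mode contribution has a non-negligible imaginary part")
    return contrib.real


def identify_predictive_mode(clusters: list[ModeCluster], *,
                             alpha: float = 0.05,
                             ) -> tuple[int | None, dict[int, float]]:
    """Find the cluster with dominant behavior prediction accuracy.

    Returns the index of the cluster with the highest mean member CC and the
    BH-FDR-adjusted one-sided rank-sum p-values against every other cluster.
    The winner's ``predictive`` flag is set only if every comparison is
    significant after correction.
    """
    from .stats import bh_fdr

    scored = [(i, c) for i, c in enumerate(clusters)
              if np.isfinite(c.mean_cc) and len(c.member_cc) > 0]
    if not scored:
        return None, {}
    best_i, best = max(scored, key=lambda t: t[1].mean_cc)
    best_cc = [c for c in best.member_cc if np.isfinite(c)]
    pvals, keys = [], []
    for i, c in scored:
        if i == best_i:
            continue
        other = [v for v in c.member_cc if np.isfinite(v)]
        if len(other) == 0:
            continue
        _, p = stats.ranksums(best_cc, other, alternative="greater")
        pvals.append(p)
        keys.append(i)
    for c in clusters:
        c.predictive = False
    if not pvals:
        best.predictive = True  # vacuous dominance with a single cluster
        return best_i, {}
    rejected, p_adj = bh_fdr(np.array(pvals), alpha=alpha)
    best.predictive = bool(np.all(rejected))
    return best_i, dict(zip(keys, p_adj))
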