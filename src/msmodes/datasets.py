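"""Dataset containers, validation, fold splitting and HDF5 I/O.

The unit every pipeline stage consumes is :class:`NeuralDataset`: binary spike
events on a fast (10 ms) time base, LFP band log-power features on a slower
(50 ms) time base, and behavior trajectories sampled on the fast time base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "TimeBase",
    "NeuralDataset",
    "FoldSplit",
    "FormatError",
    "ValidationError",
    "load_dataset",
    "save_dataset",
    "load_behavior_csv",
    "make_folds",
]


class FormatError(ValueError):
    """A file does not conform to the expected HDF5 layout."""


class ValidationError(ValueError):
    """A dataset violates one of its structural invariants."""


@dataclass(frozen=True)
class TimeBase:
    """Processing time base shared by all streams.

    Parameters
    ----------
    dt : float
        Seconds per processing step; the latent state advances at this step.
    k : int
        Integer ratio of the LFP time-scale to the spike time-scale
        (50 ms / 10 ms = 5 by default).  LFP features exist only at steps
        that are multiples of ``k``.
    T : int
        Number of processing steps.
    """

    dt: float = 0.01
    k: int = 5
    T: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if int(self.k) != self.k or self.k < 1:
            raise ValidationError("k must be an integer >= 1")
        if self.T < 0:
            raise ValidationError("T must be nonnegative")

    @property
    def lfp_steps(self) -> np.ndarray:
        """Steps (0-based) at which LFP features exist: k-1, 2k-1, ...

        With 0-based, half-open step indexing, the m-th LFP feature window
        (m = 1, 2, ...) covers steps [ (m-1)k, mk ), so the feature is
        attached to the last step it covers.
        """
        n = self.T // self.k
        return self.k * np.arange(1, n + 1) - 1

    @property
    def n_lfp_steps(self) -> int:
        return self.T // self.k

    @property
    def nyquist(self) -> float:
        return 0.5 / self.dt


@dataclass
class NeuralDataset:
    """Aligned spike, LFP-feature and behavior streams on one time base.

    ``spikes`` is a T x n_c binary matrix, ``lfp`` a (T // k) x n_y real
    matrix of band log-power features, ``behavior`` a T x n_b real matrix.
    Channel metadata keeps spike/LFP channel ids (non-overlapping pools) and
    a band label per LFP feature.
    """

    spikes: np.ndarray
    lfp: np.ndarray
    behavior: np.ndarray
    timebase: TimeBase
    spike_channel_ids: list[str] = field(default_factory=list)
    lfp_channel_ids: list[str] = field(default_factory=list)
    band_labels: list[str] = field(default_factory=list)
    behavior_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        self.lfp = np.asarray(self.lfp, dtype=float)
        self.behavior = np.asarray(self.behavior, dtype=float)
        if not self.spike_channel_ids:
            self.spike_channel_ids = [f"s{i}" for i in range(self.n_c)]
        if not self.lfp_channel_ids and self.n_y:
            self.lfp_channel_ids = [f"l{i}" for i in range(self.n_y)]
        if not self.band_labels and self.n_y:
            self.band_labels = ["broadband"] * self.n_y
        if not self.behavior_labels and self.n_b:
            self.behavior_labels = [f"b{i}" for i in range(self.n_b)]
        self.validate()

    # -- shape accessors -------------------------------------------------
    @property
    def n_c(self) -> int:
        return self.spikes.shape[1]

    @property
    def n_y(self) -> int:
        return self.lfp.shape[1]

    @property
    def n_b(self) -> int:
        return self.behavior.shape[1]

    @property
    def T(self) -> int:
        return self.timebase.T

    def validate(self) -> None:
        tb = self.timebase
        if self.spikes.ndim != 2 or self.lfp.ndim != 2 or self.behavior.ndim != 2:
            raise ValidationError("spikes, lfp and behavior must be 2-D arrays")
        if self.n_c == 0 and self.n_y == 0:
            raise ValidationError("no neural channels: need spikes or LFP features")
        if self.spikes.shape[0] != tb.T:
            raise ValidationError(
                f"spikes rows {self.spikes.shape[0]} != T {tb.T}"
            )
        if self.behavior.shape[0] != tb.T:
            raise ValidationError(
                f"behavior rows {self.behavior.shape[0]} != T {tb.T}"
            )
        if self.lfp.shape[0] != tb.n_lfp_steps:
            raise ValidationError(
                f"lfp rows {self.lfp.shape[0]} != floor(T/k) {tb.n_lfp_steps}"
            )
        if self.n_c and not np.isin(self.spikes, (0, 1)).all():
            raise ValidationError("spikes not binary")
        if self.n_y and not np.isfinite(self.lfp).all():
            raise ValidationError("lfp contains non-finite values")
        if self.n_b and not np.isfinite(self.behavior).all():
            raise ValidationError("behavior contains non-finite values")
        if set(self.spike_channel_ids) & set(self.lfp_channel_ids):
            raise ValidationError("spike and LFP channel id pools overlap")
        if self.n_y and len(self.band_labels) != self.n_y:
            raise ValidationError("band_labels length != n_y")


@dataclass(frozen=True)
class FoldSplit:
    """One cross-validation fold: half-open step ranges on the fast time base."""

    index: int
    train_ranges: tuple[tuple[int, int], ...]
    test_ranges: tuple[tuple[int, int], ...]

    def test_steps(self) -> np.ndarray:
        return np.concatenate(
            [np.arange(a, b) for a, b in self.test_ranges]
        ) if self.test_ranges else np.empty(0, dtype=int)

    def train_steps(self) -> np.ndarray:
        return np.concatenate(
            [np.arange(a, b) for a, b in self.train_ranges]
        ) if self.train_ranges else np.empty(0, dtype=int)


# ---------------------------------------------------------------------------
# HDF5 I/O
# ---------------------------------------------------------------------------

def save_dataset(ds: NeuralDataset, path) -> None:
    """Write a dataset to the canonical HDF5 layout (round-trip exact)."""
    ds.validate()
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.create_dataset("spikes", data=ds.spikes.astype(np.uint8))
        g = f.create_group("lfp")
        g.create_dataset("features", data=ds.lfp.astype(np.float64))
        g.create_dataset("band_labels", data=np.array(ds.band_labels, dtype=str_dt))
        f.create_dataset("behavior", data=ds.behavior.astype(np.float64))
        m = f.create_group("meta")
        m.attrs["dt"] = ds.timebase.dt
        m.attrs["k"] = ds.timebase.k
        m.create_dataset(
            "spike_channel_ids", data=np.array(ds.spike_channel_ids, dtype=str_dt)
        )
        m.create_dataset(
            "lfp_channel_ids", data=np.array(ds.lfp_channel_ids, dtype=str_dt)
        )
        m.create_dataset(
            "behavior_labels", data=np.array(ds.behavior_labels, dtype=str_dt)
        )


def _require(f: h5py.File, node: str):
    if node not in f:
        raise FormatError(f"missing HDF5 node: {node}")
    return f[node]


def load_dataset(path) -> NeuralDataset:
    """Load and validate a dataset from the canonical HDF5 layout."""
    with h5py.File(path, "r") as f:
        spikes = _require(f, "spikes")[()]
        lfp = _require(f, "lfp/features")[()]
        band_labels = [s.decode() if isinstance(s, bytes) else str(s)
                       for s in _require(f, "lfp/band_labels")[()]]
        behavior = _require(f, "behavior")[()]
        meta = _require(f, "meta")
        if "dt" not in meta.attrs or "k" not in meta.attrs:
            raise FormatError("missing HDF5 node: meta/{dt,k}")
        tb = TimeBase(dt=float(meta.attrs["dt"]), k=int(meta.attrs["k"]),
                      T=spikes.shape[0])
        def _strs(name):
            return [s.decode() if isinstance(s, bytes) else str(s)
                    for s in _require(f, f"meta/{name}")[()]]
        ds = NeuralDataset(
            spikes=spikes,
            lfp=lfp,
            behavior=behavior,
            timebase=tb,
            spike_channel_ids=_strs("spike_channel_ids"),
            lfp_channel_ids=_strs("lfp_channel_ids"),
            band_labels=band_labels,
            behavior_labels=_strs("behavior_labels"),
        )
    return ds


def load_behavior_csv(path, timebase: TimeBase) -> np.ndarray:
    """Read behavior from CSV (one header row of labels, one row per step)."""
    df = pd.read_csv(path)
    z = df.to_numpy(dtype=float)
    if z.shape[0] != timebase.T:
        raise ValidationError(f"behavior CSV has {z.shape[0]} rows, expected {timebase.T}")
    return z


# ---------------------------------------------------------------------------
# Cross-validation folds
# ---------------------------------------------------------------------------

def make_folds(ds: NeuralDataset, n_folds: int = 5, contiguous: bool = True,
               seed: int | None = None) -> list[FoldSplit]:
    """Partition [0, T) into cross-validation folds.

    Folds are contiguous temporal blocks by default, which avoids temporal
    leakage in autocorrelated series; boundaries are snapped down to
    multiples of ``k`` so LFP availability is consistent within folds.  With
    ``contiguous=False`` the k-blocks are assigned to folds at random.
    """
    tb = ds.timebase
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if tb.T < n_folds * tb.k:
        raise ValueError(f"T={tb.T} too small for {n_folds} folds with k={tb.k}")
    n_blocks = tb.T // tb.k
    # block b covers steps [b*k, (b+1)*k); a possible remainder tail joins the last fold
    edges = np.round(np.linspace(0, n_blocks, n_folds + 1)).astype(int)
    if contiguous:
        block_of_fold = [np.arange(edges[i], edges[i + 1]) for i in range(n_folds)]
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n_blocks)
        block_of_fold = [np.sort(perm[edges[i]:edges[i + 1]]) for i in range(n_folds)]
    folds = []
    for i in range(n_folds):
        test = _blocks_to_ranges(block_of_fold[i], tb.k)
        if i == n_folds - 1 and tb.T % tb.k:
            # the trailing partial k-block joins the last fold's test set
            tail_start = n_blocks * tb.k
            if test and test[-1][1] == tail_start:
                test[-1] = (test[-1][0], tb.T)
            else:
                test.append((tail_start, tb.T))
        train_mask = np.ones(tb.T, dtype=bool)
        for a, b in test:
            train_mask[a:b] = False
        train = _mask_to_ranges(train_mask)
        folds.append(FoldSplit(index=i, train_ranges=tuple(train),
                               test_ranges=tuple(test)))
    return folds


def _blocks_to_ranges(blocks: np.ndarray, k: int) -> list[tuple[int, int]]:
    ranges: list[tuple[int, int]] = []
    for b in blocks:
        a, e = int(b) * k, (int(b) + 1) * k
        if ranges and ranges[-1][1] == a:
            ranges[-1] = (ranges[-1][0], e)
        else:
            ranges.append((a, e))
    return ranges


def _mask_to_ranges(mask: np.ndarray) -> list[tuple[int, int]]:
    ranges: list[tuple[int, int]] = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return ranges
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            ranges.append((int(start), int(prev) + 1))
            start = i
        prev = i
    ranges.append((int(start), int(prev) + 1))
    return ranges
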