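"""Raw-signal front end: band log-power features and 10 ms spike bins.

Continuous voltage traces are turned into the two observation streams the
models consume: LFP is low-passed at 400 Hz, decimated to 1 kHz,
common-average referenced, and summarized as log-power in seven canonical
frequency bands from a 300 ms causal STFT window hopped every 50 ms; spikes
are threshold crossings of the 0.3-6.6 kHz band-passed signal at
mean - 3.5 SD, binned to 10 ms binary values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .datasets import TimeBase

__all__ = [
    "ContinuousRecording",
    "BandDefinition",
    "DEFAULT_BANDS",
    "extract_lfp",
    "band_log_power",
    "detect_spikes",
    "bin_spike_events",
]


@dataclass
class ContinuousRecording:
    """Multichannel continuous voltage trace."""

    samples: np.ndarray   # (n_channels, n_samples)
    fs: float             # Hz

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float    # Hz
    high: float   # Hz

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"band {self.name}: need 0 < low < high")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4, 8),
    BandDefinition("alpha", 8, 12),
    BandDefinition("beta1", 12, 24),
    BandDefinition("beta2", 24, 34),
    BandDefinition("gamma1", 34, 55),
    BandDefinition("gamma2", 65, 95),
    BandDefinition("gamma3", 130, 170),
)


def extract_lfp(raw: ContinuousRecording, *, cutoff: float = 400.0,
                out_fs: float = 1000.0) -> ContinuousRecording:
    """Low-pass the raw signal at 400 Hz and decimate to 1 kHz.

    Zero-phase 4th-order Butterworth, applied forward-backward.
    """
    if raw.fs < out_fs:
        raise ValueError(f"fs={raw.fs} below output rate {out_fs}")
    sos = signal.butter(4, cutoff, btype="low", fs=raw.fs, output="sos")
    filt = signal.sosfiltfilt(sos, raw.samples, axis=1)
    step = raw.fs / out_fs
    idx = np.round(np.arange(0, raw.samples.shape[1], step)).astype(int)
    idx = idx[idx < raw.samples.shape[1]]
    return ContinuousRecording(samples=filt[:, idx], fs=out_fs)


def band_log_power(lfp1k: ContinuousRecording,
                   bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
                   timebase: TimeBase | None = None, *,
                   window_s: float = 0.3, hop_s: float = 0.05,
                   ) -> tuple[np.ndarray, list[str], list[str]]:
    """Band log-power features from a 1 kHz LFP recording.

    Common-average reference across channels (a no-op for one channel), then
    a Hann-tapered short-time Fourier transform on 300 ms causal windows
    hopped every 50 ms; per-band power is summed over in-band frequency
    bins and log-transformed.  The first windows, which would start before
    the recording, use the available causal samples zero-padded on the left.

    Returns ``(features, feature_channel_ids, feature_band_labels)`` with
    features ordered channel-major, band-minor; row m corresponds to the
    causal window ending at time (m+1)*hop.
    """
    fs = lfp1k.fs
    x = lfp1k.samples
    nwin = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    n_ch, n_samp = x.shape
    if n_samp < nwin:
        raise ValueError(f"signal shorter ({n_samp}) than window ({nwin})")
    for b in bands:
        if b.high >= fs / 2:
            raise ValueError(f"band {b.name} upper edge {b.high} >= Nyquist")
    if n_ch > 1:
        x = x - x.mean(axis=0, keepdims=True)

    taper = np.hanning(nwin)
    freqs = np.fft.rfftfreq(nwin, d=1.0 / fs)
    band_bins = [np.flatnonzero((freqs >= b.low) & (freqs <= b.high))
                 for b in bands]
    n_steps = n_samp // hop
    feats = np.empty((n_steps, n_ch * len(bands)))
    for m in range(n_steps):
        end = (m + 1) * hop
        start = end - nwin
        if start < 0:
            seg = np.zeros((n_ch, nwin))
            seg[:, -end:] = x[:, :end]
        else:
            seg = x[:, start:end]
        spec = np.fft.rfft(seg * taper, axis=1)
        power = np.abs(spec) ** 2
        for bi, bins in enumerate(band_bins):
            feats[m, bi::len(bands)] = np.log(power[:, bins].sum(axis=1) + 1e-300)
    chan_ids = [f"l{c}" for c in range(n_ch) for _ in bands]
    band_labels = [b.name for _ in range(n_ch) for b in bands]
    return feats, chan_ids, band_labels


def detect_spikes(raw: ContinuousRecording, timebase: TimeBase, *,
                  band: tuple[float, float] = (300.0, 6600.0),
                  threshold_sd: float = 3.5,
                  robust: bool = False) -> np.ndarray:
    """Threshold-crossing spike detection binned to binary 10 ms values.

    The raw trace is band-passed (0.3-6.6 kHz, zero-phase 4th-order
    Butterworth); an event is a downward crossing of mean - 3.5 SD of the
    filtered trace.  With ``robust=True`` the center/scale are median/MAD.
    Invariant to DC offsets by construction.
    """
    if raw.fs < 10_000:
        raise ValueError(f"fs={raw.fs} too low for spike detection (need >= 10 kHz)")
    hi = min(band[1], 0.999 * raw.fs / 2)
    sos = signal.butter(4, (band[0], hi), btype="band", fs=raw.fs, output="sos")
    filt = signal.sosfiltfilt(sos, raw.samples, axis=1)
    n_ch = filt.shape[0]
    T = timebase.T
    out = np.zeros((T, n_ch), dtype=np.uint8)
    for c in range(n_ch):
        tr = filt[c]
        if robust:
            center = np.median(tr)
            scale = 1.4826 * np.median(np.abs(tr - center))
        else:
            center, scale = tr.mean(), tr.std()
        thresh = center - threshold_sd * scale
        below = tr < thresh
        crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
        times = crossings / raw.fs
        times = times[times < T * timebase.dt]
        out[:, c] = np.maximum(out[:, c], bin_spike_events(times, timebase))
    return out


def bin_spike_events(event_times, timebase: TimeBase) -> np.ndarray:
    """Bin event times (seconds) into half-open 10 ms bins [t*dt, (t+1)*dt),
    with a 1 marking any bin containing at least one event."""
    t = np.asarray(event_times, dtype=float)
    out = np.zeros(timebase.T, dtype=np.uint8)
    if t.size == 0:
        return out
    if t.min() < 0 or t.max() >= timebase.T * timebase.dt:
        raise ValueError("event time outside [0, T*dt)")
    idx = np.floor(t / timebase.dt).astype(int)
    out[idx] = 1
    return out
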