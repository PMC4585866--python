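"""Cochleogram front-end: waveform -> time-frequency predictor grid.

Stimuli enter the decision model as cochleograms binned at 15.6 ms in
time and 54 logarithmically spaced channels between 96 and 7760 Hz.
The front-end here is a constant-Q bank of second-order resonant
bandpass filters (quality factor Q = 8, i.e. -3 dB bandwidth f/8),
followed by half-wave rectification, low-pass envelope smoothing and
power-law amplitude compression — a standard functional cochlea
approximation.  The estimation machinery downstream only depends on
the binning grid, which is what this module guarantees.

For a 680 ms stimulus the default grid is 43 frames x 54 channels
(floor(0.680 / 0.0156) = 43); partial trailing frames are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class CochleogramConfig:
    sample_rate: int = 48_000
    n_channels: int = 54
    f_min: float = 96.0
    f_max: float = 7760.0
    quality_factor: float = 8.0
    # channel overlap of the original cochlea model; recorded but not
    # interpreted by this front-end
    overlap: float = 0.40
    time_bin: float = 0.0156
    smoothing_hz: float = 64.0
    compression_exponent: float = 0.3


@dataclass(frozen=True)
class Filterbank:
    config: CochleogramConfig
    center_freqs: np.ndarray
    ba: tuple  # per-channel (b, a) bandpass coefficients
    smoother: tuple  # (b, a) of the envelope low-pass


@dataclass(frozen=True)
class Cochleogram:
    """n_time x n_freq nonnegative energy matrix with its grid metadata."""

    values: np.ndarray
    time_bin: float
    center_freqs: np.ndarray
    source_ref: str = ""

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def n_freq(self) -> int:
        return self.values.shape[1]


def make_filterbank(config: CochleogramConfig | None = None) -> Filterbank:
    """Constant-Q resonator bank on geometrically spaced center frequencies."""
    cfg = config or CochleogramConfig()
    nyq = cfg.sample_rate / 2
    if cfg.f_max >= nyq:
        raise ValueError(
            f"top channel {cfg.f_max} Hz at or above Nyquist ({nyq} Hz)")
    if not (0 < cfg.f_min < cfg.f_max):
        raise ValueError("need 0 < f_min < f_max")
    cfs = np.geomspace(cfg.f_min, cfg.f_max, cfg.n_channels)
    ba = tuple(signal.iirpeak(f, cfg.quality_factor, fs=cfg.sample_rate)
               for f in cfs)
    smoother = signal.butter(2, cfg.smoothing_hz, fs=cfg.sample_rate)
    return Filterbank(config=cfg, center_freqs=cfs, ba=ba, smoother=smoother)


def compute_cochleogram(waveform: np.ndarray, filterbank: Filterbank,
                        config: CochleogramConfig | None = None,
                        source_ref: str = "") -> Cochleogram:
    """Filter, rectify, smooth, compress, and bin a waveform.

    Deterministic: identical waveforms give bit-identical cochleograms.
    Frame count is floor(duration / time_bin); trailing samples beyond
    the last full frame are discarded.
    """
    cfg = config or filterbank.config
    x = np.asarray(waveform, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty waveform")
    fs = cfg.sample_rate
    n_frames = int(np.floor(len(x) / fs / cfg.time_bin))
    if n_frames < 1:
        raise ValueError("waveform shorter than one analysis frame")
    edges = np.floor(np.arange(n_frames + 1) * cfg.time_bin * fs).astype(int)
    bs, as_ = filterbank.smoother
    values = np.empty((n_frames, len(filterbank.center_freqs)))
    for ch, (b, a) in enumerate(filterbank.ba):
        y = signal.lfilter(b, a, x)
        env = signal.lfilter(bs, as_, np.maximum(y, 0.0))
        env = np.power(np.maximum(env, 0.0), cfg.compression_exponent)
        csum = np.concatenate([[0.0], np.cumsum(env)])
        values[:, ch] = (csum[edges[1:]] - csum[edges[:-1]]) / np.diff(edges)
    return Cochleogram(values=values, time_bin=cfg.time_bin,
                       center_freqs=filterbank.center_freqs,
                       source_ref=source_ref)


def vectorize(cochleogram: Cochleogram) -> np.ndarray:
    """Row-major (time-major) flattening: pixel (t, f) -> index t*n_freq + f."""
    return cochleogram.values.ravel()


def devectorize(pixel_vector: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    return np.asarray(pixel_vector).reshape(grid_shape)
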