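"""Synthesis and mixing of VCCV targets and white-noise maskers.

The listening task is a /da/ vs /ga/ categorization of VCCV non-words
(e.g. /alda/, /alga/) embedded in Gaussian white noise.  The phonetic
contrast lives in the second-syllable formant-transition onsets: /da/
has widely separated F2/F3 onsets, /ga/ has F2 and F3 converging onto a
common locus near 2 kHz.  Because the original recordings are not part
of this package, targets are produced by a parametric source-filter
synthesizer (pulse-train glottal source through time-varying resonant
formant filters) that honors the printed timing: 680 ms total duration
and a second-syllable energy onset at exactly 328 ms, identical across
all four targets.

All waveforms handled here are RMS-normalized; a stimulus at SNR s (dB)
is ``gamma * (target + lambda * noise)`` with ``lambda = 10**(-s/20)``
and ``gamma`` restoring unit RMS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.io import wavfile

CONSONANT_LABELS = ("da", "ga")
CONTEXT_LABELS = ("l", "r-fricative")

DEFAULT_SAMPLE_RATE = 48_000
DEFAULT_DURATION = 0.680
DEFAULT_SYLLABLE2_ONSET = 0.328


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x, dtype=np.float64))))


def rms_normalize(x: np.ndarray) -> np.ndarray:
    r = _rms(x)
    if r == 0.0:
        raise ValueError("cannot RMS-normalize an all-zero signal")
    return np.asarray(x, dtype=np.float64) / r


@dataclass(frozen=True)
class TargetSignal:
    """One VCCV target waveform with its timing metadata."""

    samples: np.ndarray
    sample_rate: int
    consonant_label: str
    context_label: str
    syllable2_onset: float
    duration: float

    def __post_init__(self):
        n = len(self.samples)
        if abs(self.duration - n / self.sample_rate) > 1e-9:
            raise ValueError("duration inconsistent with sample count")
        if not (0.0 < self.syllable2_onset < self.duration):
            raise ValueError("syllable2_onset must lie inside the stimulus")

    @property
    def target_id(self) -> str:
        return f"a{self.context_label[0]}{self.consonant_label}"

    @property
    def response_class(self) -> int:
        """0 for /da/, 1 for /ga/ (the response coding of the task)."""
        return CONSONANT_LABELS.index(self.consonant_label)


@dataclass(frozen=True)
class NoiseSignal:
    """A stored white-noise masker, reproducible from its seed."""

    samples: np.ndarray
    seed: int
    index: int = 0


@dataclass(frozen=True)
class StimulusMix:
    samples: np.ndarray
    snr_db: float
    noise_scale: float
    power_norm: float
    target_ref: str
    noise_ref: int
    analysis_start: int = 0  # sample index where the analysis window begins


@dataclass(frozen=True)
class TimingConfig:
    """Segment layout of the VCCV token (seconds)."""

    duration: float = DEFAULT_DURATION
    syllable2_onset: float = DEFAULT_SYLLABLE2_ONSET
    vowel1_end: float = 0.230
    closure_start: float = 0.278  # stop closure: silence until syllable-2 onset
    transition_dur: float = 0.080  # CV formant transition length
    f0: float = 120.0  # glottal source fundamental


# Formant trajectories (Hz).  Vowel /a/ steady-state targets are shared;
# the consonant onsets encode the /da/-/ga/ contrast: distant F2/F3
# onsets for /da/, close (velar-locus) onsets for /ga/.
VOWEL_A = (700.0, 1200.0, 2500.0)
CONSONANT_ONSETS = {
    "da": (650.0, 1400.0, 2550.0),
    "ga": (650.0, 1900.0, 2100.0),
}
CONTEXT_FORMANTS = {
    "l": (350.0, 1050.0, 2800.0),
    "r-fricative": (500.0, 1100.0, 2300.0),
}


def formant_onsets(consonant_label: str) -> tuple[float, float, float]:
    """F1/F2/F3 onset frequencies of the second-syllable transition."""
    if consonant_label not in CONSONANT_LABELS:
        raise ValueError(f"unknown consonant label {consonant_label!r}")
    return CONSONANT_ONSETS[consonant_label]


def _resonator_filter(x: np.ndarray, freqs: np.ndarray, bw: float, fs: int,
                      block: int = 64) -> np.ndarray:
    """Filter through a time-varying two-pole resonator.

    ``freqs`` gives the per-sample center frequency; coefficients are
    updated block-wise with filter state carried across blocks.
    """
    y = np.empty_like(x)
    zi = np.zeros(2)
    for start in range(0, len(x), block):
        stop = min(start + block, len(x))
        f = float(freqs[(start + stop) // 2])
        r = np.exp(-np.pi * bw / fs)
        theta = 2 * np.pi * f / fs
        a = np.array([1.0, -2 * r * np.cos(theta), r * r])
        b = np.array([1.0 - r])
        y[start:stop], zi = signal.lfilter(b, a, x[start:stop], zi=zi)
    return y


def _voiced_segment(n: int, trajectories: np.ndarray, f0: float, fs: int,
                    attack: float = 0.005, release: float = 0.02) -> np.ndarray:
    """Synthesize one voiced segment: pulse train through 3 formant resonators.

    A glottal pulse is placed at the very first sample so the segment's
    energy onset coincides with its start.
    """
    src = np.zeros(n)
    period = max(1, int(round(fs / f0)))
    src[::period] = 1.0
    # mild spectral tilt: integrate pulses into decaying exponentials
    src = signal.lfilter([1.0], [1.0, -0.97], src)
    out = np.zeros(n)
    for k, bw in enumerate((90.0, 110.0, 170.0)):
        out += _resonator_filter(src, trajectories[k], bw, fs)
    env = np.ones(n)
    na = min(n, int(attack * fs))
    nr = min(n, int(release * fs))
    if na > 0:
        env[:na] = np.arange(1, na + 1) / na
    if nr > 0:
        env[-nr:] *= np.linspace(1.0, 0.0, nr)
    return out * env


def synthesize_vccv(consonant_label: str, context_label: str,
                    timing_config: TimingConfig | None = None,
                    seed: int = 0,
                    sample_rate: int = DEFAULT_SAMPLE_RATE) -> TargetSignal:
    """Synthesize one VCCV target (e.g. /alda/) as a TargetSignal.

    Deterministic given (labels, timing_config, seed); the seed only
    drives the fricative aspiration noise of the r-context.
    """
    if consonant_label not in CONSONANT_LABELS:
        raise ValueError(f"unknown consonant label {consonant_label!r}")
    if context_label not in CONTEXT_LABELS:
        raise ValueError(f"unknown context label {context_label!r}")
    tc = timing_config or TimingConfig()
    fs = sample_rate
    nyq = fs / 2
    onset_freqs = CONSONANT_ONSETS[consonant_label]
    for f in (*VOWEL_A, *onset_freqs, *CONTEXT_FORMANTS[context_label]):
        if f >= nyq:
            raise ValueError(f"formant frequency {f} Hz at or above Nyquist")

    n_total = int(round(tc.duration * fs))
    x = np.zeros(n_total)
    rng = np.random.default_rng(seed)

    def place(seg: np.ndarray, t0: float):
        i0 = int(round(t0 * fs))
        x[i0:i0 + len(seg)] += seg[:max(0, n_total - i0)]

    # syllable 1: vowel /a/ then the context consonant, then closure silence
    n_v1 = int(round(tc.vowel1_end * fs))
    traj = np.tile(np.array(VOWEL_A)[:, None], (1, n_v1))
    place(_voiced_segment(n_v1, traj, tc.f0, fs), 0.0)

    n_c1 = int(round((tc.closure_start - tc.vowel1_end) * fs))
    ctx = CONTEXT_FORMANTS[context_label]
    traj = np.tile(np.array(ctx)[:, None], (1, n_c1))
    c1 = 0.4 * _voiced_segment(n_c1, traj, tc.f0, fs)
    if context_label == "r-fricative":
        # uvular fricative: add filtered aspiration noise to the voicing
        noise = rng.standard_normal(n_c1)
        c1 += 0.15 * _resonator_filter(noise, np.full(n_c1, ctx[1]), 400.0, fs)
    place(c1, tc.vowel1_end)

    # syllable 2: transition from consonant onset into /a/, then steady vowel
    n_s2 = n_total - int(round(tc.syllable2_onset * fs))
    n_tr = int(round(tc.transition_dur * fs))
    traj = np.empty((3, n_s2))
    for k in range(3):
        traj[k, :n_tr] = np.linspace(onset_freqs[k], VOWEL_A[k], n_tr)
        traj[k, n_tr:] = VOWEL_A[k]
    s2 = _voiced_segment(n_s2, traj, tc.f0, fs, release=0.04)
    place(s2, tc.syllable2_onset)

    return TargetSignal(
        samples=rms_normalize(x),
        sample_rate=fs,
        consonant_label=consonant_label,
        context_label=context_label,
        syllable2_onset=tc.syllable2_onset,
        duration=n_total / fs,
    )


def default_targets(sample_rate: int = DEFAULT_SAMPLE_RATE,
                    timing_config: TimingConfig | None = None,
                    seed: int = 0) -> list[TargetSignal]:
    """The four task targets: /alda/, /alga/ and their r-context twins."""
    return [
        synthesize_vccv(cons, ctx, timing_config, seed, sample_rate)
        for ctx in CONTEXT_LABELS for cons in CONSONANT_LABELS
    ]


def measure_syllable2_onset(target: TargetSignal,
                            rel_threshold: float = 1e-7) -> float:
    """Locate the second-syllable energy onset from the waveform itself.

    Finds the end of the stop-closure silence — the last silent gap of at
    least 10 ms — and returns the time of the first sample after it whose
    amplitude exceeds ``rel_threshold`` times the waveform maximum.  The
    closure is true silence, so the tiny threshold pins the onset to the
    first sample carrying second-syllable energy.
    """
    x = np.abs(target.samples)
    active = x > rel_threshold * x.max()
    idx = np.flatnonzero(active)
    gaps = np.diff(idx)
    min_gap = int(0.010 * target.sample_rate)
    big = np.flatnonzero(gaps >= min_gap)
    if len(big) == 0:
        raise ValueError("no inter-syllable silence found")
    return idx[big[-1] + 1] / target.sample_rate


def generate_noise(n_samples: int, seed: int, index: int = 0) -> NoiseSignal:
    """One white Gaussian masker, RMS-normalized, reproducible from its seed."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng([seed, index])
    return NoiseSignal(rms_normalize(rng.standard_normal(n_samples)),
                       seed=seed, index=index)


@dataclass(frozen=True)
class FadeConfig:
    """Leading noise-only ramp for listener comfort (excluded from analysis)."""

    duration: float = 0.050


def mix_at_snr(target: TargetSignal, noise: NoiseSignal, snr_db: float,
               fade_config: FadeConfig | None = None) -> StimulusMix:
    """Mix an RMS-normalized target and noise at the requested broadband SNR.

    Returns ``gamma * (t + lambda * n)`` with ``lambda = 10**(-snr_db/20)``
    and gamma the power-normalization factor restoring unit RMS over the
    analysis window.  An optional noise fade-in is prepended and flagged
    via ``analysis_start``.
    """
    t, n = target.samples, noise.samples
    if len(t) != len(n):
        raise ValueError("target and noise lengths differ")
    lam = 10.0 ** (-snr_db / 20.0)
    core = t + lam * n
    gamma = 1.0 / _rms(core)
    core = gamma * core
    offset = 0
    if fade_config is not None and fade_config.duration > 0:
        n_fade = int(round(fade_config.duration * target.sample_rate))
        rng = np.random.default_rng([noise.seed, noise.index, 1])
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_fade) / n_fade))
        fade = gamma * lam * ramp * rng.standard_normal(n_fade)
        core = np.concatenate([fade, core])
        offset = n_fade
    return StimulusMix(samples=core, snr_db=float(snr_db), noise_scale=lam,
                       power_norm=gamma, target_ref=target.target_id,
                       noise_ref=noise.seed, analysis_start=offset)


def save_wav(path, samples: np.ndarray, sample_rate: int) -> None:
    """Write a waveform as 16-bit PCM WAV, scaled to 90% full scale."""
    peak = np.max(np.abs(samples))
    if peak == 0:
        raise ValueError("refusing to write an all-zero waveform")
    pcm = np.round(samples / peak * 0.9 * 32767).astype(np.int16)
    wavfile.write(path, sample_rate, pcm)


def load_wav(path, consonant_label: str = "da", context_label: str = "l",
             syllable2_onset: float = DEFAULT_SYLLABLE2_ONSET) -> TargetSignal:
    """Read a PCM WAV target; samples are RMS-normalized on load."""
    fs, data = wavfile.read(path)
    data = np.asarray(data, dtype=np.float64)
    if data.ndim > 1:
        data = data.mean(axis=1)
    return TargetSignal(samples=rms_normalize(data), sample_rate=int(fs),
                        consonant_label=consonant_label,
                        context_label=context_label,
                        syllable2_onset=syllable2_onset,
                        duration=len(data) / fs)
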