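"""Auditory front-end: pre-emphasis, framing, Hamming windowing, STFT power
spectrum and log mel-filterbank energies.

The front-end converts a mono audio clip into a ``frames x n_filters`` matrix
of log mel energies, mimicking the cochlear stage of an MFCC pipeline but
stopping at the filterbank outputs (no cepstral/DCT step). Triangular filters
are spaced uniformly on the mel scale ``mel(f) = 2595 * log10(1 + f/700)``
and the filterbank outputs are log-compressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.io import wavfile


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AudioClip:
    """A mono audio clip.

    Parameters
    ----------
    samples : np.ndarray
        1-D float array of amplitudes (dimensionless).
    sample_rate : int
        Sampling rate in Hz, > 0.
    label : int, optional
        Class id, if the clip belongs to a labeled dataset.
    """

    samples: np.ndarray
    sample_rate: int
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError(
                f"AudioClip requires mono (1-D) samples, got shape {self.samples.shape}"
            )
        if self.samples.size == 0:
            raise ValueError("AudioClip requires a non-empty sample array")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.samples.size / self.sample_rate


@dataclass
class FrontendConfig:
    """Configuration of the auditory front-end.

    Defaults follow the environmental-sound profile (100 ms frames with 50 ms
    shift, 20 filters over 200-8000 Hz); :func:`tidigits_profile` gives the
    speech profile (25 ms frames, 15 ms shift, 200-10000 Hz).
    """

    preemphasis_alpha: float = 0.97
    frame_length_ms: float = 100.0
    frame_shift_ms: float = 50.0
    n_fft: Optional[int] = None        # next power of two >= frame length if None
    n_filters: int = 20
    fmin_hz: float = 200.0
    fmax_hz: float = 8000.0
    log_floor: float = 1e-10
    unit_peak: bool = True             # unit peak height (else area-normalized)

    def __post_init__(self) -> None:
        if not 0.0 <= self.preemphasis_alpha < 1.0:
            raise ValueError("preemphasis_alpha must lie in [0, 1)")
        if self.frame_shift_ms > self.frame_length_ms:
            raise ValueError("frame_shift_ms must not exceed frame_length_ms")
        if self.n_filters < 1:
            raise ValueError("n_filters must be >= 1")
        if not 0.0 < self.fmin_hz < self.fmax_hz:
            raise ValueError("need 0 < fmin_hz < fmax_hz")
        if self.log_floor <= 0.0:
            raise ValueError("log_floor must be positive")

    def frame_length_samples(self, sample_rate: int) -> int:
        return int(round(self.frame_length_ms * sample_rate / 1000.0))

    def frame_shift_samples(self, sample_rate: int) -> int:
        return int(round(self.frame_shift_ms * sample_rate / 1000.0))

    def fft_size(self, sample_rate: int) -> int:
        if self.n_fft is not None:
            return self.n_fft
        n = self.frame_length_samples(sample_rate)
        return 1 << max(0, (n - 1).bit_length())


def rwcp_profile() -> FrontendConfig:
    """Environmental-sound profile: 100/50 ms frames, 200-8000 Hz."""
    return FrontendConfig()


def tidigits_profile() -> FrontendConfig:
    """Spoken-digit profile: 25 ms frames with 15 ms shift, 200-10000 Hz."""
    return FrontendConfig(frame_length_ms=25.0, frame_shift_ms=15.0,
                          fmax_hz=10000.0)


@dataclass
class FeatureMatrix:
    """Per-clip log mel energies, ``frames x n_filters``."""

    values: np.ndarray
    frame_shift_ms: float
    source_duration_ms: float
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("FeatureMatrix values must be 2-D (frames x filters)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FeatureMatrix values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_filters(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# WAV I/O
# ---------------------------------------------------------------------------

def read_wav(path, label: Optional[int] = None) -> AudioClip:
    """Read a mono WAV file (integer PCM or float) into an AudioClip.

    Integer PCM is rescaled to [-1, 1); multi-channel input is rejected.
    """
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(
            f"{path}: expected mono WAV, got {data.shape[1]} channels"
        )
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    return AudioClip(samples=samples, sample_rate=int(rate), label=label)


def write_wav(path, clip: AudioClip) -> None:
    """Write an AudioClip as 16-bit PCM WAV."""
    x = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(path, clip.sample_rate, (x * 32767.0).astype(np.int16))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def preemphasize(clip: AudioClip, alpha: float) -> AudioClip:
    """First-order high-pass filter y[n] = x[n] - alpha * x[n-1], y[0] = x[0]."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must lie in [0, 1)")
    x = clip.samples
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - alpha * x[:-1]
    return AudioClip(samples=y, sample_rate=clip.sample_rate, label=clip.label)


def n_frames_for(n_samples: int, frame_len: int, frame_step: int) -> int:
    """Number of full frames; the last partial frame is dropped."""
    if n_samples < frame_len:
        return 0
    return (n_samples - frame_len) // frame_step + 1


def frame_and_window(clip: AudioClip, cfg: FrontendConfig) -> np.ndarray:
    """Slice the clip into overlapping frames and apply a Hamming window.

    Returns a ``n_frames x frame_len`` matrix. Raises if the clip is shorter
    than one frame.
    """
    frame_len = cfg.frame_length_samples(clip.sample_rate)
    frame_step = cfg.frame_shift_samples(clip.sample_rate)
    n = clip.samples.size
    if n < frame_len:
        raise ValueError(
            f"clip of {n} samples is shorter than one frame "
            f"({frame_len} samples = {cfg.frame_length_ms} ms at {clip.sample_rate} Hz)"
        )
    count = n_frames_for(n, frame_len, frame_step)
    idx = np.arange(frame_len)[None, :] + frame_step * np.arange(count)[:, None]
    window = np.hamming(frame_len)
    return clip.samples[idx] * window[None, :]


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(cfg: FrontendConfig, sample_rate: int) -> np.ndarray:
    """Triangular mel filterbank, ``n_filters x (n_fft/2 + 1)``.

    Filter centers are equally spaced on the mel scale between fmin and fmax;
    each triangle spans from the previous center to the next. By default each
    filter has unit peak height; with ``unit_peak=False`` filters are scaled
    to unit area (sum over bins).
    """
    nyquist = sample_rate / 2.0
    if cfg.fmax_hz > nyquist:
        raise ValueError(
            f"fmax_hz={cfg.fmax_hz} exceeds Nyquist frequency {nyquist}"
        )
    n_fft = cfg.fft_size(sample_rate)
    n_bins = n_fft // 2 + 1
    # n_filters + 2 edge points uniform in mel; centers are the interior points
    mel_pts = np.linspace(hz_to_mel(cfg.fmin_hz), hz_to_mel(cfg.fmax_hz),
                          cfg.n_filters + 2)
    hz_pts = mel_to_hz(mel_pts)
    freqs = np.arange(n_bins) * (sample_rate / n_fft)
    fb = np.zeros((cfg.n_filters, n_bins))
    for i in range(cfg.n_filters):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        rising = (freqs - lo) / (ctr - lo)
        falling = (hi - freqs) / (hi - ctr)
        fb[i] = np.maximum(0.0, np.minimum(rising, falling))
        if not cfg.unit_peak:
            area = fb[i].sum()
            if area > 0:
                fb[i] /= area
    return fb


def filterbank_centers_hz(cfg: FrontendConfig) -> np.ndarray:
    """Center frequencies (Hz) of the triangular filters."""
    mel_pts = np.linspace(hz_to_mel(cfg.fmin_hz), hz_to_mel(cfg.fmax_hz),
                          cfg.n_filters + 2)
    return mel_to_hz(mel_pts[1:-1])


def extract_features(clip: AudioClip, cfg: FrontendConfig) -> FeatureMatrix:
    """Full front-end: pre-emphasis, framing + Hamming window, power spectrum,
    mel filterbank projection and log compression."""
    emphasized = preemphasize(clip, cfg.preemphasis_alpha)
    frames = frame_and_window(emphasized, cfg)
    n_fft = cfg.fft_size(clip.sample_rate)
    spectrum = np.fft.rfft(frames, n=n_fft, axis=1)
    power = np.abs(spectrum) ** 2
    fb = mel_filterbank(cfg, clip.sample_rate)
    energies = power @ fb.T
    values = np.log(energies + cfg.log_floor)
    return FeatureMatrix(
        values=values,
        frame_shift_ms=cfg.frame_shift_ms,
        source_duration_ms=clip.duration_ms,
        label=clip.label,
    )
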