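"""Noise corruption: additive background noise at fixed SNR, multi-condition
dataset construction, and neuronal noise (spike jitter and deletion).

SNR is defined on sample energies, ``10 * log10(E_signal / E_noise)`` with
``E = sum(x^2)``; a seeded random contiguous segment of the noise recording
is scaled to reach the requested level and added to the clean clip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .frontend import AudioClip
from .som import SpikePattern


@dataclass
class NoiseMixConfig:
    """Multi-condition corpus construction settings."""

    snr_levels_db: Sequence[float] = (20.0, 10.0, 0.0, -5.0)
    seed: int = 0
    include_clean: bool = True

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.snr_levels_db)):
            raise ValueError("snr_levels_db must be finite")


@dataclass
class SpikeNoiseConfig:
    """Neuronal-noise settings. ``jitter_sigma_fraction`` is the jitter std
    as a fraction of the spike generation period T (swept 0.1-0.8 in the
    robustness experiments)."""

    jitter_sigma_fraction: float = 0.0
    deletion_ratio: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sigma_fraction < 0:
            raise ValueError("jitter_sigma_fraction must be >= 0")
        if not 0.0 <= self.deletion_ratio <= 1.0:
            raise ValueError("deletion_ratio must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Environmental noise
# ---------------------------------------------------------------------------

def mix_at_snr(signal: AudioClip, noise: AudioClip, snr_db: float,
               seed: Optional[int] = None,
               rng: Optional[np.random.Generator] = None) -> AudioClip:
    """Add a random noise segment to the signal at the requested SNR.

    A contiguous segment of the noise clip with the signal's length is drawn
    (seeded) and scaled by ``g = sqrt(E_s / (E_n * 10^(snr_db/10)))`` so that
    the scaled-noise energy sits exactly ``snr_db`` below the signal energy.
    """
    if noise.sample_rate != signal.sample_rate:
        raise ValueError(
            f"sample-rate mismatch: signal {signal.sample_rate} Hz, "
            f"noise {noise.sample_rate} Hz"
        )
    n = signal.samples.size
    if noise.samples.size < n:
        raise ValueError(
            f"noise clip ({noise.samples.size} samples) shorter than the "
            f"signal ({n} samples)"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    start = int(rng.integers(0, noise.samples.size - n + 1))
    segment = noise.samples[start:start + n]
    e_s = float(np.sum(signal.samples ** 2))
    e_n = float(np.sum(segment ** 2))
    if e_n == 0.0:
        raise ValueError("selected noise segment has zero energy")
    gain = np.sqrt(e_s / (e_n * 10.0 ** (snr_db / 10.0)))
    return AudioClip(samples=signal.samples + gain * segment,
                     sample_rate=signal.sample_rate, label=signal.label)


def measure_snr_db(signal: AudioClip, mixed: AudioClip) -> float:
    """SNR implied by a clean/mixed pair (mixed - clean is the added noise)."""
    added = mixed.samples - signal.samples
    return 10.0 * np.log10(np.sum(signal.samples ** 2) / np.sum(added ** 2))


def build_multicondition_set(clean: Sequence[AudioClip], noise: AudioClip,
                             cfg: NoiseMixConfig) -> List[AudioClip]:
    """Clean clips (optionally) plus one noise-mixed copy per clip per SNR
    level; labels preserved, deterministic under the config seed."""
    if not clean:
        raise ValueError("build_multicondition_set requires a non-empty clean set")
    rng = np.random.default_rng(cfg.seed)
    out: List[AudioClip] = []
    if cfg.include_clean:
        out.extend(clean)
    for snr in cfg.snr_levels_db:
        for clip in clean:
            out.append(mix_at_snr(clip, noise, snr, rng=rng))
    return out


# ---------------------------------------------------------------------------
# Neuronal noise
# ---------------------------------------------------------------------------

def jitter_spikes(pattern: SpikePattern, sigma_ms: float,
                  seed: Optional[int] = None) -> SpikePattern:
    """Add zero-mean Gaussian noise (std sigma_ms) to every spike time.

    Times are clipped to [0, duration] so no event is lost; events are
    re-sorted afterwards. ``sigma_ms = 0`` returns an identical pattern.
    """
    if sigma_ms < 0:
        raise ValueError("sigma_ms must be >= 0")
    if sigma_ms == 0.0:
        return SpikePattern(events=list(pattern.events),
                            duration_ms=pattern.duration_ms,
                            n_units=pattern.n_units, label=pattern.label)
    rng = np.random.default_rng(seed)
    times = pattern.time_array() + rng.normal(0.0, sigma_ms, pattern.n_events)
    times = np.clip(times, 0.0, pattern.duration_ms)
    units = pattern.unit_array()
    order = np.argsort(times, kind="stable")
    events = [(int(units[i]), float(times[i])) for i in order]
    return SpikePattern(events=events, duration_ms=pattern.duration_ms,
                        n_units=pattern.n_units, label=pattern.label)


def delete_spikes(pattern: SpikePattern, ratio: float,
                  seed: Optional[int] = None,
                  exact_count: bool = False) -> SpikePattern:
    """Remove spikes at a given rate, preserving order and duration.

    By default each event is dropped independently with probability ``ratio``
    (i.i.d. Bernoulli); with ``exact_count=True`` a uniformly random subset
    of exactly ``round(ratio * n_events)`` events is removed instead.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = pattern.n_events
    if exact_count:
        n_del = int(round(ratio * n))
        drop = np.zeros(n, dtype=bool)
        drop[rng.choice(n, size=n_del, replace=False)] = True
    else:
        drop = rng.random(n) < ratio
    events = [ev for ev, d in zip(pattern.events, drop) if not d]
    return SpikePattern(events=events, duration_ms=pattern.duration_ms,
                        n_units=pattern.n_units, label=pattern.label)
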