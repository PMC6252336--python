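"""Synthetic datasets: isolated sound events with class-specific spectral
trajectories, babble-like background noise, and synthetic spike patterns.

The sound generator emulates short (default 0.5-1.0 s) isolated events from a
handful of classes, each defined by a set of linearly swept partials with an
attack/decay amplitude envelope plus a white-noise floor. The spike generator
emulates the map's output directly: per-class prototype unit sequences with
controllable time warping and unit substitution. Both are pure functions of
(spec, n, seed), so every pipeline stage is testable without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sp_signal

from .frontend import AudioClip
from .som import SpikePattern


# ---------------------------------------------------------------------------
# Sound events
# ---------------------------------------------------------------------------

@dataclass
class SoundClassSpec:
    """One sound class: partials as (start_hz, end_hz) sweeps, an envelope,
    a duration range and a relative white-noise floor."""

    class_id: int
    partials: Sequence[Tuple[float, float]]
    attack_ms: float = 20.0
    decay_ms: float = 100.0
    duration_range_ms: Tuple[float, float] = (500.0, 1000.0)
    noise_floor: float = 0.01

    def __post_init__(self) -> None:
        lo, hi = self.duration_range_ms
        if lo > hi:
            raise ValueError("duration range min must be <= max")
        for f0, f1 in self.partials:
            if f0 <= 0 or f1 <= 0:
                raise ValueError("partial frequencies must be positive")


def default_sound_specs(n_classes: int = 5,
                        duration_range_ms: Tuple[float, float] = (500.0, 1000.0),
                        noise_floor: float = 0.01) -> List[SoundClassSpec]:
    """Five archetypal event classes with well-separated spectral
    trajectories: steady harmonic tone, rising sweep, falling sweep, high
    tone cluster, and crossing sweeps. For more classes, additional steady
    multi-tone classes are appended on a mel-like progression."""
    base = [
        [(500.0, 500.0), (1000.0, 1000.0)],
        [(400.0, 3000.0)],
        [(4000.0, 800.0)],
        [(2500.0, 2500.0), (5000.0, 5000.0)],
        [(300.0, 2000.0), (2000.0, 300.0)],
    ]
    specs: List[SoundClassSpec] = []
    for c in range(n_classes):
        if c < len(base):
            partials = base[c]
        else:
            f = 600.0 * (1.3 ** (c - len(base) + 1))
            partials = [(f, f), (1.8 * f, 1.8 * f)]
        specs.append(SoundClassSpec(class_id=c, partials=partials,
                                    duration_range_ms=duration_range_ms,
                                    noise_floor=noise_floor))
    return specs


def _envelope(n: int, sample_rate: int, attack_ms: float, decay_ms: float) -> np.ndarray:
    env = np.ones(n)
    n_att = min(n, int(round(attack_ms * sample_rate / 1000.0)))
    n_dec = min(n, int(round(decay_ms * sample_rate / 1000.0)))
    if n_att > 0:
        env[:n_att] = np.linspace(0.0, 1.0, n_att)
    if n_dec > 0:
        env[n - n_dec:] = np.minimum(env[n - n_dec:], np.linspace(1.0, 0.0, n_dec))
    return env


def synthesize_event(spec: SoundClassSpec, duration_ms: float,
                     sample_rate: int, rng: np.random.Generator) -> AudioClip:
    """One event: summed linear sweeps with random initial phases, an
    attack/decay envelope and a white-noise floor; peak-normalized."""
    nyquist = sample_rate / 2.0
    for f0, f1 in spec.partials:
        if max(f0, f1) >= nyquist:
            raise ValueError(
                f"partial ({f0}, {f1}) Hz at or above Nyquist {nyquist} Hz"
            )
    n = int(round(duration_ms * sample_rate / 1000.0))
    t = np.arange(n) / sample_rate
    dur_s = n / sample_rate
    x = np.zeros(n)
    for f0, f1 in spec.partials:
        # linear sweep: phase = 2*pi*(f0*t + (f1-f0)*t^2/(2*D))
        phase = 2.0 * np.pi * (f0 * t + (f1 - f0) * t ** 2 / (2.0 * dur_s))
        x += np.sin(phase + rng.uniform(0.0, 2.0 * np.pi))
    x *= _envelope(n, sample_rate, spec.attack_ms, spec.decay_ms)
    if spec.noise_floor > 0:
        x += spec.noise_floor * rng.standard_normal(n)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.95 * x / peak
    return AudioClip(samples=x, sample_rate=sample_rate, label=spec.class_id)


def generate_sound_dataset(specs: Sequence[SoundClassSpec], n_per_class: int,
                           sample_rate: int = 16000,
                           seed: int = 0) -> List[AudioClip]:
    """n_per_class clips per class with seeded duration draws; deterministic
    per (specs, n, seed)."""
    if not specs:
        raise ValueError("generate_sound_dataset requires at least one spec")
    rng = np.random.default_rng(seed)
    clips: List[AudioClip] = []
    for spec in specs:
        lo, hi = spec.duration_range_ms
        for _ in range(n_per_class):
            duration = rng.uniform(lo, hi)
            clips.append(synthesize_event(spec, duration, sample_rate, rng))
    return clips


def babble_noise(duration_ms: float, sample_rate: int = 16000,
                 seed: int = 0, n_bands: int = 8,
                 band_range_hz: Tuple[float, float] = (100.0, 4000.0)) -> AudioClip:
    """Babble-like noise: a sum of amplitude-modulated band-limited noise
    bands, log-spaced across the band range, each modulated by a slow
    (~4 Hz) positive envelope. A stand-in for multi-talker recordings."""
    n = int(round(duration_ms * sample_rate / 1000.0))
    rng = np.random.default_rng(seed)
    edges = np.geomspace(band_range_hz[0], band_range_hz[1], n_bands + 1)
    x = np.zeros(n)
    nyquist = sample_rate / 2.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        sos = sp_signal.butter(2, [lo / nyquist, hi / nyquist],
                               btype="bandpass", output="sos")
        band = sp_signal.sosfilt(sos, rng.standard_normal(n))
        # slow positive modulation envelope
        env_sos = sp_signal.butter(2, 4.0 / nyquist, btype="lowpass",
                                   output="sos")
        env = sp_signal.sosfilt(env_sos, rng.standard_normal(n))
        env = 1.0 + env / (np.std(env) + 1e-12) * 0.5
        x += band * np.clip(env, 0.0, None)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.95 * x / peak
    return AudioClip(samples=x, sample_rate=sample_rate)


def make_sound_fixture(n_classes: int = 5, n_train: int = 20, n_test: int = 20,
                       sample_rate: int = 16000, seed: int = 0,
                       ) -> Tuple[List[AudioClip], List[AudioClip]]:
    """Default study fixture: n_classes classes, n_train + n_test clips each,
    0.5-1.0 s at 16 kHz, disjoint train/test randomness."""
    specs = default_sound_specs(n_classes)
    train = generate_sound_dataset(specs, n_train, sample_rate, seed=seed)
    test = generate_sound_dataset(specs, n_test, sample_rate, seed=seed + 10_000)
    return train, test


# ---------------------------------------------------------------------------
# Spike patterns
# ---------------------------------------------------------------------------

@dataclass
class SpikeClassSpec:
    """One spike-pattern class: a prototype unit sequence (one unit per
    frame), the frame period T, a per-frame unit substitution probability and
    a multiplicative duration-warp range."""

    class_id: int
    n_units: int
    prototype: Sequence[int]
    frame_period_ms: float = 50.0
    substitution_prob: float = 0.0
    warp_range: Tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if any(not 0 <= u < self.n_units for u in self.prototype):
            raise ValueError("prototype units must lie in [0, n_units)")
        lo, hi = self.warp_range
        if not (0 < lo <= hi):
            raise ValueError("warp range must satisfy 0 < min <= max")
        if not 0.0 <= self.substitution_prob <= 1.0:
            raise ValueError("substitution_prob must lie in [0, 1]")


def default_spike_specs(n_classes: int = 2, n_units: int = 16,
                        length: int = 20, frame_period_ms: float = 50.0,
                        substitution_prob: float = 0.0,
                        warp_range: Tuple[float, float] = (1.0, 1.0),
                        seed: int = 1234) -> List[SpikeClassSpec]:
    """Distinct random-walk prototypes, one per class, from a fixed seed.

    Each class walks within its own band of the unit range, giving the low
    intra-class / high inter-class variability the encoding stage produces
    on well-separated sound classes."""
    if n_units < n_classes:
        raise ValueError("need at least one unit per class")
    rng = np.random.default_rng(seed)
    specs = []
    for c in range(n_classes):
        lo = c * n_units // n_classes
        hi = (c + 1) * n_units // n_classes - 1
        walk = int(rng.integers(lo, hi + 1))
        proto = []
        for _ in range(length):
            walk = int(np.clip(walk + rng.integers(-2, 3), lo, hi))
            proto.append(walk)
        specs.append(SpikeClassSpec(class_id=c, n_units=n_units,
                                    prototype=proto,
                                    frame_period_ms=frame_period_ms,
                                    substitution_prob=substitution_prob,
                                    warp_range=warp_range))
    return specs


def _warp_sequence(proto: Sequence[int], factor: float) -> List[int]:
    """Resample the unit sequence to round(len * factor) frames (nearest)."""
    n_out = max(1, int(round(len(proto) * factor)))
    idx = np.minimum((np.arange(n_out) / factor).astype(int), len(proto) - 1)
    return [proto[i] for i in idx]


def generate_spike_dataset(specs: Sequence[SpikeClassSpec], n_per_class: int,
                           seed: int = 0) -> List[SpikePattern]:
    """Per sample: draw a warp factor, resample the prototype, substitute
    each unit with probability ``substitution_prob``, and emit one event per
    frame at multiples of the frame period."""
    if not specs:
        raise ValueError("generate_spike_dataset requires at least one spec")
    rng = np.random.default_rng(seed)
    patterns: List[SpikePattern] = []
    for spec in specs:
        for _ in range(n_per_class):
            factor = rng.uniform(*spec.warp_range)
            seq = _warp_sequence(list(spec.prototype), factor)
            units = []
            for u in seq:
                if spec.substitution_prob > 0 and rng.random() < spec.substitution_prob:
                    u = int(rng.integers(0, spec.n_units))
                units.append(u)
            T = spec.frame_period_ms
            events = [(u, i * T) for i, u in enumerate(units)]
            patterns.append(SpikePattern(events=events,
                                         duration_ms=len(units) * T,
                                         n_units=spec.n_units,
                                         label=spec.class_id))
    return patterns


def mean_pairwise_edit_distance(patterns: Sequence[SpikePattern]) -> float:
    """Mean Levenshtein distance between unit sequences (intra-set
    variability diagnostic)."""
    seqs = [tuple(p.unit_array()) for p in patterns]
    if len(seqs) < 2:
        return 0.0
    total, count = 0, 0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            total += _edit_distance(seqs[i], seqs[j])
            count += 1
    return total / count


def _edit_distance(a: Tuple[int, ...], b: Tuple[int, ...]) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (ca != cb))
        prev = cur
    return prev[len(b)]
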