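"""Single-layer spiking classifier: kernel LIF neurons trained with the
Maximum-Margin Tempotron rule, a ReSuMe variant, and decision/evaluation
procedures.

Each output neuron integrates input spikes through a normalized
difference-of-exponentials postsynaptic-potential kernel

    K(t - t_j) = K0 * (exp(-(t - t_j)/tau_m) - exp(-(t - t_j)/tau_s)),  t >= t_j

and fires when its membrane potential crosses threshold while rising. The
classifier is single-spike: input spikes arriving after an output spike are
shunted (ignored). Training is one-vs-all: the target neuron must exceed
``V_thr + margin`` (else LTP at the time of maximum potential), non-target
neurons must stay below ``V_thr - margin`` (else LTD at their erroneous spike
time). At test time the margin is removed and three decision rules apply: no
spike -> highest peak potential; one spike -> that class; several spikes ->
earliest spike.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .som import SpikePattern


# ---------------------------------------------------------------------------
# PSP kernel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelParams:
    """Dual-exponential PSP kernel constants.

    ``t_peak`` is where the unnormalized difference of exponentials peaks and
    ``k0`` scales the kernel so its maximum value is exactly 1.
    """

    tau_m: float
    tau_s: float
    k0: float
    t_peak: float


def make_kernel(tau_m: float, tau_s: float) -> KernelParams:
    """Closed-form normalization: t_peak = tau_m*tau_s/(tau_m - tau_s) *
    ln(tau_m/tau_s), k0 = 1/(exp(-t_peak/tau_m) - exp(-t_peak/tau_s))."""
    if not tau_m > tau_s > 0:
        raise ValueError(
            f"kernel shape requires tau_m > tau_s > 0, got tau_m={tau_m}, tau_s={tau_s}"
        )
    t_peak = tau_m * tau_s / (tau_m - tau_s) * math.log(tau_m / tau_s)
    k0 = 1.0 / (math.exp(-t_peak / tau_m) - math.exp(-t_peak / tau_s))
    return KernelParams(tau_m=tau_m, tau_s=tau_s, k0=k0, t_peak=t_peak)


def psp_kernel(params: KernelParams, t_rel) -> np.ndarray:
    """K(t_rel) for t_rel >= 0, zero otherwise (causal Heaviside gate)."""
    t = np.asarray(t_rel, dtype=np.float64)
    out = params.k0 * (np.exp(-t / params.tau_m) - np.exp(-t / params.tau_s))
    return np.where(t >= 0.0, out, 0.0)


# ---------------------------------------------------------------------------
# Neuron / config / decision types
# ---------------------------------------------------------------------------

@dataclass
class TempotronNeuron:
    weights: np.ndarray
    kernel: KernelParams
    v_thr: float = 1.0
    margin: float = 0.5
    v_rest: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if not self.v_thr > self.v_rest:
            raise ValueError("v_thr must exceed v_rest")


@dataclass
class ClassifierConfig:
    learning_rate: float = 0.005
    epochs: int = 10
    dt: float = 1.0
    weight_init_sigma: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class Decision:
    label: int
    fired: List[bool]
    decision_time_ms: float
    peak_potentials: List[float]


@dataclass
class Trace:
    """Membrane potential sampled on a uniform grid, plus the output spike
    time if the effective threshold was crossed."""

    times: np.ndarray
    v: np.ndarray
    spike_time: Optional[float]

    @property
    def fired(self) -> bool:
        return self.spike_time is not None


# ---------------------------------------------------------------------------
# Membrane dynamics
# ---------------------------------------------------------------------------

# Simulation extends past the pattern so late PSPs can still cross threshold.
POST_PATTERN_TAU_M = 3.0


def _grid(duration_ms: float, dt: float, tau_m: float) -> np.ndarray:
    t_end = duration_ms + POST_PATTERN_TAU_M * tau_m
    n = int(math.floor(t_end / dt)) + 1
    return np.arange(n) * dt


def _potential_on_grid(weights: np.ndarray, kernel: KernelParams,
                       units: np.ndarray, times: np.ndarray,
                       grid: np.ndarray, v_rest: float) -> np.ndarray:
    """V(t) = sum_j w_j sum_{t_j < t} K(t - t_j) + v_rest on the grid.

    Each exponential sum factorizes as exp(-t/tau) * cumsum(w * exp(t_j/tau)),
    giving O(E + G) work. The factored exponents stay well inside float64
    range for pattern durations up to tens of seconds.
    """
    v = np.full(grid.shape, v_rest, dtype=np.float64)
    if units.size == 0:
        return v
    w = weights[units]
    # first grid index strictly after each event (t_j < t)
    idx = np.searchsorted(grid, times, side="right")
    for tau, sign in ((kernel.tau_m, 1.0), (kernel.tau_s, -1.0)):
        contrib = np.zeros(grid.size + 1)
        np.add.at(contrib, idx, w * np.exp(times / tau))
        running = np.cumsum(contrib[:-1])
        v += sign * kernel.k0 * np.exp(-grid / tau) * running
    return v


def membrane_trace(neuron: TempotronNeuron, pattern: SpikePattern,
                   dt: float = 1.0, shunt_after_spike: bool = True,
                   effective_thr: Optional[float] = None) -> Trace:
    """Simulate the membrane potential for one input pattern.

    A spike is registered at the first grid point where ``V >= effective_thr``
    and V is rising (``V(t) > V(t - dt)``). With shunting, input events at or
    after the spike are dropped and the trace recomputed from the remaining
    events (the portion up to the spike is unchanged by construction).
    ``effective_thr=None`` (or inf) simulates without spiking.
    """
    units = pattern.unit_array()
    times = pattern.time_array()
    if units.size and units.max() >= neuron.weights.size:
        raise ValueError(
            f"pattern references unit {units.max()} but neuron has "
            f"{neuron.weights.size} inputs"
        )
    grid = _grid(pattern.duration_ms, dt, neuron.kernel.tau_m)
    v = _potential_on_grid(neuron.weights, neuron.kernel, units, times, grid,
                           neuron.v_rest)
    spike_time: Optional[float] = None
    if effective_thr is not None and np.isfinite(effective_thr):
        above = v >= effective_thr
        rising = np.zeros_like(above)
        rising[1:] = v[1:] > v[:-1]
        hits = np.nonzero(above & rising)[0]
        if hits.size:
            spike_time = float(grid[hits[0]])
            if shunt_after_spike:
                keep = times < spike_time
                v = _potential_on_grid(neuron.weights, neuron.kernel,
                                       units[keep], times[keep], grid,
                                       neuron.v_rest)
    return Trace(times=grid, v=v, spike_time=spike_time)


def find_t_max(trace: Trace) -> Tuple[float, float]:
    """Earliest grid time attaining the maximum potential. For a neuron that
    fired, the spike time is the update time (post-spike dynamics ignored)."""
    if trace.times.size == 0:
        raise ValueError("empty trace")
    if trace.fired:
        i = int(np.searchsorted(trace.times, trace.spike_time))
        return float(trace.spike_time), float(trace.v[i])
    i = int(np.argmax(trace.v))
    return float(trace.times[i]), float(trace.v[i])


def _t_max_post_onset(trace: Trace, event_times: np.ndarray) -> float:
    """Time of maximum potential for weight updates.

    If the potential never rises above rest, the earliest-maximum convention
    lands before the first input spike and any spike-sum over preceding
    events would be empty forever; in that degenerate case the maximum is
    taken over the post-onset part of the trace instead.
    """
    t_max, _ = find_t_max(trace)
    if event_times.size and not np.any(event_times < t_max):
        sel = trace.times > event_times.min()
        t_max = float(trace.times[sel][int(np.argmax(trace.v[sel]))])
    return t_max


# ---------------------------------------------------------------------------
# Maximum-Margin Tempotron learning
# ---------------------------------------------------------------------------

def tempotron_update(neuron: TempotronNeuron, pattern: SpikePattern,
                     is_target: bool, learning_rate: float,
                     dt: float = 1.0) -> Tuple[np.ndarray, bool]:
    """One sample's weight delta under the Maximum-Margin Tempotron rule.

    Training thresholds: ``v_thr + margin`` for the target neuron,
    ``v_thr - margin`` for the rest. LTP when the target fails to fire
    (update at the time of maximum potential), LTD when a non-target fires
    (update at the erroneous spike time); otherwise zero.

    Returns ``(delta, error)`` where delta has one entry per input unit.
    """
    eff = neuron.v_thr + neuron.margin if is_target else neuron.v_thr - neuron.margin
    trace = membrane_trace(neuron, pattern, dt=dt, shunt_after_spike=True,
                           effective_thr=eff)
    delta = np.zeros_like(neuron.weights)
    if is_target and not trace.fired:
        sign = 1.0
    elif (not is_target) and trace.fired:
        sign = -1.0
    else:
        return delta, False
    units = pattern.unit_array()
    times = pattern.time_array()
    if sign > 0:
        t_max = _t_max_post_onset(trace, times)
    else:
        t_max, _ = find_t_max(trace)
    mask = times < t_max
    contrib = psp_kernel(neuron.kernel, t_max - times[mask])
    np.add.at(delta, units[mask], sign * learning_rate * contrib)
    return delta, True


def init_neurons(n_classes: int, n_units: int, kernel: KernelParams,
                 cfg: ClassifierConfig, v_thr: float = 1.0,
                 margin: float = 0.5, v_rest: float = 0.0) -> List[TempotronNeuron]:
    """One output neuron per class, Gaussian weights (mean 0, sigma from cfg)."""
    rng = np.random.default_rng(cfg.seed)
    return [
        TempotronNeuron(weights=rng.normal(0.0, cfg.weight_init_sigma, n_units),
                        kernel=kernel, v_thr=v_thr, margin=margin, v_rest=v_rest)
        for _ in range(n_classes)
    ]


def train_one_vs_all(patterns: Sequence[SpikePattern], n_classes: int,
                     cfg: ClassifierConfig,
                     kernel: Optional[KernelParams] = None,
                     v_thr: float = 1.0, margin: float = 0.5,
                     neurons: Optional[List[TempotronNeuron]] = None,
                     ) -> Tuple[List[TempotronNeuron], List[int]]:
    """Train one neuron per class on labeled spike patterns.

    Stochastic per-sample updates: each epoch presents all samples in a
    seeded shuffled order; every class neuron receives a Tempotron update
    with ``is_target = (label == class)``. Returns the trained neurons and
    the per-epoch count of erroneous (updated) neuron-sample pairs.
    """
    if not patterns:
        raise ValueError("train_one_vs_all requires a non-empty training set")
    for p in patterns:
        if p.label is None or not 0 <= p.label < n_classes:
            raise ValueError(f"pattern label {p.label} outside [0, {n_classes})")
    if kernel is None:
        kernel = make_kernel(750.0, 187.5)
    if neurons is None:
        n_units = patterns[0].n_units
        neurons = init_neurons(n_classes, n_units, kernel, cfg,
                               v_thr=v_thr, margin=margin)
    rng = np.random.default_rng(cfg.seed + 1)
    epoch_errors: List[int] = []
    for _ in range(cfg.epochs):
        errors = 0
        for i in rng.permutation(len(patterns)):
            p = patterns[i]
            for c, neuron in enumerate(neurons):
                delta, err = tempotron_update(neuron, p, is_target=(c == p.label),
                                              learning_rate=cfg.learning_rate,
                                              dt=cfg.dt)
                if err:
                    neuron.weights = neuron.weights + delta
                    errors += 1
        epoch_errors.append(errors)
    return neurons, epoch_errors


# ---------------------------------------------------------------------------
# Decision procedure
# ---------------------------------------------------------------------------

def classify(neurons: Sequence[TempotronNeuron], pattern: SpikePattern,
             dt: float = 1.0) -> Decision:
    """Apply the three-way decision rule at the plain threshold (no margin):

    1. no neuron fires -> class with the highest peak potential
       (ties: lowest class index);
    2. exactly one fires -> its class;
    3. several fire -> earliest spike (ties: higher peak, then lowest index).
    """
    spike_times: List[Optional[float]] = []
    peaks: List[float] = []
    for neuron in neurons:
        trace = membrane_trace(neuron, pattern, dt=dt, shunt_after_spike=True,
                               effective_thr=neuron.v_thr)
        spike_times.append(trace.spike_time)
        peaks.append(float(np.max(trace.v)))
    fired = [t is not None for t in spike_times]
    n_fired = sum(fired)
    duration = pattern.duration_ms
    if n_fired == 0:
        label = int(np.argmax(peaks))
        t_dec = duration
    elif n_fired == 1:
        label = fired.index(True)
        t_dec = float(spike_times[label])
    else:
        # earliest spike; ties by higher peak then lower index
        candidates = [(spike_times[c], -peaks[c], c)
                      for c in range(len(neurons)) if fired[c]]
        candidates.sort()
        label = candidates[0][2]
        t_dec = float(spike_times[label])
    return Decision(label=label, fired=fired, decision_time_ms=t_dec,
                    peak_potentials=peaks)


def truncate_pattern(pattern: SpikePattern, fraction: float) -> SpikePattern:
    """Keep only events with ``t <= fraction * duration`` (duration kept)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    cutoff = fraction * pattern.duration_ms
    events = [(u, t) for u, t in pattern.events if t <= cutoff]
    return SpikePattern(events=events, duration_ms=pattern.duration_ms,
                        n_units=pattern.n_units, label=pattern.label)


def accuracy(neurons: Sequence[TempotronNeuron],
             patterns: Sequence[SpikePattern], dt: float = 1.0) -> float:
    """Percent of patterns whose decided class matches the label."""
    if not patterns:
        raise ValueError("accuracy requires a non-empty pattern set")
    hits = sum(classify(neurons, p, dt=dt).label == p.label for p in patterns)
    return 100.0 * hits / len(patterns)


def evaluate_early_decision(neurons: Sequence[TempotronNeuron],
                            patterns: Sequence[SpikePattern],
                            fractions: Sequence[float],
                            dt: float = 1.0) -> Tuple[Dict[float, float], List[float]]:
    """Truncated-input accuracy plus decision-time statistics.

    For each fraction f, events after ``f * duration`` are removed before
    classification. On the full patterns, the ratio decision_time/duration is
    recorded per sample (1.0 when no neuron fires).
    """
    accs: Dict[float, float] = {}
    for f in fractions:
        truncated = [truncate_pattern(p, f) for p in patterns]
        accs[float(f)] = accuracy(neurons, truncated, dt=dt)
    ratios = [classify(neurons, p, dt=dt).decision_time_ms / p.duration_ms
              for p in patterns]
    return accs, ratios


# ---------------------------------------------------------------------------
# ReSuMe variant (spike-time based, single desired spike per class)
# ---------------------------------------------------------------------------

def resume_desired_time(neuron: TempotronNeuron,
                        class_patterns: Sequence[SpikePattern],
                        dt: float = 1.0) -> float:
    """Desired output spike time for one class: present each of the class's
    patterns to the randomly initialized neuron (no spiking) and return the
    mean of the times of maximum membrane potential."""
    if not class_patterns:
        raise ValueError("resume_desired_time requires at least one pattern")
    t_maxes = []
    for p in class_patterns:
        trace = membrane_trace(neuron, p, dt=dt, effective_thr=None)
        t_maxes.append(_t_max_post_onset(trace, p.time_array()))
    return float(np.mean(t_maxes))


def _resume_window_sum(pattern: SpikePattern, t_ref: float, amplitude: float,
                       tau_w: float, bias: float, n_units: int) -> np.ndarray:
    """Per-unit sum of the learning window over input spikes preceding t_ref."""
    out = np.zeros(n_units)
    units = pattern.unit_array()
    times = pattern.time_array()
    mask = times < t_ref
    vals = bias + amplitude * np.exp(-(t_ref - times[mask]) / tau_w)
    np.add.at(out, units[mask], vals)
    return out


def resume_train(patterns: Sequence[SpikePattern], n_classes: int,
                 desired_times: Sequence[float], cfg: ClassifierConfig,
                 kernel: Optional[KernelParams] = None, v_thr: float = 1.0,
                 amplitude: Optional[float] = None,
                 tau_w: Optional[float] = None, bias: float = 0.0,
                 neurons: Optional[List[TempotronNeuron]] = None,
                 ) -> Tuple[List[TempotronNeuron], List[int]]:
    """Remote-supervision training in the single-desired-spike regime.

    Each class neuron has one desired spike time. For its own class's
    patterns the neuron is potentiated at the desired time through an
    exponential window over preceding input spikes; wherever it actually
    spikes it is depressed through the same window, so an actual spike
    exactly at the desired time yields zero net update. Non-target neurons
    have no desired spike and are only depressed when they fire.
    """
    if len(desired_times) != n_classes:
        raise ValueError("need one desired time per class")
    if not patterns:
        raise ValueError("resume_train requires a non-empty training set")
    if kernel is None:
        kernel = make_kernel(750.0, 187.5)
    if amplitude is None:
        amplitude = cfg.learning_rate
    if tau_w is None:
        tau_w = kernel.tau_s
    n_units = patterns[0].n_units
    if neurons is None:
        neurons = init_neurons(n_classes, n_units, kernel, cfg, v_thr=v_thr,
                               margin=0.0)
    rng = np.random.default_rng(cfg.seed + 1)
    epoch_errors: List[int] = []
    for _ in range(cfg.epochs):
        errors = 0
        for i in rng.permutation(len(patterns)):
            p = patterns[i]
            for c, neuron in enumerate(neurons):
                trace = membrane_trace(neuron, p, dt=cfg.dt,
                                       shunt_after_spike=True,
                                       effective_thr=neuron.v_thr)
                t_des = desired_times[c] if c == p.label else None
                t_act = trace.spike_time
                if t_des is not None and t_act == t_des:
                    continue  # matched spike trains: zero net update
                delta = np.zeros(n_units)
                changed = False
                if t_des is not None:
                    delta += _resume_window_sum(p, t_des, amplitude, tau_w,
                                                bias, n_units)
                    changed = True
                if t_act is not None:
                    delta -= _resume_window_sum(p, t_act, amplitude, tau_w,
                                                bias, n_units)
                    changed = True
                if changed:
                    neuron.weights = neuron.weights + delta
                    errors += 1
        epoch_errors.append(errors)
    return neurons, epoch_errors


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_classifier(path, neurons: Sequence[TempotronNeuron]) -> None:
    first = neurons[0]
    payload = {
        "format": "somsnn-snn-v1",
        "n_classes": len(neurons),
        "n_units": int(first.weights.size),
        "kernel": asdict(first.kernel),
        "v_thr": first.v_thr,
        "margin": first.margin,
        "v_rest": first.v_rest,
        "weights": [n.weights.tolist() for n in neurons],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_classifier(path) -> List[TempotronNeuron]:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "somsnn-snn-v1":
        raise ValueError(f"{path}: not a classifier file")
    kernel = KernelParams(**payload["kernel"])
    return [
        TempotronNeuron(weights=np.array(w, dtype=np.float64), kernel=kernel,
                        v_thr=payload["v_thr"], margin=payload["margin"],
                        v_rest=payload["v_rest"])
        for w in payload["weights"]
    ]
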